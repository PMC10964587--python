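"""Beta diversity, PERMANOVA, paired tests, BH, concordance, sharing."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from amplipair.compare import (
    bh_adjust,
    bray_curtis,
    paired_wilcoxon,
    pcoa,
    permanova,
    shared_taxa,
    spearman_top_taxa,
    taxon_platform_comparison,
)
from amplipair.io import CountTable


def euclidean_dm(points: np.ndarray, ids=None) -> DistanceMatrix:
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_self_distance_zero(self):
        df = pd.DataFrame({"s1": [2, 1], "s2": [2, 1]}, index=["a", "b"])
        assert bray_curtis(CountTable(df))["s1", "s2"] == 0.0

    def test_disjoint_supports(self):
        df = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]}, index=["a", "b"])
        assert bray_curtis(CountTable(df))["s1", "s2"] == pytest.approx(1.0)

    def test_closed_form(self):
        df = pd.DataFrame({"s1": [2, 1], "s2": [1, 1]}, index=["a", "b"])
        assert bray_curtis(CountTable(df))["s1", "s2"] == pytest.approx(1 / 6)

    def test_matches_scipy_on_random_proportions(self, rng):
        df = pd.DataFrame(
            rng.integers(1, 200, size=(15, 6)), columns=[f"s{i}" for i in range(6)]
        )
        ours = bray_curtis(CountTable(df))
        ra = df / df.sum(axis=0)
        for i, j in itertools.combinations(range(6), 2):
            ref = scipy_braycurtis(ra.iloc[:, i], ra.iloc[:, j])
            assert ours[f"s{i}", f"s{j}"] == pytest.approx(ref)

    def test_zero_sum_sample_rejected(self):
        df = pd.DataFrame({"s1": [1, 1], "s2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            bray_curtis(CountTable(df))


class TestPcoa:
    def test_collinear_points_recovered_on_first_axis(self):
        dm = DistanceMatrix(
            np.array([[0.0, 3, 7], [3, 0, 4], [7, 4, 0]]), ids=["a", "b", "c"]
        )
        result = pcoa(dm)
        axis1 = result.coordinates.iloc[:, 0].to_numpy()
        gaps = [
            abs(axis1[0] - axis1[1]),
            abs(axis1[1] - axis1[2]),
            abs(axis1[0] - axis1[2]),
        ]
        assert gaps == pytest.approx([3.0, 4.0, 7.0], abs=1e-9)
        assert np.all(np.abs(result.eigenvalues[1:]) < 1e-9)

    def test_equilateral_distances_give_equal_positive_eigenvalues(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        eig = pcoa(dm).eigenvalues
        assert eig[0] == pytest.approx(eig[1])
        assert eig[0] > 0

    def test_reconstructs_euclidean_distances(self, rng):
        for _ in range(5):
            points = rng.normal(size=(12, 4))
            dm = euclidean_dm(points)
            coords = pcoa(dm).coordinates.to_numpy()
            rebuilt = squareform(pdist(coords))
            assert np.allclose(rebuilt, dm.data, atol=1e-9)

    def test_proportions_sum_to_one(self, rng):
        dm = euclidean_dm(rng.normal(size=(10, 3)))
        result = pcoa(dm)
        assert result.proportion_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(result.eigenvalues) <= 1e-9)

    def test_matches_skbio_eigenvalues(self, rng):
        dm = euclidean_dm(rng.normal(size=(9, 3)))
        ours = pcoa(dm).eigenvalues
        theirs = skbio_pcoa(dm, method="eigh").eigvals.to_numpy()
        assert np.allclose(ours[:6], theirs[:6], atol=1e-9)


def oracle_permanova_enumeration(dm: DistanceMatrix, labels: list) -> float:
    """Exhaustive PERMANOVA p-value, written from the sums-of-squares
    definition with explicit loops (independent of the implementation)."""
    d = dm.data
    n = len(labels)

    def f_stat(lab):
        groups = sorted(set(lab))
        a = len(groups)
        ss_total = sum(
            d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_within = 0.0
        for g in groups:
            members = [i for i in range(n) if lab[i] == g]
            ss_g = sum(
                d[i, j] ** 2
                for i in members
                for j in members
                if i < j
            )
            ss_within += ss_g / len(members)
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    assignments = set(itertools.permutations(labels))
    extreme = sum(f_stat(list(lab)) >= f_obs for lab in assignments)
    return extreme / len(assignments)


class TestPermanova:
    def test_no_separation_gives_large_p(self):
        dm = DistanceMatrix(np.ones((6, 6)) - np.eye(6), ids=list("abcdef"))
        res = permanova(dm, ["x"] * 3 + ["y"] * 3, n_permutations=199, seed=0)
        assert math.isfinite(res.pseudo_F)
        assert res.p_value > 0.5

    def test_exact_mode_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            points = rng.normal(size=(6, 3))
            points[3:] += rng.normal(scale=1.5, size=3)
            dm = euclidean_dm(points)
            labels = ["x"] * 3 + ["y"] * 3
            res = permanova(dm, labels, method="exact")
            assert res.p_value == pytest.approx(
                oracle_permanova_enumeration(dm, labels)
            )
            assert res.n_permutations == 20

    def test_extreme_separation_reaches_p_floor(self, rng):
        points = np.vstack(
            [rng.normal(0, 0.05, size=(6, 2)), rng.normal(50, 0.05, size=(6, 2))]
        )
        dm = euclidean_dm(points)
        res = permanova(dm, ["x"] * 6 + ["y"] * 6, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_pseudo_f_matches_skbio(self, rng):
        points = rng.normal(size=(14, 4))
        points[7:, 0] += 1.0
        dm = euclidean_dm(points)
        labels = ["x"] * 7 + ["y"] * 7
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=0)
        assert ours.pseudo_F == pytest.approx(float(theirs["test statistic"]))

    def test_deterministic_under_seed(self, rng):
        dm = euclidean_dm(rng.normal(size=(10, 3)))
        labels = ["x"] * 5 + ["y"] * 5
        a = permanova(dm, labels, n_permutations=99, seed=7)
        b = permanova(dm, labels, n_permutations=99, seed=7)
        assert a == b

    def test_small_group_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "x", "x", "y"])


def oracle_wilcoxon_exact(x, y) -> float:
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    m = d.size
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    t_obs = ranks[d > 0].sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=m):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    p = 2 * min(np.mean(stats <= t_obs), np.mean(stats >= t_obs))
    return min(1.0, p)


class TestPairedWilcoxon:
    def test_identical_vectors(self):
        assert paired_wilcoxon([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_five_consistent_pairs(self):
        _, p = paired_wilcoxon([2, 3, 4, 5, 6], [1.0, 1.5, 2.0, 2.5, 3.0])
        assert p == pytest.approx(2 / 32)

    @pytest.mark.parametrize("m", range(3, 11))
    def test_matches_sign_pattern_enumeration(self, m, rng):
        for _ in range(10):
            x = rng.normal(size=m)
            y = x + rng.normal(size=m)  # untied with probability 1
            _, p = paired_wilcoxon(x, y)
            assert p == pytest.approx(oracle_wilcoxon_exact(x, y))

    def test_tied_ranks_fall_back_to_corrected_normal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x + np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0])  # all |d| tied
        _, p = paired_wilcoxon(y, x)
        assert 0.0 < p <= 1.0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_closed_form_vector(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_definition(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q_sorted = [
                min((m / j) * p[order[j - 1]] for j in range(i, m + 1))
                for i in range(1, m + 1)
            ]
            q = np.empty(m)
            q[order] = np.minimum(q_sorted, 1.0)
            return q

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 20))
            assert bh_adjust(p) == pytest.approx(oracle(p))

    def test_q_dominates_p(self, rng):
        p = rng.uniform(size=30)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSpearmanTopTaxa:
    def test_identical_profiles_give_rho_one(self):
        df = pd.DataFrame(
            {"a1": [10, 30, 60], "a2": [20, 30, 50], "a3": [30, 30, 40]},
            index=["t1", "t2", "t3"],
        )
        rho = spearman_top_taxa(df, df.rename(columns=lambda c: "b" + c[1:]),
                                [("a1", "b1"), ("a2", "b2"), ("a3", "b3")], top_n=3)
        assert np.allclose(rho.to_numpy(), 1.0)

    def test_closed_form_negative_rho(self):
        # taxon X proportions across 3 subjects: A (.1,.2,.3), B (.3,.1,.2)
        a = pd.DataFrame({"a1": [10, 90], "a2": [20, 80], "a3": [30, 70]},
                         index=["X", "Y"])
        b = pd.DataFrame({"b1": [30, 70], "b2": [10, 90], "b3": [20, 80]},
                         index=["X", "Y"])
        rho = spearman_top_taxa(a, b, [("a1", "b1"), ("a2", "b2"), ("a3", "b3")],
                                top_n=2)
        assert rho["X"] == pytest.approx(-0.5)
        assert rho["Y"] == pytest.approx(-0.5)

    def test_top_n_selection_pools_platforms(self, rng):
        counts = rng.integers(1, 1000, size=(25, 8))
        a = pd.DataFrame(counts, index=[f"t{i}" for i in range(25)],
                         columns=[f"a{j}" for j in range(8)])
        b = pd.DataFrame(rng.integers(1, 1000, size=(25, 8)),
                         index=[f"t{i}" for i in range(25)],
                         columns=[f"b{j}" for j in range(8)])
        pairs = [(f"a{j}", f"b{j}") for j in range(8)]
        rho = spearman_top_taxa(a, b, pairs, top_n=20)
        assert len(rho) == 20
        ra = (a / a.sum()).mean(axis=1) + (b / b.sum()).mean(axis=1)
        expected_top = set(ra.sort_values(ascending=False).index[:20])
        assert set(rho.index) == expected_top


class TestSharedTaxa:
    def test_identical_tables_share_everything(self):
        df = pd.DataFrame({"s1": [50, 50], "s2": [30, 70]}, index=["a", "b"])
        shared, ua, ub = shared_taxa(df, df.copy())
        assert shared == {"a", "b"} and not ua and not ub

    def test_threshold_splits_presence(self):
        # taxon "rare": 0.05% on A, 0.5% on B
        a = pd.DataFrame({"s1": [1, 1999]}, index=["rare", "core"])
        b = pd.DataFrame({"s1": [10, 1990]}, index=["rare", "core"])
        shared, ua, ub = shared_taxa(a, b, min_mean_abundance=0.1)
        assert "rare" in ub and "rare" not in shared and not ua

    def test_matches_filter_then_compare_oracle(self, rng):
        a = pd.DataFrame(rng.integers(0, 300, size=(30, 5)),
                         index=[f"t{i}" for i in range(30)])
        b = pd.DataFrame(rng.integers(0, 300, size=(30, 5)),
                         index=[f"t{i}" for i in range(30)])
        shared, ua, ub = shared_taxa(a, b, min_mean_abundance=0.5)
        pa = set((100 * (a / a.sum()).mean(axis=1)).loc[lambda s: s > 0.5].index)
        pb = set((100 * (b / b.sum()).mean(axis=1)).loc[lambda s: s > 0.5].index)
        assert shared == pa & pb and ua == pa - pb and ub == pb - pa


class TestTaxonPlatformComparison:
    def test_q_dominates_p_and_contains_rho(self, rng):
        a = pd.DataFrame(rng.integers(1, 500, size=(12, 6)),
                         index=[f"t{i}" for i in range(12)],
                         columns=[f"a{j}" for j in range(6)])
        b = pd.DataFrame(rng.integers(1, 500, size=(12, 6)),
                         index=[f"t{i}" for i in range(12)],
                         columns=[f"b{j}" for j in range(6)])
        pairs = [(f"a{j}", f"b{j}") for j in range(6)]
        out = taxon_platform_comparison(a, b, pairs, top_n=10)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()
        assert out["spearman_rho"].notna().sum() == 10
        assert out["spearman_rho"].dropna().between(-1, 1).all()
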