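"""Beta diversity and between-platform statistics.

Bray–Curtis dissimilarity on relative abundances, classical metric PCoA
(eigendecomposition of the Gower-centred squared-distance matrix, negative
eigenvalues reported verbatim with no correction), seeded PERMANOVA with an
optional exhaustive-enumeration mode, paired Wilcoxon signed-rank tests with
Benjamini–Hochberg adjustment, Spearman concordance of the most abundant
taxa, and abundance-thresholded taxon sharing.

Distance matrices travel as :class:`skbio.DistanceMatrix` (symmetry and
zero diagonal enforced by construction).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "bray_curtis",
    "pcoa",
    "permanova",
    "paired_wilcoxon",
    "bh_adjust",
    "spearman_top_taxa",
    "shared_taxa",
    "taxon_platform_comparison",
]

logger = logging.getLogger("amplipair")


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA output: coordinates on positive axes, all eigenvalues, and the
    proportion of positive-eigenvalue variance each axis explains."""

    coordinates: pd.DataFrame  # samples × axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all, non-increasing (negatives kept verbatim)
    proportion_explained: np.ndarray  # per positive axis, sums to 1


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None


def bray_curtis(table: CountTable | pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples, on relative abundances.

    BC(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i) with x, y proportions.
    """
    if isinstance(table, CountTable):
        ra = table.relative_abundance()
    else:
        totals = table.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("zero-sum sample in abundance table")
        ra = table / totals
    if ra.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = ra.to_numpy().T  # samples × features
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    d = diff / tot
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(ra.columns))


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Eigendecomposition of -0.5 * J D^2 J with J the centering matrix;
    coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues.  Negative eigenvalues are reported but produce no axes.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least three samples for ordination")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(1.0, abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigval,
        proportion_explained=eigval[pos] / eigval[pos].sum(),
    )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups: "pd.Series | dict | list",
    n_permutations: int = 999,
    seed: int | None = 0,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational multivariate ANOVA (the adonis test) on a distance matrix.

    ``method="sampled"`` draws ``n_permutations`` random label permutations
    and uses the add-one p-value (#{F_perm >= F_obs} + 1)/(n_permutations+1).
    ``method="exact"`` enumerates every distinct assignment of the label
    multiset (feasible for small n) and reports the plain tail fraction.
    """
    ids = list(dm.ids)
    if isinstance(groups, dict):
        labels = [groups[i] for i in ids]
    elif isinstance(groups, pd.Series):
        labels = [groups[i] for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ValueError("one group label per sample required")
    codes, _ = pd.factorize(np.asarray(labels))
    sizes = np.bincount(codes)
    if codes.max() < 1:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = dm.data**2
    f_obs = _pseudo_f(d2, codes)
    if method == "exact":
        perms = {p for p in itertools.permutations(codes.tolist())}
        f_perm = np.array([_pseudo_f(d2, np.array(p)) for p in perms])
        p = float(np.mean(f_perm >= f_obs))
        return PermanovaResult(float(f_obs), p, len(perms), None)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm) >= f_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; the p-value is exact (full sign-pattern
    enumeration) when at most 25 non-zero differences remain and their
    absolute values are untied, otherwise a normal approximation with tie
    and continuity corrections is used.  All differences zero gives
    (0.0, 1.0) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    untied = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and untied) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _relative_abundance(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, CountTable):
        return table.relative_abundance()
    return table / table.sum(axis=0)


def spearman_top_taxa(
    table_a: CountTable | pd.DataFrame,
    table_b: CountTable | pd.DataFrame,
    pairs: list[tuple[str, str]],
    top_n: int = 20,
) -> pd.Series:
    """Per-taxon Spearman rho across paired samples for the most abundant taxa.

    Taxa are ranked by mean relative abundance pooled over both platforms'
    paired samples (so neither platform drives the selection); for each of
    the ``top_n`` taxa, rho is the rank correlation (average ranks on ties)
    of per-pair relative abundances between platforms.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three complete pairs")
    ra_a = _relative_abundance(table_a)
    ra_b = _relative_abundance(table_b)
    cols_a = [a for a, _ in pairs]
    cols_b = [b for _, b in pairs]
    taxa = ra_a.index.union(ra_b.index)
    ra_a = ra_a.reindex(taxa, fill_value=0.0)[cols_a]
    ra_b = ra_b.reindex(taxa, fill_value=0.0)[cols_b]
    pooled_mean = (ra_a.mean(axis=1) + ra_b.mean(axis=1)) / 2
    if len(taxa) < top_n:
        logger.warning(
            "only %d taxa available; using all instead of top %d", len(taxa), top_n
        )
        top_n = len(taxa)
    top = pooled_mean.sort_values(ascending=False).index[:top_n]
    rho = {}
    for taxon in top:
        a = ra_a.loc[taxon].to_numpy()
        b = ra_b.loc[taxon].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]):
            rho[taxon] = 1.0 if np.allclose(a, b) else float("nan")
        else:
            rho[taxon] = float(stats.spearmanr(a, b).statistic)
    return pd.Series(rho, name="spearman_rho")


def shared_taxa(
    table_a: CountTable | pd.DataFrame,
    table_b: CountTable | pd.DataFrame,
    min_mean_abundance: float = 0.1,
) -> tuple[set[str], set[str], set[str]]:
    """Taxa detected on both / only one platform above an abundance floor.

    A taxon is "present" on a platform when its mean relative abundance
    across that platform's samples exceeds ``min_mean_abundance`` (percent).
    Returns (shared, unique_to_a, unique_to_b).
    """
    ra_a = _relative_abundance(table_a) * 100.0
    ra_b = _relative_abundance(table_b) * 100.0
    present_a = set(ra_a.index[ra_a.mean(axis=1) > min_mean_abundance])
    present_b = set(ra_b.index[ra_b.mean(axis=1) > min_mean_abundance])
    return present_a & present_b, present_a - present_b, present_b - present_a


def taxon_platform_comparison(
    table_a: CountTable | pd.DataFrame,
    table_b: CountTable | pd.DataFrame,
    pairs: list[tuple[str, str]],
    top_n: int = 20,
) -> pd.DataFrame:
    """Per-taxon platform comparison table.

    For every taxon: mean relative abundance (percent) on each platform over
    the paired samples, the paired Wilcoxon statistic and p-value, the BH
    q-value across all taxa, and — for the pooled top-``top_n`` taxa — the
    Spearman rho between platforms.
    """
    ra_a = _relative_abundance(table_a)
    ra_b = _relative_abundance(table_b)
    cols_a = [a for a, _ in pairs]
    cols_b = [b for _, b in pairs]
    taxa = ra_a.index.union(ra_b.index)
    ra_a = ra_a.reindex(taxa, fill_value=0.0)[cols_a]
    ra_b = ra_b.reindex(taxa, fill_value=0.0)[cols_b]
    stats_rows = []
    for taxon in taxa:
        w, p = paired_wilcoxon(ra_a.loc[taxon], ra_b.loc[taxon])
        stats_rows.append(
            {
                "taxon": taxon,
                "mean_ra_a": 100.0 * ra_a.loc[taxon].mean(),
                "mean_ra_b": 100.0 * ra_b.loc[taxon].mean(),
                "wilcoxon_statistic": w,
                "p_value": p,
            }
        )
    out = pd.DataFrame(stats_rows).set_index("taxon")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    rho = spearman_top_taxa(table_a, table_b, pairs, top_n=top_n)
    out["spearman_rho"] = rho.reindex(out.index)
    return out.sort_values("q_value")
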