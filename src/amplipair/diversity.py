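"""Rarefaction, alpha diversity and rank aggregation.

Conventions: Chao1 is the bias-corrected form S_obs + f1(f1-1)/(2(f2+1))
(the default in the dominant community-ecology software); Shannon uses the
natural log (nats).  Rarefaction subsamples without replacement
(multivariate hypergeometric); the analytic expected-richness curve
E[S_d] = sum_i (1 - C(N-N_i, d)/C(N, d)) is evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CountTable, Lineage

__all__ = [
    "AlphaDiversity",
    "RarefactionCurve",
    "rarefy",
    "rarefaction_curve",
    "chao1",
    "shannon",
    "aggregate_to_rank",
    "alpha_diversity_table",
]

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    observed_features: int
    chao1: float
    shannon: float

    def __post_init__(self) -> None:
        if self.chao1 < self.observed_features:
            raise ValueError("chao1 cannot fall below observed richness")
        if self.shannon < 0:
            raise ValueError("shannon entropy cannot be negative")


@dataclass(frozen=True)
class RarefactionCurve:
    sample_id: str
    depths: tuple[int, ...]
    expected_richness: tuple[float, ...]


def _as_counts(counts: Mapping[str, int] | pd.Series) -> pd.Series:
    s = pd.Series(counts, dtype="int64")
    if (s < 0).any():
        raise ValueError("counts must be non-negative")
    return s


def rarefy(
    counts: Mapping[str, int] | pd.Series, depth: int, seed: int = 0
) -> pd.Series:
    """Subsample one sample's counts to ``depth`` reads without replacement."""
    s = _as_counts(counts)
    total = int(s.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    if depth == total:
        return s.copy()
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(s.to_numpy(), depth)
    return pd.Series(drawn, index=s.index)


def rarefaction_curve(
    counts: Mapping[str, int] | pd.Series, depths: Sequence[int], sample_id: str = ""
) -> RarefactionCurve:
    """Analytic expected richness at each depth (hypergeometric expectation)."""
    s = _as_counts(counts)
    n = int(s.sum())
    if n == 0:
        raise ValueError("sample has zero total count")
    ni = s.to_numpy()[s.to_numpy() > 0]
    expected = []
    for d in depths:
        if d > n:
            raise ValueError(f"depth {d} exceeds total count {n}")
        # P(feature i absent) = C(n - ni, d) / C(n, d), 0 when d > n - ni
        keep = (n - ni) >= d
        log_absent = np.full(ni.shape, -np.inf)
        m = n - ni[keep]
        log_absent[keep] = (
            gammaln(m + 1)
            - gammaln(d + 1)
            - gammaln(m - d + 1)
            - (gammaln(n + 1) - gammaln(d + 1) - gammaln(n - d + 1))
        )
        expected.append(float(np.sum(1.0 - np.exp(log_absent))))
    return RarefactionCurve(
        sample_id=sample_id,
        depths=tuple(int(d) for d in depths),
        expected_richness=tuple(expected),
    )


def chao1(counts: Mapping[str, int] | pd.Series) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1)/(2(f2+1))."""
    s = _as_counts(counts)
    if s.sum() == 0:
        raise ValueError("sample has zero total count")
    nz = s[s > 0]
    s_obs = len(nz)
    f1 = int((nz == 1).sum())
    f2 = int((nz == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: Mapping[str, int] | pd.Series) -> float:
    """Shannon entropy of the relative-abundance distribution, in nats."""
    s = _as_counts(counts)
    total = s.sum()
    if total == 0:
        raise ValueError("sample has zero total count")
    p = s[s > 0].to_numpy() / total
    return float(-(p * np.log(p)).sum())


def aggregate_to_rank(
    table: CountTable, assignments: Mapping[str, "object"], rank: str
) -> CountTable:
    """Sum counts over features sharing the named rank value.

    ``assignments`` maps feature id to anything exposing ``.lineage``
    (an :class:`~amplipair.assign.AssignmentResult`) or to a
    :class:`~amplipair.io.Lineage` directly.  Features unassigned at the
    rank are pooled under the reserved ``Unassigned`` row.  Per-sample
    totals are preserved exactly.
    """
    labels = {}
    for feat in table.feature_ids:
        if feat not in assignments:
            raise ValueError(f"feature {feat!r} has no assignment")
        entry = assignments[feat]
        lineage: Lineage = getattr(entry, "lineage", entry)
        name = lineage.get(rank)
        labels[feat] = name if name else UNASSIGNED
    grouped = table.data.groupby(
        pd.Series(labels).reindex(table.feature_ids)
    ).sum()
    grouped.index.name = "feature_id"
    return CountTable(grouped)


def alpha_diversity_table(
    table: CountTable, depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 and Shannon.

    When ``depth`` is given each sample is first rarefied to it with a
    single seeded draw (samples shallower than ``depth`` are skipped, which
    mirrors common pipeline behaviour).
    """
    rows = []
    for i, sid in enumerate(table.sample_ids):
        s = table.sample_counts(sid)
        if depth is not None:
            if s.sum() < depth:
                continue
            s = rarefy(s, depth, seed=seed + i)
        rows.append(
            {
                "sample_id": sid,
                "observed_features": int((s > 0).sum()),
                "chao1": chao1(s),
                "shannon": shannon(s),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
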