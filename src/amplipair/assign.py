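"""Two-tier taxonomic assignment of ASV sequences.

Tier 1: a query identical to a reference sequence inherits its full lineage
(``method="exact"``).  Tier 2: a k-mer naive-Bayes classifier with bootstrap
confidence assigns the lineage down to genus; queries that reach genus are
then aligned against the whole reference database and the identity-gap rule
decides whether a species can be called (``method="nb_gap"``), otherwise the
read stays at genus (``nb_only``).  Queries whose bootstrap support does not
reach the genus threshold are ``unassigned``.

The classifier follows the classical rRNA naive-Bayes convention: 8-mer
word-presence likelihoods per genus with prior (n_g(w)+0.5)/(N_g+1), and
bootstrap resamples of ceil(W/8) of the query's W distinct words.

The identity-gap rule mirrors common best-hit curation practice: keep hits
with full query coverage and >= 97% identity; call the best hit's species
only when it beats the best hit of any *other* species by more than 2
identity points.  Ties across species are never called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import semiglobal_identity
from .io import RANKS, CountTable, Lineage, SequenceRecord

__all__ = [
    "Hit",
    "AssignmentResult",
    "ReferenceDB",
    "align_identity",
    "species_gap_rule",
    "nb_classify",
    "assign_all",
    "pct_assigned",
]

KMER_K = 8


@dataclass(frozen=True)
class Hit:
    """One database match of a query: reference id, species, identity, coverage."""

    ref_id: str
    species: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must be in [0, 100]")


@dataclass(frozen=True)
class AssignmentResult:
    """Assigned lineage, per-rank bootstrap confidence, and the pathway used."""

    lineage: Lineage
    confidence: dict[str, float] = field(default_factory=dict)
    method: str = "unassigned"  # exact | nb_gap | nb_only | unassigned

    def __post_init__(self) -> None:
        if self.method not in ("exact", "nb_gap", "nb_only", "unassigned"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.lineage.species and self.method not in ("exact", "nb_gap"):
            raise ValueError("species may only be set by the exact or gap pathway")


def _kmer_codes(residues: str, k: int = KMER_K) -> np.ndarray:
    """Distinct k-mer codes (base-4) of a sequence; windows containing
    ambiguity codes are skipped."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    words = win[valid] @ powers
    return np.unique(words)


class ReferenceDB:
    """Species-labelled reference sequences plus the per-genus word index."""

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        lineages: Mapping[str, Lineage],
        k: int = KMER_K,
    ) -> None:
        if not records:
            raise ValueError("reference database is empty")
        self.records = list(records)
        self.lineages = dict(lineages)
        self.k = k
        for rec in self.records:
            lin = self.lineages.get(rec.id)
            if lin is None:
                raise ValueError(f"reference {rec.id!r} has no lineage")
            if not lin.species:
                raise ValueError(f"reference {rec.id!r} lineage lacks a species")
        # genera sorted by name: classification is then invariant to the
        # order references were supplied in, and argmax ties are deterministic
        self.genera = sorted({self.lineages[r.id].genus for r in self.records})
        self._genus_index = {g: i for i, g in enumerate(self.genera)}
        # lineage prefix (ranks above species) representing each genus
        self.genus_lineage: dict[str, Lineage] = {}
        for rec in self.records:
            lin = self.lineages[rec.id]
            self.genus_lineage.setdefault(lin.genus, lin.truncate(6))
        self._loglik: np.ndarray | None = None
        self._by_sequence = {}
        for rec in self.records:
            self._by_sequence.setdefault(rec.residues, rec.id)

    def exact_match(self, residues: str) -> str | None:
        """Reference id whose sequence equals ``residues`` exactly, if any."""
        return self._by_sequence.get(residues)

    @property
    def loglik(self) -> np.ndarray:
        """Genus × 4^k log word likelihood matrix (lazy)."""
        if self._loglik is None:
            n_words = 4**self.k
            counts = np.zeros((len(self.genera), n_words), dtype=np.float64)
            n_seqs = np.zeros(len(self.genera), dtype=np.float64)
            for rec in self.records:
                gi = self._genus_index[self.lineages[rec.id].genus]
                words = _kmer_codes(rec.residues, self.k)
                counts[gi, words] += 1.0
                n_seqs[gi] += 1.0
            self._loglik = np.log(
                (counts + 0.5) / (n_seqs[:, None] + 1.0)
            ).astype(np.float32)
        return self._loglik


def align_identity(
    query: SequenceRecord, ref: SequenceRecord
) -> tuple[float, float]:
    """Semi-global identity/coverage of ``query`` against ``ref``.

    Free end gaps on the reference, full query aligned; identity counts
    internal gap columns; coverage is 100 by construction.
    """
    return semiglobal_identity(query.residues, ref.residues)


def species_gap_rule(
    hits: Iterable[Hit],
    min_identity: float = 97.0,
    min_coverage: float = 100.0,
    gap: float = 2.0,
) -> str | None:
    """Best-hit species call with an identity-gap safeguard.

    Returns the best-identity hit's species iff no hit of a *different*
    species comes within ``gap`` identity points of it; ties at the top
    across species yield no call.  The result does not depend on input
    order.
    """
    kept = [
        h
        for h in hits
        if h.coverage >= min_coverage and h.identity >= min_identity
    ]
    if not kept:
        return None
    best = max(kept, key=lambda h: h.identity)
    others = [h.identity for h in kept if h.species != best.species]
    if not others:
        return best.species
    second = max(others)
    if second >= best.identity:  # a different species ties (or beats) the top
        return None
    return best.species if best.identity - second > gap else None


def nb_classify(
    query: SequenceRecord,
    db: ReferenceDB,
    n_boot: int = 100,
    min_conf: float = 80.0,
    seed=0,
) -> AssignmentResult:
    """Naive-Bayes genus classification with bootstrap confidence.

    The lineage is truncated at the deepest rank whose bootstrap confidence
    reaches ``min_conf``; species is never set here.
    """
    words = _kmer_codes(query.residues, db.k)
    if words.size == 0:
        return AssignmentResult(Lineage.empty(), {}, "unassigned")
    L = db.loglik[:, words]  # genera × W
    top = int(np.argmax(L.sum(axis=1)))
    rng = np.random.default_rng(seed)
    w = words.size
    draw = math.ceil(w / 8)
    picks = rng.integers(0, w, size=(n_boot, draw))
    # bootstrap scores: for each resample, per-genus sum over drawn words
    boot_scores = L[:, picks.ravel()].reshape(len(db.genera), n_boot, draw).sum(axis=2)
    winners = np.argmax(boot_scores, axis=0)  # per-bootstrap top genus
    top_lineage = db.genus_lineage[db.genera[top]]
    winner_lineages = [db.genus_lineage[db.genera[g]] for g in winners]
    confidence: dict[str, float] = {}
    for depth, rank in enumerate(RANKS[:6]):
        name = top_lineage.ranks[depth]
        conf = 100.0 * sum(
            1 for wl in winner_lineages if wl.ranks[depth] == name
        ) / n_boot
        confidence[rank] = conf
    depth = 0
    for rank in RANKS[:6]:
        if confidence[rank] >= min_conf:
            depth += 1
        else:
            break
    lineage = top_lineage.truncate(depth)
    method = "nb_only" if lineage.genus else "unassigned"
    return AssignmentResult(lineage, confidence, method)


def assign_all(
    queries: Sequence[SequenceRecord],
    db: ReferenceDB,
    n_boot: int = 100,
    min_conf: float = 80.0,
    min_identity: float = 97.0,
    min_coverage: float = 100.0,
    gap: float = 2.0,
    restrict_to_genus: bool = False,
    seed: int = 0,
) -> dict[str, AssignmentResult]:
    """Run the full assignment pathway for every query.

    Pathway: exact full-sequence match -> naive-Bayes genus -> alignment of
    genus-assigned queries against the database (optionally restricted to
    the classified genus) with the identity-gap species rule.
    """
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate query ids: {dups}")
    results: dict[str, AssignmentResult] = {}
    for qi, query in enumerate(queries):
        ref_id = db.exact_match(query.residues)
        if ref_id is not None:
            results[query.id] = AssignmentResult(
                db.lineages[ref_id], {}, "exact"
            )
            continue
        # per-query deterministic substream
        nb = nb_classify(
            query, db, n_boot=n_boot, min_conf=min_conf, seed=(seed, qi)
        )
        if not nb.lineage.genus:
            results[query.id] = nb
            continue
        candidates = db.records
        if restrict_to_genus:
            candidates = [
                r for r in db.records
                if db.lineages[r.id].genus == nb.lineage.genus
            ]
        hits = []
        for ref in candidates:
            identity, coverage = align_identity(query, ref)
            hits.append(
                Hit(ref.id, db.lineages[ref.id].species, identity, coverage)
            )
        species = species_gap_rule(
            hits, min_identity=min_identity, min_coverage=min_coverage, gap=gap
        )
        if species is None:
            results[query.id] = nb
        else:
            best = max(
                (h for h in hits if h.species == species),
                key=lambda h: h.identity,
            )
            results[query.id] = AssignmentResult(
                db.lineages[best.ref_id], nb.confidence, "nb_gap"
            )
    return results


def pct_assigned(
    assignments: Mapping[str, AssignmentResult],
    counts: CountTable,
    rank: str,
) -> tuple[float, pd.Series]:
    """Percent of reads assigned at ``rank``: pooled and per sample.

    Weighted by read counts: a feature counts as assigned when its lineage
    names the requested rank.
    """
    missing = [f for f in counts.feature_ids if f not in assignments]
    if missing:
        raise ValueError(f"features without assignments: {missing[:5]}")
    assigned_mask = pd.Series(
        {f: bool(assignments[f].lineage.get(rank)) for f in counts.feature_ids}
    )
    totals = counts.totals()
    if totals.sum() == 0:
        raise ValueError("count table has zero total reads")
    assigned = counts.data[assigned_mask.reindex(counts.feature_ids)].sum(axis=0)
    per_sample = 100.0 * assigned / totals
    pooled = 100.0 * assigned.sum() / totals.sum()
    return float(pooled), per_sample
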