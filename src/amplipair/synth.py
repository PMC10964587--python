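"""Synthetic inputs for the whole pipeline.

Everything downstream — classification, diversity, platform comparison — is
exercised on data from this module, so it generates:

* a species-labelled reference database with controlled identity structure
  (genera diverge from a common ancestor, species within a genus diverge
  from their genus ancestor, and the species-level differences are placed
  mostly *outside* the short-read window so that V3-V4 fragments of
  congeneric species are harder to tell apart than full-length genes);
* mock-community read sets with known truth labels;
* a paired-platform, multi-niche count-table study with known per-sample
  true proportions and per-taxon platform bias.

All generators are deterministic under their seed.  Mutations used to build
the reference are substitutions only, which makes the identity targets
analytic: two sequences independently mutated from an ancestor at per-site
rate d share a site with probability (1-d)^2 + d^2/3, so d is solved from
the requested pairwise identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NICHES, PLATFORMS, CountTable, Lineage, SampleMetadata, SequenceRecord
from .mock import MockComponent, expected_composition

__all__ = [
    "ReferenceSpec",
    "StudyDesign",
    "BiasModel",
    "GroundTruth",
    "generate_reference",
    "extract_subregion",
    "simulate_mock_reads",
    "simulate_paired_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReferenceSpec:
    """Parameters of the synthetic reference database.

    ``inter_genus_identity`` / ``intra_genus_identity`` are target mean
    pairwise identities between genera and between congeneric species.
    ``subregion`` is the 0-based half-open window standing in for the V3-V4
    hypervariable stretch; ``intra_subregion_weight`` is the probability
    that a species-level substitution falls inside that window (small, so
    short fragments under-resolve species).
    """

    n_genera: int = 10
    species_per_genus: int = 3
    gene_length: int = 1450
    inter_genus_identity: float = 0.85
    intra_genus_identity: float = 0.975
    subregion: tuple[int, int] = (450, 870)
    intra_subregion_weight: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("need at least one genus and one species per genus")
        if not (0 < self.inter_genus_identity < self.intra_genus_identity < 1):
            raise ValueError(
                "need 0 < inter_genus_identity < intra_genus_identity < 1"
            )
        s, e = self.subregion
        if not (0 <= s < e <= self.gene_length):
            raise ValueError("subregion must lie within the gene")


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the paired-platform study.

    Defaults emulate a 9-subject, 3-niche design sequenced on both
    platforms, with one faecal sample missing and an ~8x depth asymmetry
    (short-read mean 100,000 vs long-read mean 12,500 filtered reads).
    Compositional variability has three log-normal layers: ``base_sigma``
    spreads taxon weights within a niche, ``subject_sigma`` is the
    between-subject effect (shared by both platforms of a subject), and
    ``technical_sigma`` is independent library-level noise per (sample,
    platform) from PCR/prep.
    """

    n_subjects: int = 9
    niches: tuple[str, ...] = NICHES
    platforms: tuple[str, ...] = PLATFORMS
    mean_depth: Mapping[str, float] = field(
        default_factory=lambda: {"illumina": 100_000.0, "pacbio": 12_500.0}
    )
    missing: tuple[tuple[str, str], ...] = (("S9", "faeces"),)
    base_sigma: float = 1.5
    subject_sigma: float = 0.8
    technical_sigma: float = 0.2
    seed: int = 0

    def subjects(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subjects)]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for p in self.platforms:
            if self.mean_depth[p] < 1:
                raise ValueError("mean depths must be >= 1")
        subjects = set(self.subjects())
        for subj, niche in self.missing:
            if subj not in subjects or niche not in self.niches:
                raise ValueError(f"missing pair ({subj}, {niche}) not in design")


@dataclass(frozen=True)
class BiasModel:
    """Multiplicative per-(taxon, platform) representation factors."""

    factors: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.factors.values()):
            raise ValueError("bias multipliers must be positive")

    def factor(self, taxon: str, platform: str) -> float:
        return self.factors.get((taxon, platform), 1.0)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew: the recovery target for tests."""

    base_composition: dict[str, dict[str, float]]  # niche -> taxon -> fraction
    bias: BiasModel
    sample_proportions: dict[str, dict[str, float]]  # sample_id -> taxon -> fraction


def _divergence_for_identity(identity: float) -> float:
    """Per-lineage substitution fraction d so that two sequences mutated
    independently from one ancestor have expected identity ``identity``:
    solve (1-d)^2 + d^2/3 = identity for the smaller root."""
    a, b, c = 4.0 / 3.0, -2.0, 1.0 - identity
    return (-b - math.sqrt(b * b - 4 * a * c)) / (2 * a)


def _mutate(
    seq: np.ndarray, n_mut: int, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute ``n_mut`` distinct positions (drawn from ``positions``)
    with a uniformly chosen *different* base."""
    out = seq.copy()
    pos = rng.choice(positions, size=min(n_mut, positions.size), replace=False)
    for p in pos:
        current = out[p]
        choices = _BASES[_BASES != current]
        out[p] = rng.choice(choices)
    return out


def generate_reference(
    spec: ReferenceSpec,
) -> tuple[list[SequenceRecord], dict[str, Lineage]]:
    """Build the labelled reference database described by ``spec``.

    One ancestral gene per genus is derived from a global root at the
    inter-genus divergence; each species mutates its genus ancestor at the
    intra-genus divergence, with species-level substitutions placed inside
    the short-read window only with probability ``intra_subregion_weight``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.gene_length
    root = rng.integers(0, 4, size=L)
    root = _BASES[root]
    d_inter = _divergence_for_identity(spec.inter_genus_identity)
    d_intra = _divergence_for_identity(spec.intra_genus_identity)
    all_pos = np.arange(L)
    s, e = spec.subregion
    window = np.zeros(L, dtype=bool)
    window[s:e] = True
    inside, outside = all_pos[window], all_pos[~window]

    records: list[SequenceRecord] = []
    lineages: dict[str, Lineage] = {}
    # cross-genus pairs carry genus- plus species-level substitutions, so the
    # genus ancestors only need the difference to land on the inter target
    n_inter = int(round(max(d_inter - d_intra, 0.0) * L))
    n_intra = int(round(d_intra * L))
    for g in range(spec.n_genera):
        genus = f"Genus{g + 1:02d}"
        ancestor = _mutate(root, n_inter, all_pos, rng)
        for sp in range(spec.species_per_genus):
            species = f"{genus} species{sp + 1:02d}"
            n_in = rng.binomial(n_intra, spec.intra_subregion_weight)
            n_out = n_intra - n_in
            seq = _mutate(ancestor, n_in, inside, rng)
            seq = _mutate(seq, n_out, outside, rng)
            rec_id = f"ref_g{g + 1:02d}_s{sp + 1:02d}"
            residues = seq.tobytes().decode("ascii")
            records.append(
                SequenceRecord(id=rec_id, residues=residues, description=species)
            )
            lineages[rec_id] = Lineage(
                (
                    "Bacteria",
                    f"Phylum{g % 4 + 1:02d}",
                    f"Class{g % 4 + 1:02d}",
                    f"Order{g % 4 + 1:02d}",
                    f"Family{g + 1:02d}",
                    genus,
                    species,
                )
            )
    return records, lineages


def extract_subregion(
    record: SequenceRecord, interval: tuple[int, int]
) -> SequenceRecord:
    """Slice a 0-based half-open window out of a sequence.

    The id is suffixed with the interval so slices stay distinguishable
    from their source.
    """
    start, end = interval
    if not (0 <= start < end <= len(record.residues)):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds for {record.id!r} "
            f"(length {len(record.residues)})"
        )
    return SequenceRecord(
        id=f"{record.id}_{start}_{end}",
        residues=record.residues[start:end],
        description=record.description,
    )


def simulate_mock_reads(
    community: Sequence[MockComponent],
    refs: Mapping[str, SequenceRecord],
    n_reads: int,
    subst_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Draw reads from a mock community's expected composition.

    Read counts per species are multinomial at the copy-number-normalised
    expected proportions; each read carries i.i.d. substitutions at
    ``subst_rate``.  Returns the reads and a complete read-id -> true
    species mapping.
    """
    for comp in community:
        if comp.name not in refs:
            raise ValueError(f"community member {comp.name!r} missing from reference")
    rng = np.random.default_rng(seed)
    expectation = expected_composition(community)
    probs = (expectation.relative_abundance() / 100.0).to_numpy()
    names = list(expectation.table.index)
    counts = rng.multinomial(n_reads, probs)
    reads: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    idx = 0
    for name, n in zip(names, counts):
        template = np.frombuffer(
            refs[name].residues.encode("ascii"), dtype=np.uint8
        )
        for _ in range(n):
            seq = template.copy()
            if subst_rate > 0:
                mask = rng.random(seq.shape[0]) < subst_rate
                for p in np.flatnonzero(mask):
                    choices = _BASES[_BASES != seq[p]]
                    seq[p] = rng.choice(choices)
            read_id = f"read_{idx:06d}"
            reads.append(
                SequenceRecord(
                    id=read_id,
                    residues=seq.tobytes().decode("ascii"),
                    description=f"from {name}",
                )
            )
            truth[read_id] = name
            idx += 1
    return reads, truth


def simulate_paired_study(
    design: StudyDesign,
    taxa: Sequence[str],
    bias: BiasModel | None = None,
) -> tuple[dict[str, CountTable], list[SampleMetadata], GroundTruth]:
    """Simulate the paired-platform count-table study.

    Per niche a base composition is drawn once (log-normal weights,
    normalised); each subject modulates it with a log-normal effect; each
    platform further multiplies by its bias factors and renormalises; counts
    are multinomial at a Poisson-perturbed depth around the platform mean.
    Missing (subject, niche) pairs are absent from both platforms' output.
    """
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    bias = bias or BiasModel()
    rng = np.random.default_rng(design.seed)
    taxa = list(taxa)
    k = len(taxa)

    base: dict[str, np.ndarray] = {}
    for niche in design.niches:
        w = rng.lognormal(0.0, design.base_sigma, size=k)
        base[niche] = w / w.sum()

    bias_vec = {
        p: np.array([bias.factor(t, p) for t in taxa]) for p in design.platforms
    }

    counts: dict[str, dict[str, np.ndarray]] = {p: {} for p in design.platforms}
    metadata: list[SampleMetadata] = []
    sample_props: dict[str, dict[str, float]] = {}
    missing = set(design.missing)
    for niche in design.niches:
        for subject in design.subjects():
            effect = rng.lognormal(0.0, design.subject_sigma, size=k)
            if (subject, niche) in missing:
                continue  # effect drawn anyway so other samples are unaffected
            subj_p = base[niche] * effect
            subj_p = subj_p / subj_p.sum()
            for platform in design.platforms:
                # library-level technical noise: each platform's library of a
                # sample is an independent log-normal perturbation of the
                # subject's composition (PCR/prep variability)
                tech = rng.lognormal(0.0, design.technical_sigma, size=k)
                q = subj_p * bias_vec[platform] * tech
                q = q / q.sum()
                depth = max(1, int(rng.poisson(design.mean_depth[platform])))
                c = rng.multinomial(depth, q)
                sid = f"{platform[0].upper()}_{subject}_{niche}"
                counts[platform][sid] = c
                metadata.append(
                    SampleMetadata(
                        sample_id=sid, subject=subject, niche=niche, platform=platform
                    )
                )
                sample_props[sid] = dict(zip(taxa, q.tolist()))

    tables = {
        p: CountTable(
            pd.DataFrame(counts[p], index=pd.Index(taxa, name="feature_id"))
        )
        for p in design.platforms
    }
    truth = GroundTruth(
        base_composition={
            n: dict(zip(taxa, base[n].tolist())) for n in design.niches
        },
        bias=bias,
        sample_proportions=sample_props,
    )
    return tables, metadata, truth
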