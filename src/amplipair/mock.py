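"""Expected composition of defined mock communities.

When equal DNA masses of several species are pooled, the expected fraction of
16S rRNA amplicon reads per species is *not* equal: a species with a small
genome packs more genome copies into a nanogram, and each genome carries a
species-specific number of rRNA operon (rrn) copies.  The model is

    mass_per_genome  = genome_size_bp * w          (w = 1.079e-12 ng per bp)
    genomes_per_ng   = input_mass / mass_per_genome
    copies_per_ng    = genomes_per_ng * rrn_copy_number
    RA_i (%)         = 100 * copies_i / sum_j copies_j

All arithmetic is done at full float precision; rounding happens only when a
table is printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BP_MASS_NG",
    "MockComponent",
    "MockExpectation",
    "mass_per_genome",
    "expected_composition",
    "compare_to_expected",
    "MOCK1_COMPONENTS",
    "MOCK2_COMPONENTS",
]

#: mean mass of one double-stranded base pair, in nanograms
BP_MASS_NG = 1.079e-12


@dataclass(frozen=True)
class MockComponent:
    """One community member: its genome size, rrn copy number and input mass."""

    name: str
    genome_size: int  # bp
    copy_number: int  # 16S rRNA gene copies per genome
    input_mass: float = 1.0  # ng

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"{self.name}: genome_size must be positive")
        if self.copy_number < 1:
            raise ValueError(f"{self.name}: copy_number must be >= 1")
        if self.input_mass <= 0:
            raise ValueError(f"{self.name}: input_mass must be positive")


@dataclass(frozen=True)
class MockExpectation:
    """Derived expectation table for a mock community.

    ``table`` has one row per component with columns ``genome_size``,
    ``copy_number``, ``input_mass``, ``mass_per_genome`` (ng),
    ``genomes_per_ng``, ``copies_per_ng`` and ``relative_abundance`` (percent,
    summing to 100).
    """

    table: pd.DataFrame
    total_copies: float

    def relative_abundance(self) -> pd.Series:
        return self.table["relative_abundance"]


def mass_per_genome(genome_size: int | float) -> float:
    """Mass of one genome in ng: size in bp times the mean bp mass."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return genome_size * BP_MASS_NG


def expected_composition(components: Sequence[MockComponent]) -> MockExpectation:
    """Copy-number-normalised expected composition of a mock community."""
    if not components:
        raise ValueError("need at least one component")
    names = [c.name for c in components]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate component names: {dups}")
    mass = np.array([mass_per_genome(c.genome_size) for c in components])
    genomes = np.array([c.input_mass for c in components]) / mass
    copies = genomes * np.array([c.copy_number for c in components])
    total = copies.sum()
    ra = 100.0 * copies / total
    table = pd.DataFrame(
        {
            "genome_size": [c.genome_size for c in components],
            "copy_number": [c.copy_number for c in components],
            "input_mass": [c.input_mass for c in components],
            "mass_per_genome": mass,
            "genomes_per_ng": genomes / np.array([c.input_mass for c in components]),
            "copies_per_ng": copies / np.array([c.input_mass for c in components]),
            "relative_abundance": ra,
        },
        index=pd.Index(names, name="name"),
    )
    return MockExpectation(table=table, total_copies=float(total))


def compare_to_expected(
    observed: Mapping[str, float], expected: MockExpectation
) -> pd.DataFrame:
    """Observed-vs-expected deviation table.

    ``observed`` maps component name to observed relative abundance in
    percent.  Names present on only one side are kept, with the missing side
    reported as 0 and flagged (``only_observed`` marks putative false
    positives, ``only_expected`` marks dropouts).  ``difference`` is
    observed − expected; ``ratio`` is observed / expected (NaN when the
    expectation is 0).
    """
    if any(v < 0 for v in observed.values()):
        raise ValueError("observed abundances must be non-negative")
    exp = expected.table["relative_abundance"]
    names = list(exp.index) + [n for n in observed if n not in exp.index]
    rows = []
    for name in names:
        e = float(exp.get(name, 0.0))
        o = float(observed.get(name, 0.0))
        if name not in observed:
            flag = "only_expected"
        elif name not in exp.index:
            flag = "only_observed"
        else:
            flag = ""
        rows.append(
            {
                "name": name,
                "observed": o,
                "expected": e,
                "difference": o - e,
                "ratio": o / e if e > 0 else float("nan"),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("name")


# Components of the two in-house mock communities used in the paired-platform
# benchmark (genome size in bp and rrn copy number per strain; 1 ng of each
# species' DNA).  Mock 2 swaps Neisseria sicca for Streptococcus mutans.
MOCK1_COMPONENTS: tuple[MockComponent, ...] = (
    MockComponent("Actinomyces oris", 3_184_721, 3),
    MockComponent("Fusobacterium nucleatum", 2_443_126, 5),
    MockComponent("Rothia dentocariosa", 2_506_025, 3),
    MockComponent("Streptococcus oralis", 1_931_548, 4),
    MockComponent("Neisseria sicca", 2_566_407, 4),
)

MOCK2_COMPONENTS: tuple[MockComponent, ...] = (
    MockComponent("Actinomyces oris", 3_184_721, 3),
    MockComponent("Fusobacterium nucleatum", 2_443_126, 5),
    MockComponent("Rothia dentocariosa", 2_506_025, 3),
    MockComponent("Streptococcus oralis", 1_931_548, 4),
    MockComponent("Streptococcus mutans", 2_019_343, 5),
)
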