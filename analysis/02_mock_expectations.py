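#!/usr/bin/env python
"""Expected composition of the two mock communities, and observed deviations.

Equal DNA masses of five species do not give equal expected read fractions:
the model converts genome size to genomes per nanogram and multiplies by the
rrn copy number. This script writes both expectation tables and scores the
observed mock compositions reported for each sequencing platform against
them (the over-representation of Neisseria and the depletion of Actinomyces
are the headline deviations).
"""

from pathlib import Path

from amplipair.mock import (
    MOCK1_COMPONENTS,
    MOCK2_COMPONENTS,
    compare_to_expected,
    expected_composition,
)

OUT = Path("results/mock")

# observed relative abundances (%) of selected mock members as reported per
# platform in the benchmarking study
OBSERVED_MOCK1 = {
    "illumina": {"Neisseria sicca": 25.84, "Actinomyces oris": 5.47},
    "pacbio": {"Neisseria sicca": 42.55, "Actinomyces oris": 1.7},
}
OBSERVED_MOCK2 = {
    "illumina": {"Streptococcus mutans": 37.23},
    "pacbio": {"Streptococcus mutans": 68.9},
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, components, observed in (
        ("mock1", MOCK1_COMPONENTS, OBSERVED_MOCK1),
        ("mock2", MOCK2_COMPONENTS, OBSERVED_MOCK2),
    ):
        expectation = expected_composition(components)
        expectation.table.to_csv(OUT / f"{label}_expectation.tsv", sep="\t")
        print(f"{label} expected RA (%):")
        print(expectation.relative_abundance().round(2).to_string())
        for platform, obs in observed.items():
            table = compare_to_expected(obs, expectation)
            table.to_csv(OUT / f"{label}_{platform}_deviation.tsv", sep="\t")
            for name in obs:
                row = table.loc[name]
                print(
                    f"  {platform:8s} {name}: observed {row['observed']:.2f}%, "
                    f"expected {row['expected']:.2f}%, "
                    f"deviation {row['difference']:+.2f}"
                )


if __name__ == "__main__":
    main()
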