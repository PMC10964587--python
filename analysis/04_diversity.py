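#!/usr/bin/env python
"""Alpha diversity of the simulated paired study, per platform and niche.

Rarefies every sample to a common depth (default 4500 reads), computes
observed richness, Chao1 and Shannon at the feature (ASV-like) and genus
levels, writes per-sample tables, and prints platform means per niche with
a paired Wilcoxon p-value — the same summaries the platform comparison of
a real paired study reports.
"""

import argparse
from pathlib import Path

import pandas as pd

from amplipair import io
from amplipair.compare import paired_wilcoxon
from amplipair.diversity import aggregate_to_rank, alpha_diversity_table

SIM = Path("results/sim")
OUT = Path("results/diversity")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--depth", type=int, default=4500)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    OUT.mkdir(parents=True, exist_ok=True)
    metadata = io.read_metadata(SIM / "metadata.tsv")
    lineages = io.read_taxonomy_table(SIM / "reference_taxonomy.tsv")
    species_to_lineage = {lin.species: lin for lin in lineages.values()}
    by_sample = {m.sample_id: m for m in metadata}

    frames = []
    for platform in ("illumina", "pacbio"):
        table = io.read_count_table(SIM / f"counts_{platform}.tsv")
        for rank, t in (
            ("asv", table),
            ("genus", aggregate_to_rank(table, species_to_lineage, "genus")),
        ):
            alpha = alpha_diversity_table(t, depth=args.depth, seed=args.seed)
            alpha["platform"] = platform
            alpha["rank"] = rank
            alpha["niche"] = [by_sample[s].niche for s in alpha.index]
            alpha["subject"] = [by_sample[s].subject for s in alpha.index]
            frames.append(alpha)
    alpha = pd.concat(frames)
    alpha.to_csv(OUT / "alpha_diversity.tsv", sep="\t")

    for rank in ("asv", "genus"):
        sub = alpha[alpha["rank"] == rank]
        print(f"\n{rank}-level alpha diversity (rarefied to {args.depth}):")
        for niche in ("saliva", "subgingival", "faeces"):
            cell = sub[sub["niche"] == niche]
            wide = cell.pivot(index="subject", columns="platform", values="chao1").dropna()
            _, p = paired_wilcoxon(wide["illumina"], wide["pacbio"])
            means = cell.groupby("platform")[["chao1", "shannon"]].mean()
            print(
                f"  {niche:12s} chao1 I {means.loc['illumina', 'chao1']:6.1f} "
                f"P {means.loc['pacbio', 'chao1']:6.1f} (wilcoxon p={p:.3f})  "
                f"shannon I {means.loc['illumina', 'shannon']:.2f} "
                f"P {means.loc['pacbio', 'shannon']:.2f}"
            )
    print(f"\nwrote {OUT / 'alpha_diversity.tsv'}")


if __name__ == "__main__":
    main()
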