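# amplipair

Paired-platform 16S rRNA amplicon analysis: what changes when you sequence
the same microbiome samples with short reads covering the V3–V4
hypervariable window versus full-length (V1–V9) gene reads?

`amplipair` re-implements, as a tested library plus a small set of analysis
drivers, the analytical layer of such a comparison for human saliva,
subgingival plaque and faecal samples:

* **Mock-community expectation model.** Pooling equal DNA masses of several
  species does not give equal expected read fractions. For component *i*
  with genome size *gᵢ* (bp), rrn copy number *cᵢ* and input mass *mᵢ* (ng):

  massᵢ = gᵢ · w (w = 1.079×10⁻¹² ng/bp), copiesᵢ = cᵢ · mᵢ / massᵢ,
  RAᵢ = 100 · copiesᵢ / Σⱼ copiesⱼ.

* **Two-tier species assignment.** Exact full-sequence matches inherit the
  reference lineage; everything else goes through an 8-mer naive-Bayes
  genus classifier with bootstrap confidence (floor 80), and genus-assigned
  reads are aligned semi-globally against the whole database where the
  best hit's species is called only at ≥ 97% identity, 100% query coverage,
  and a > 2-point identity margin over the best hit of any other species.

* **Diversity and platform statistics.** Rarefaction (single seeded draw
  and the analytic hypergeometric curve), bias-corrected Chao1, Shannon
  (nats), Bray–Curtis distances, PCoA, seeded PERMANOVA (with an exhaustive
  mode for small *n*), paired Wilcoxon signed-rank tests with
  Benjamini–Hochberg adjustment, Spearman concordance of the top-20 taxa,
  and > 0.1% shared-taxon sets.

* **Synthetic paired-study generator.** A species-labelled reference with
  controlled identity structure (species-level differences concentrated
  outside the short-read window), mock read sets with truth labels, and a
  9-subject × 3-niche × 2-platform count-table study with known per-taxon
  platform bias — so every downstream claim is testable without downloads.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 0
python analysis/02_mock_expectations.py
python analysis/05_platform_comparison.py --seed 0
```

`02_mock_expectations.py` prints the copy-number-normalised expectation for
the five-species mock community and the deviation of the observed values:

```
mock1 expected RA (%):
Actinomyces oris           12.05
Fusobacterium nucleatum    26.19
Rothia dentocariosa        15.32
Streptococcus oralis       26.50
Neisseria sicca            19.94
  illumina Neisseria sicca: observed 25.84%, expected 19.94%, deviation +5.90
```

i.e. although each species contributed 1 ng, copy-number normalisation
predicts unequal proportions, and the observed mock composition
over-represents *Neisseria* by about six points on the short-read platform.

`05_platform_comparison.py` reports, on the simulated study:

```
PERMANOVA illumina-saliva vs illumina-subgingival    p = 0.001
PERMANOVA illumina-saliva vs pacbio-saliva           p = 0.788
saliva      : 9 pairs, 3 taxa q<0.05, 15/20 top taxa rho>0.8, shared>0.1%: 10 (unique I 0, P 0)
```

samples separate by body niche but not by sequencing platform, every taxon
above 0.1% mean abundance is detected by both platforms, most abundant taxa
are rank-concordant between platforms, and the three taxa simulated with a
factor-2 platform bias are exactly the ones flagged after BH correction.

The drivers run in order (01 writes the simulated study the others read)
and leave their tables under `results/`. A `amplipair` console script
exposes the same functionality as subcommands (`simulate`, `mock-expect`,
`mock-compare`, `classify`, `diversity`, `compare`).

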