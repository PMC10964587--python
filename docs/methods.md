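# Methods

## Mock-community expectation

A defined community pools equal DNA masses of member species. The expected
fraction of 16S amplicon reads per member is proportional to the number of
16S gene copies its DNA contributes: genomes per ng = input mass / (genome
size × w), with w = 1.079×10⁻¹² ng per base pair (mean mass of one
double-stranded bp), multiplied by the rrn copy number. All arithmetic is
kept at double precision; rounding happens only at printing. Comparisons
against published tables use "agreement at the printed number of
significant figures, last digit ± 1", because such tables mix rounding and
truncation (e.g. a mass per genome printed as 2.178E-06 where the product
computes to 2.1789E-06).

`compare_to_expected` reports observed − expected differences and ratios
per member, flagging names present on one side only (dropouts and putative
false positives such as a contaminant detected at 0.01%).

## Two-tier taxonomy assignment

1. **Exact tier.** A query identical, over its full length, to a reference
   sequence inherits that reference's complete lineage. Substring matches
   do not count: exactness keeps the tier deterministic.
2. **Naive-Bayes genus tier.** The classical rRNA word-matching model:
   per genus, the likelihood of each 8-mer is (n_g(w) + 0.5)/(N_g + 1)
   where n_g(w) counts reference sequences of genus g containing w and N_g
   counts sequences of g. A query is scored by the sum of log likelihoods
   over its distinct 8-mers; bootstrap confidence comes from 100 resamples
   of ⌈W/8⌉ of its W distinct words (drawn with replacement). Per-rank
   confidence is the percentage of bootstrap winners agreeing with the top
   genus at that rank, hence non-increasing with depth; the lineage is
   truncated at the deepest rank with confidence ≥ 80. Genera are sorted
   by name before scoring, so results do not depend on reference order and
   argmax ties resolve deterministically.
3. **Identity-gap species tier.** Genus-assigned queries are aligned
   against the whole reference database (a flag can restrict the search to
   the classified genus). Hits are kept at ≥ 97% identity and 100% query
   coverage; the best hit's species is called only when the best hit of
   any *other* species trails by more than 2 identity points. A tie at the
   top across species yields no call — "best match" is undefined under
   ties, and additional references of the *same* species never block a
   call. When the gap rule fires, the query adopts the winning reference's
   full lineage.

### Alignment

Semi-global dynamic programming: the query aligns end-to-end, gaps hanging
off either end of the reference are free (so a short amplicon scores
cleanly against a full-length gene). Scoring is pinned at match +1,
mismatch −1, gap −2. Identity is 100 × matches / alignment columns, where
columns include internal gaps but exclude the free reference overhangs;
coverage is 100 by construction. Among co-optimal alignments the traceback
prefers diagonal over query-gap over reference-gap moves and the rightmost
maximal end column, making the reported identity deterministic. The inner
loop is JIT-compiled (numba); a pure-Python full-matrix implementation of
the same model serves as an independent oracle in the tests.

## Diversity

* **Rarefaction** subsamples without replacement (multivariate
  hypergeometric). Index computation uses one draw at a fixed seed,
  mirroring common pipeline behaviour; the analytic expectation
  E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)), evaluated with log-gamma terms, is
  exposed where an expectation is wanted. The pipeline default depth is
  4500 reads; samples shallower than the target are skipped.
* **Chao1** uses the bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)), the
  default of the dominant community-ecology software.
* **Shannon** uses natural log (nats), same convention.
* **Rank aggregation** sums counts over features sharing a rank name;
  features unassigned at the rank pool under a reserved `Unassigned` row,
  so per-sample totals are preserved exactly.

## Platform comparison

* **Bray–Curtis** on per-sample proportions; distances live in
  `skbio.DistanceMatrix` containers.
* **PCoA**: eigendecomposition of the Gower-centred squared-distance
  matrix. Negative eigenvalues (non-Euclidean input) are reported verbatim
  — no Lingoes/Cailliez correction — and produce no axes; proportions
  explained are over positive eigenvalues.
* **PERMANOVA**: pseudo-F from within/total sums of squared distances;
  sampled mode draws seeded label permutations and uses the add-one
  p-value (count+1)/(B+1); exact mode enumerates all distinct label
  assignments (used for small-n validation). Subjects recur across niches
  but permutation is unrestricted (no strata) — a documented limitation.
  Pairwise contrasts are reported without multiplicity correction, with an
  optional BH flag.
* **Paired Wilcoxon** on relative abundances, pairs aligned by
  (subject, niche) across platforms; subjects missing one platform are
  dropped from that niche's test. Zero differences are dropped; the exact
  two-sided p (full sign-pattern enumeration) is used when ≤ 25 untied
  differences remain, otherwise the normal approximation with tie and
  continuity corrections. The degenerate all-zero case returns p = 1.
* **Benjamini–Hochberg** step-up q-values across taxa.
* **Spearman concordance**: taxa ranked by mean relative abundance pooled
  over both platforms (so selection favours neither); for the top 20, rho
  uses average ranks on ties.
* **Shared taxa**: a taxon counts as present on a platform when its mean
  relative abundance across that platform's samples within the niche
  exceeds 0.1% (per-niche by default; a flag computes it overall).

## Synthetic data generator

The generator emulates the *post-denoising* products of a paired-platform
study — ASV-style count tables, not raw reads; no chimeras, quality
scores, primers, or within-genome operon variation.

* **Reference.** One root gene (default 1450 bp); genus ancestors diverge
  from it and species diverge from their genus ancestor, substitutions
  only, so identity targets are analytic: two sequences independently
  mutated at per-site rate d from an ancestor agree at a site with
  probability (1−d)² + d²/3, and d is solved from the requested pairwise
  identity (defaults: 0.85 between genera, 0.975 within). Cross-genus
  pairs also carry species-level substitutions, so genus ancestors are
  mutated by the *difference* of the two divergences. Species-level
  substitutions land inside the short-read window (default [450, 870), a
  V3–V4-sized slice) only with probability 0.1 — this encodes the
  biological premise that congeneric species are nearly identical over a
  two-region window while remaining distinguishable over the full gene.
* **Mock reads**: multinomial draws from the copy-number-normalised
  expectation, i.i.d. substitutions at a configurable rate, complete truth
  labels.
* **Paired study.** Per niche, a base composition (log-normal weights,
  sigma 1.5, normalised). Per subject, a log-normal effect (sigma 0.8)
  shared by both platforms. Per library — i.e. per (sample, platform) — an
  independent log-normal technical effect (sigma 0.2) modelling PCR/prep
  variability, then per-taxon platform bias factors, renormalisation, and
  a multinomial draw at a Poisson-perturbed depth (means 100,000
  short-read, 12,500 long-read — the ~8× asymmetry of a typical paired
  design). One faecal subject is missing by default, giving
  2 × (9+9+8) = 52 samples. The technical layer matters: without it,
  sequencing-depth noise alone is so small at 10⁵ reads that the
  deterministic renormalisation shift induced by *any* bias makes every
  unbiased taxon significantly different between platforms, which no real
  paired study shows. All generators are deterministic under their seed.
* **What passing tests do not show.** Real amplicon data add primer and
  amplification bias structured by taxonomy, chimeras, contamination,
  overdispersion beyond log-normal, and a reference database that is
  incomplete for the community; recovery results on this generator
  therefore bound best-case behaviour of the statistics, not field
  performance.

## Validation scales and numerical choices

Oracle tests run the aligner against a brute-force DP (500 random pairs),
the exact Wilcoxon against full sign-pattern enumeration (all m ≤ 10),
PERMANOVA against exhaustive label enumeration (n = 6), PCoA against
distance reconstruction at 1e-9, and the gap rule against an independent
enumerator. Calibration uses 500 null PERMANOVA datasets (two groups of 9,
199 permutations; rejection rate checked against [0.03, 0.07]) and 1000 BH
replicates (100 p-values, 10 true effects; mean false-discovery proportion
≤ 0.07). Parameter recovery simulates 20 single-niche studies of 20
subjects at depth 10⁵ with a factor-2 bias on three mid-abundance taxa;
the biased taxa must carry the three smallest q-values in ≥ 90% of seeds,
and without bias ≥ 16 of the top-20 taxa must reach Spearman rho > 0.8 in
≥ 90% of seeds. Mid-abundance targets are deliberate: a factor-2 change on
a taxon near the depth floor is genuinely undetectable, and biasing the
dominant taxa shifts the whole composition enough (via renormalisation)
that unbiased taxa tie the biased ones at the exact-test p-value floor.
Species-resolution validation uses 500 error-free reads from the default
reference and their window slices; full-length reads must reach species
for ≥ 95% of reads and slices must stay strictly lower.
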