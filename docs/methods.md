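# Methods

## The subtyping procedure

The pipeline targets Illumina-450K-style β-values: per-probe methylated
signal fractions in [0,1] with a strongly bimodal marginal distribution.
The subtype discovery step is deliberately *reference-anchored*: instead
of clustering on raw variability, it first discards everything that is
methylated in normal tissue (β ≥ 0.3 in any normal), restricts to promoter
context (TSS1500, TSS200, 5′UTR, 1stExon), and keeps only probes whose
across-tumour SD exceeds 0.20. The surviving probes are *dichotomized* at
β ≥ 0.3 before clustering. Dichotomization plus the asymmetric-binary
(Jaccard) distance makes the procedure robust to tumour-purity dilution:
a probe's methylation only has to clear the 0.3 presence threshold, not
match in magnitude, and joint absence (the vast majority of cells in a
sparse binary matrix) carries no weight.

Thresholds are applied exactly as written: the normal filter and the SD
filter are strict (`<` 0.3, `>` 0.20), the dichotomization boundary is
presence (β = 0.3 → 1), and the LOH-contrast probe selection uses the
inclusive `SD ≥ 0.20` — the two SD conventions are kept separate because
they serve different selections.

### Ward clustering

Agglomeration is implemented in-package with the Lance–Williams Ward
update so both common variants are available and deterministic:

- `ward.D2` (default): the update runs on squared distances and merge
  heights are reported on the original distance scale. This treats the
  input distances as Euclidean and matches `scipy.cluster.hierarchy`
  (verified in the tests).
- `ward.D`: the update runs on the distances as given (verified against R
  `hclust(..., "ward.D")` in the tests).

Ties in merge cost are broken toward the lexicographically smallest
cluster-id pair; with continuous data ties are measure-zero, so partitions
are invariant to probe and sample order in practice. Degenerate all-absent
sample pairs get distance 0 (with a warning) so clustering stays total.
`k` is a configuration parameter (default 3); a silhouette scan over
k ∈ [2,6] is offered as a report only, never as an automatic override.

## Statistical machinery

- **Differential methylation**: per-probe two-sample *t*-tests, Welch by
  default (pooled variance is a config option), BH-adjusted **within each
  subgroup pair** (a pooled family is available), significant when
  *q* < 0.05 and |Δβ| ≥ 0.20. The inclusive effect-size boundary is the
  default and configurable; boundary cases are measure-zero on continuous
  data. Probes with zero variance and equal means in both groups get
  *p* = 1 rather than an undefined statistic.
- **Fisher tests**: 2×2 via the point-probability (two-sided) convention;
  the omnibus r×c test enumerates all tables with the observed margins
  (feasible for 3×2/3×3 at n ≤ 100; verified against R `fisher.test`).
  Categorical subgroup association defaults to one-vs-rest 2×2
  decompositions because per-subgroup enrichment is the quantity of
  interest; BH runs across the subgroup comparisons of one feature, never
  across features.
- **Rank-based tests**: Kruskal–Wallis with tie correction (all-identical
  input returns H = 0, p = 1 instead of erroring); pairwise rank-sum post
  hocs are exact (full enumeration) when both groups have ≤ 10
  observations and no ties, otherwise normal approximation with tie and
  continuity correction; BH across the pairs.
- **Expression**: CPM = counts/library·10⁶; a gene is "expressed" with
  ≥ 3 CPM in at least max(2, ⌊0.05·n⌋) samples — the floor of 2 reproduces
  a 2-sample threshold at a 47-sample cohort. TMM uses the published
  defaults (30% M-trim, 5% A-trim, precision weights, upper-quartile
  reference selection, geometric-mean-1 rescaling) and matches edgeR's
  `calcNormFactors` to machine precision on test fixtures. Methylation is
  correlated (Pearson, t-distributed p at df = n−2) with
  log₂(TMM-adjusted CPM + 1) over DM sites mapping to gene footprints of
  expressed genes, BH across all tested (probe, gene) pairs. The log
  transform and offset are package choices (configurable); numerically
  constant probes are skipped and logged.
- **Arm summaries**: length-weighted LOH fraction and length-weighted
  median logR per (sample, arm); weighted-median ties break toward the
  lower value. The LOH-vs-methylation contrast compares an explicitly
  named LOH-enriched subgroup against the rest per probe (rank-sum + BH)
  and in aggregate (per-sample mean β difference with a percentile
  bootstrap interval, 1000 resamples by default).
- **Islet signature**: signature probes are those whose α-like and β-like
  reference profiles differ by > 0.3 mean β; each tumour is scored
  mean|β − α| − mean|β − β-profile| and called by nearest profile (exact
  ties unclassified). This replaces a visual heat-map comparison with a
  deterministic rule; calls are invariant to adding non-signature probes.

## The synthetic cohort generator

The generator emulates the study conditions the pipeline is designed for:
11 normals and 90 tumours in three latent subgroups (30 each), 5000
probes, bimodal β drawn from two beta-distribution modes with means 0.1
and 0.8 and concentration 50 (chosen so a background probe stays below the
0.3 presence cutoff in all 11 normals with probability ≥ 0.99), 200
planted promoter DM probes per subgroup at a group-mean Δβ of 0.4, 5%
dichotomized-state flip noise on tumour cells, subgroup-dependent clinical
covariates, whole-arm LOH planted per subgroup (logR −0.3), 47 tumours
with RNA counts, and gene-expression linkage of |r| = 0.8 for half of the
DM genes with random sign.

Design points worth knowing:

- **Partial (subclonal) hypermethylation.** A planted probe is methylated
  in a target-subgroup sample with probability
  q = Δβ/(μ_high − μ_low) ≈ 0.57, as a per-(gene, sample) state shared by
  all of the gene's planted probes. This realizes the target group-mean
  Δβ = 0.4 exactly in expectation while keeping the planted probes' SD
  (≈ 0.28) above the 0.20 variability cut. A uniform shift of 0.4 in a
  one-third subgroup would give SD ≈ 0.19 and be removed by the cascade's
  own filter — i.e. the SD filter selects heterogeneously (partially)
  methylated probes, which is also the biologically expected pattern.
- **Balanced gene placement.** Every subgroup's j-th planted gene sits on
  the same chromosome, so on any chromosome subset the planted
  hyper/hypo-methylation contributions of "subgroup vs rest" cancel in
  expectation. This keeps arm LOH (planted independently) uncoupled from
  aggregate methylation differences by construction — the negative-control
  contrast is a real null, not a lucky one.
- **Clonal islet signature.** The cell-of-origin signature is a separate
  set of 150 intergenic probes methylated in *every* tumour of the
  islet-like subgroup (default T1 = β-like); it is intentionally not part
  of the subclonal DM structure and stays out of the promoter cascade.
- **Flip noise** applies to tumour cells only; normals stay clean so the
  normal-reference step of the cascade is deterministic.
- **LOH segments** are whole-arm (one segment per arm per tumour) with
  small logR jitter; no subclonal or partial-arm events.
- **Expression linkage** is linear in the gene's mean planted-probe β on
  the log2-CPM scale (amplitude 1.5, Gaussian residual scaled to hit the
  target correlation), converted to Poisson counts at library sizes of
  8–12 M. Poisson noise and the +1 log offset attenuate the realized
  per-probe correlation slightly below the 0.8 target, which the recovery
  tests account for by testing detection, not the correlation value.
- One global seed feeds a single generator stream in a fixed order
  (samples → probe layout → clinical → methylation → QC matrices →
  segments → expression); identical seeds give bit-identical cohorts and
  partial regeneration is deliberately unsupported.

### What the generator does *not* emulate

No probe-type (I/II) chemistry biases or normalization artefacts, no
batch effects, no genome-wide co-methylation/LD structure beyond the
per-gene state sharing, no detection-p physics (QC failures are planted
labels), no subclonal copy number, and no survival outcomes. Passing
tests therefore demonstrate that the implementation has the designed
operating characteristics under this idealized data model — not that the
biological conclusions of any particular cohort are correct.

## Problem sizes and numerical choices

Validation runs use cohorts of 5000–10,000 probes × ~100 samples and
20–50 simulation seeds per check, which gives stable Monte-Carlo
estimates of recovery rates (binomial SE ≲ 0.03) while keeping the whole
suite fast on a single CPU. Bootstrap intervals use 500–1000 resamples.
BH adjustment, Fisher 2×2, Kruskal–Wallis, rank-sum and the *t*-tests are
delegated to statsmodels/scipy behind the package's interfaces, with
independent brute-force oracles (step-up definition, hypergeometric
enumeration, agreement-category counting) exercised in the tests; Ward
clustering, TMM and the r×c exact test are implemented in-package and
cross-checked against scipy, edgeR and R `fisher.test` respectively.

## Known limitations

- Raw IDAT import, BMIQ/quantile normalization, batch assessment and
  correction (e.g. ComBat), read alignment and quantification are out of
  scope: the pipeline consumes normalized β matrices and gene-level
  counts.
- No moderated-variance (empirical-Bayes) DM testing and no region-level
  DMR calling; probes are tested independently.
- The exact Ward variant and tie-breaking of any particular historical
  analysis environment are not reproduced bit-for-bit; both variants are
  exposed and validated against reference implementations instead.
- The r×c exact Fisher enumerates tables and is exponential in table
  size; it is intended for small contingency tables (3×2/3×3, n ≤ ~100).
- Arm definitions ship as a config table (a synthetic 22-autosome layout
  by default); no genome-build lookup is performed.
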