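# Methods

## The LCV statistic

Expression variability is estimated per gene per tissue from a
genes × samples cpm matrix. Genes are sorted by their median cpm across
the tissue's samples (ties broken lexicographically by gene id, so all
scores are reproducible), and each gene's coefficient of variation
CV = s/x̄ is computed with the sample standard deviation (ddof = 1 by
default; configurable via `VariabilityParams.cv_ddof`).

For gene *i* in a frame of *n* genes with window size *m*, the window is
the half-open index range

```
start = clamp(i − ⌊(m−1)/2⌋, 0, max(n − m, 0));  end = start + min(m, n)
```

— centred in the interior, shifted inward at the two ends of the
expression scale so that it always contains exactly `min(m, n)` genes,
including gene *i*. If *m* exceeds the frame, the window degrades to one
global window with a logged warning (LCV then equals the global CV
percentile, mirroring what CV itself does in that limit).

Within the window, CVs receive average fractional ranks (ties share the
mean of their rank range) and

```
LCV_i = 100 · (r_i − 1) / (w − 1),   w = window size.
```

This convention gives exact endpoints — a strict window minimum scores
0, a strict maximum 100 — and 50 for a completely tied window. The
implementation slides a sorted window across the frame
(O(n·m) element moves, a few seconds for 30 000 genes at m = 10 000) and
is tested for exact equality against a brute-force oracle that builds and
ranks every window explicitly.

Properties that follow from the construction and are property-tested:
scores lie in [0, 100]; LCV is invariant to rescaling the cpm matrix and
to any strictly monotone transform applied uniformly to the CVs; the
mean LCV over a full interior window is near 50 (local detrending — the
test asserts within 2 percentile points at n = 5000, m = 500, where the
fluctuation is comfortably below that bound; at much smaller n/m the
fluctuation of this mean grows).

## Companion measures

* **SD, MAD** — per-gene sample standard deviation and unscaled median
  absolute deviation from the median, on cpm.
* **CV** — SD divided by the mean; genes with zero mean are excluded
  upstream by the expression mask (strict `cpm > threshold`).
* **DM** — the gene's CV minus the median CV of its window (same window
  convention as LCV).
* **EV** — the ratio of the observed CV to a smooth expectation given
  expression: a lowess fit of log CV on log median cpm with
  nearest-neighbor span `nn = 0.3`, EV = cv / exp(fit). This is a
  deliberate, simple re-implementation of the observed/expected idea —
  it fixes only the span parameter and claims no equivalence with any
  particular historical implementation of gamma-based expected
  variability.

Gene-level summaries used by the drug analyses take each gene's median
score across the tissues in which it is scored (mean-of-middle-two for
even counts).

## Preprocessing

Tissues are retained when they have at least 10 donors (after an
optional cause-of-death filter, used with post-mortem cohorts to keep
only trauma donors as healthy-tissue proxies). Genes with at most 10 raw
counts in **every** sample are removed before normalization — read as a
max-over-samples condition, which is the stricter and more
noise-targeted reading. TMM normalization factors are then computed: the
reference sample is the one whose 75th-percentile count fraction is
closest to the mean of those fractions; per sample, genes absent in
either member of the pair are dropped, M-values are trimmed two-sided by
0.30 and A-values by 0.05, the factor is the inverse-asymptotic-variance
weighted mean of the kept M-values, and factors are rescaled to
geometric mean 1. These are the canonical trim constants; the
implementation agrees with the Bioconductor reference implementation to
1e-6 on a frozen fixture (and to 12 digits in practice). cpm uses
effective library sizes: `cpm = count / (library_size × factor) × 1e6`.

By default TMM is computed jointly across the retained samples; a
per-tissue mode exists behind a flag (`--per-tissue-tmm`) since the
choice is not forced by anything in the data model. The robustness
benchmark normalizes within each donor subset, because the subset is the
entire dataset from the resampled pipeline's point of view.

The expression mask is computed per tissue on tissue-restricted cpm: a
gene enters the frame if its cpm is **strictly** above the threshold in
at least ⌈fraction × n⌉ samples (ceiling; fraction 0.8 by default).
Threshold 0 is the permissive mask used for measure comparisons;
threshold 7.0 is the stringent mask for analyses that need reliably
quantified genes.

## Evaluation harness

* **Expression bias** — Spearman correlation between score and median
  expression per tissue, plus the median over tissues. Unbiased measures
  sit near 0; SD/MAD near +1; CV is pushed negative by the
  mean-dispersion trend of counts.
* **Robustness to data incompleteness** — five donor subsets of
  ⌈50%⌉ of each tissue's samples, drawn without replacement from
  per-(tissue, subset) child seeds of one master seed (so adding tissues
  never perturbs existing subsets). The full pipeline (TMM, cpm, mask,
  frame, measure) is recomputed per subset; for each (gene, tissue)
  scored in all subsets, variation = sd/|mean| of the five scores; the
  pooled median over all genes and tissues summarizes the measure.
  |mean| is used because DM-like scores can be negative; genes with
  |mean| < 1e-12 are excluded and counted. Lower is more robust.
* **Window sensitivity** — pairwise Spearman correlations between LCV
  vectors computed at window sizes {10, 100, 500, 1000, 10000} on one
  frame.
* **Measure correlations** — per-tissue Spearman between LCV and each
  other measure over commonly scored genes.

## Drug-target analyses

Relative efficacy of a drug-disease pair is
`RE = 1 − n_ineffective / n_most_common_complaint`, in [0, 1], defined
only for pairs with at least 10 reports; a drug's RE is the median over
its RE-eligible indications. Each drug is summarized by its **most
variable target**: the maximum median-across-tissues LCV over its
targets, ties to the lexicographically first gene; drugs with no scored
target are excluded and counted.

The approved-versus-withdrawn contrast reports two-sided Mann-Whitney
(exact when both groups are ≤ 25 and tie-free, otherwise the normal
approximation with tie correction) and two-sided Kolmogorov-Smirnov
tests, group medians, the fraction of each group strictly above LCV 90,
and the upper-tail hypergeometric probability of the withdrawn drugs'
over-representation among the pooled set's high-LCV (> 90, strict)
drugs. Sidedness choices: the location tests are two-sided (no
directionality is assumed up front); the enrichment test is upper-tail
because it tests a stated direction. P-values are reported raw, with the
number of tests run; no multiple-testing correction is applied.

ATC level-1 stratification repeats the correlation and contrast within
each of the 14 anatomical groups having at least 10 complete
observations; drugs carrying several codes contribute to each.

Essentiality: per-gene median growth-impact score across cell lines is
negated (so larger = more essential); the top 10% (floor, ties broken by
gene id) are flagged essential; the association with variability is the
Spearman correlation between negated essentiality and median LCV.

Sex stratification keeps tissues with at least five donors of each sex,
drops X/Y genes, runs the whole pipeline separately per sex, and
compares each drug's max-target LCV between sexes (delta = female −
male; |delta| > 10 flags a drug). Samples whose sex label is neither
male nor female are retained in the data but excluded here.

Clustering of the gene × tissue LCV matrix is restricted to globally
expressed genes (scored in every tissue): genes by Ward linkage on raw
Euclidean distances (the ward.D2 convention), tissues by Ward linkage on
1 − Spearman correlation between tissue profiles; the gene tree is cut
into k = 3 clusters by default.

## Synthetic data generator

The generator emulates the *shape* of a multi-tissue bulk RNA-seq
cohort, not any particular dataset's empirical distributions:

* 19 tissues of 10–30 donors by default (~355 samples); donor sex
  assigned by a 50/50 split; ~5% of genes placed on chromosomes X/Y.
* Per-gene expected cpm ~ LogNormal(ln 10, 2.3) — spanning roughly four
  orders of magnitude; library sizes ~ LogNormal around 3 × 10⁷ with
  15% spread.
* Counts are negative binomial via gamma-Poisson with dispersion
  φ(μ) = φ₀ + φ₁/μ_cpm, jittered per gene by a LogNormal(0, 0.7)
  factor. φ₀ = 0.16 corresponds to a cross-donor biological CV of 0.4,
  typical of human tissue cohorts; φ₁ = 1.0 plants the decreasing
  mean-dispersion trend such data shows, sized so that the Spearman
  correlation between CV and median expression lands near −0.6 — the
  level real tissue RNA-seq exhibits. This trend is what gives the bias
  benchmark its signal.
* A planted fraction (10%) of high-variability genes has its dispersion
  multiplied by 6; these genes are drawn uniformly across the expression
  range so detecting them with LCV is not confounded with abundance.
* Drugs draw 1–5 targets; withdrawn drugs (1/6 of drugs) sample targets
  from the planted high-variability set with probability
  `withdrawn_bias`; ATC level-1 codes are uniform over the 14 groups.
* Outcome reports per (drug, disease): expected
  RE = clamp(base + slope · v/100, 0, 1) where *v* is the drug's
  max-target true-variability percentile (the rank of its planted
  dispersion); ineffective counts are binomial around it. For planted
  negative slopes the base is raised to 0.9 so the planted law stays
  inside the unit interval. Pairs under 10 reports are emitted but carry
  no RE.

Counts, drugs and reports use independent child seeds of the config
seed, so resizing one component leaves the others byte-identical.

What the generator does **not** emulate: per-tissue empirical expression
distributions, gene-gene correlation, batch or ischemic-time effects,
donor overlap between tissues, sequencing-run structure. Tests passing
on this generator therefore demonstrate the statistical machinery
(detrending, rank stability, planted-effect recovery), not robustness to
every artifact of real post-mortem cohorts.

## Problem sizes used by the test suite

The suite exercises the pipeline at sizes chosen to make each property
measurable while staying quick: the window-stability check uses one
30 000-gene, 30-donor tissue at GTEx-scale depth (5 × 10⁷), giving a
~29 000-gene frame; the bias check uses 15 000 genes; the robustness
ordering uses 600 genes × 20 donors × 3 tissues over 10 seeds with a
100-gene window (so the measure stays genuinely local on a ~500-gene
frame); planted-effect recovery uses 2 000 genes, 240 drugs (planted)
or 100 drugs (null) over 10 seeds each.

## Known limitations

* **Window-agreement ceiling.** The Spearman correlation between LCV
  vectors at different window sizes has an intrinsic sampling ceiling
  even with no mean-variability trend at all: a w-gene window estimates
  a percentile with binomial noise, giving r ≈ √((w−1)/(w+1)) against a
  much larger window (≈ 0.905 for w = 10) and ≈ 0.991 between windows
  100 and 1000 (measured on i.i.d. CVs). On synthetic frames with any
  genuinely mean-dependent dispersion the measured values land slightly
  below that ceiling (≈ 0.989 for the 100/500/1000 minimum, ≈ 0.89 for
  10 vs 10 000 on a ~29 000-gene frame), because the residual trend and
  the coupling between estimated median and estimated CV at 30 donors
  each shave a little off. Reported window-agreement numbers should be
  read with that ceiling in mind.
* EV here is a minimal observed/expected implementation; its absolute
  values depend on the lowess span and edge behavior, and only its
  ranking behavior is relied on.
* The exact Mann-Whitney branch is used only for tie-free groups of
  ≤ 25; with ties the tie-corrected normal approximation is used at any
  size.
* TMM assumes most genes are not differentially expressed between
  samples; grossly unbalanced synthetic compositions can violate this.
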