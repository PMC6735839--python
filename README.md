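# lcv — local coefficient of variation for gene expression

`lcv` measures how variably a gene is expressed across individuals and
asks whether that variability matters pharmacologically — for example,
whether drugs whose targets vary a lot between people tend to be less
effective in the population.

The classic dispersion statistics are confounded by expression level in
RNA-seq: SD grows with the mean, and CV = s/x̄ shrinks with it, so
ranking genes by either mostly ranks them by abundance. The **local
coefficient of variation (LCV)** removes this bias with a rank
construction. For each tissue, sort all genes by their median expression
and compute each gene's CV; then, for gene *g<sub>i</sub>*, take the
window of the *m* genes nearest to it on the expression scale (*m* = 500
by default; windows at the two ends of the scale are shifted inward so
they always hold *m* genes), and set

LCV(*g<sub>i</sub>*) = 100 · (r − 1) / (m − 1),

where *r* is the average fractional rank of CV(*g<sub>i</sub>*) among
the window's CVs. A gene scoring 0 is the least variable among genes of
similar abundance, a gene scoring 100 the most variable. Because it is a
rank statistic, LCV assumes no distribution for the variability, is
invariant to rescaling the data, and can be compared across expression
levels, tissues and datasets.

The package bundles:

- the companion measures **SD, CV, MAD, DM** (distance of a gene's CV
  from its window's median CV) and **EV** (ratio of a gene's CV to a
  local-regression expectation given its expression);
- **preprocessing**: tissue/donor selection, a raw-count noise filter,
  TMM normalization and counts-per-million conversion;
- an **evaluation harness**: expression-level bias, robustness to
  dropping half the donors, window-size sensitivity, cross-measure
  correlations;
- **drug-target analyses**: per-drug most-variable-target scores,
  relative-efficacy (RE) correlation, approved-versus-withdrawn
  contrasts (Mann-Whitney, Kolmogorov-Smirnov, hypergeometric
  enrichment above LCV 90), ATC level-1 stratification, gene
  essentiality association, sex-stratified comparison, and hierarchical
  clustering of the gene × tissue LCV matrix;
- a **synthetic data generator** producing GTEx-shaped negative-binomial
  count matrices with planted high-variability genes, plus drug tables
  and outcome-report tables with planted effects, so every analysis is
  testable without any external download.

## Worked example

Simulate three tissues of 20 donors, score variability, and relate drug
target variability to drug status and effectiveness. Here the generator
plants both effects: withdrawn drugs preferentially target
high-variability genes (`withdrawn_bias=0.8`) and expected RE declines
with target variability (`re_slope=-0.5`).

```python
import pandas as pd
from lcv import synthetic as sy
from lcv.datamodel import VariabilityParams
from lcv.preprocess import filter_low_count_genes, tmm_factors, to_cpm
from lcv.variability import compute_all, median_across_tissues
from lcv import drugs as dr

cfg = sy.SyntheticConfig(n_genes=3000, tissue_sizes=(20, 20, 20), seed=42,
                         n_drugs=150, withdrawn_bias=0.8,
                         re_slope=-0.5, re_base=0.9)
counts, meta, ann, truth = sy.simulate_counts(cfg)
counts = filter_low_count_genes(counts, 10)
cpm = {}
for t in meta.tissues():
    sub = counts.subset_samples(meta.samples_of(t))
    cpm[t] = to_cpm(sub, tmm_factors(sub), tissue=t)

table = compute_all(cpm, VariabilityParams(window_m=500), measures=("LCV",))
gene_lcv = median_across_tissues(table, "LCV")   # per-gene median over tissues

drugs = sy.simulate_drugs(cfg, truth)
true_var = truth.gene_dispersion.rank(pct=True) * 100
drug_var = pd.Series({d.drug_id: float(true_var[sorted(d.target_gene_ids)].max())
                      for d in drugs})
reports = sy.simulate_reports(cfg, drug_var)

scores, n_unscored = dr.drug_scores(drugs, gene_lcv, reports)
r, p, n = dr.re_lcv_correlation(scores)
c = dr.status_contrast(scores)
```

Output:

```
scored genes: 2725
drugs scored: 145 unscored: 5
RE vs max-target LCV: Spearman r = -0.46, p = 7.7e-09 (n = 145)
median max-target LCV: approved 76.4, withdrawn 96.0
Mann-Whitney p = 1.3e-06; KS p = 2.6e-06
fraction with LCV > 90: approved 0.25, withdrawn 0.71
hypergeometric enrichment p = 2.7e-05
```

Both planted effects are recovered: effectiveness falls as the most
variable target's LCV rises (negative Spearman r), and withdrawn drugs
sit higher on the LCV scale than approved ones by every test.

The same workflow is available from the shell:

```sh
lcv simulate --config config.txt --seed 42 --out sim/
lcv compute --counts sim/counts.tsv --meta sim/meta.tsv \
    --measures lcv,cv,dm --window 500 --out scores.tsv
lcv drugs --scores scores.tsv --drugs sim/drugs.tsv \
    --reports sim/reports.tsv --out drug_report/
lcv benchmark --counts sim/counts.tsv --meta sim/meta.tsv \
    --measures all --subsets 5 --fraction 0.5 --seed 17 --out bench/
```

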