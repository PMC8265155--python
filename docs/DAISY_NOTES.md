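# Notes on the DAISY-style comparator

The `baselines` module re-implements the DAISY data-mining protocol for
synthetic-lethality prediction as a comparator, restricted to the data
types this package handles (per-gene copy number and RNA-seq expression).
It is a faithful re-implementation of the published procedure's logic, not
a line-for-line port of any existing code, and it deviates from the
original protocol in the following documented ways.

## What is implemented

1. **Gene inactivation calls.** Gene A is called *inactive* in a cell line
   when its copy-number value falls below a loss threshold (default
   log2-ratio < −0.3) **and** its expression lies in the lowest decile
   (`loss_quantile`, default 0.1) of that gene's distribution. Genes with
   fewer than 2 inactive cell lines yield no predictions at all
   (`NotPredictableError`); they are absent from score tables, not
   zero-scored. This exclusion is the source of DAISY's reduced coverage
   relative to the clustering pipeline.
2. **Survival-of-the-fittest (SoF) component.** One-sided Wilcoxon
   rank-sum test that partner gene B's copy number is *higher* in
   A-inactive cell lines than in the remaining lines (cells that survive
   loss of A are enriched for retained/amplified B).
3. **Coexpression component.** Pearson correlation test between A and B
   expression across all cell lines.
4. **Combination.** Fisher's method over the two component p-values;
   the ranking score is −log10 of the combined p.

## Deviations from the original protocol

- **No shRNA essentiality component.** The original third procedure
  (underrepresentation of B knockdown in A-inactive lines from shRNA
  screens) requires an shRNA input this package does not model; the
  combination is therefore over two components, not three.
- **Loss-call threshold.** The exact copy-number threshold used for "loss"
  calls is a configurable parameter (default −0.3 on a log2 ratio scale)
  rather than a SNP-array-derived discrete call.
- **SoF on copy number only.** The SoF test is run on the partner's
  copy-number values; the original also considered expression-based
  variants. The expression axis enters through the coexpression component.

## The bimodality-gated surrogate

`bisep_surrogate_score` stands in for two-cluster, bimodality-gated
methods: gene A must pass a BIC gate (two-component mixture beating a
single Gaussian by ≥ 10 BIC units), cell lines split into the two
clusters, and the score is the difference of mean CRISPR scores between
the high- and low-expression groups. It reproduces that class of method's
*gating and scoring behaviour* — restricted coverage and fold-change
scores — not any specific published bimodality statistic (dip test,
kurtosis-based indices, etc.).
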