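# Methods

## The model

The package discovers candidate genetic dependency relationships (GDRs) —
gene pairs where the status of one gene modulates a cell's vulnerability
to perturbation of the other, synthetic lethality being the canonical
special case — from matched cell-line panels of RNA-seq expression, CRISPR
knockout essentiality (CERES-like scores: essential genes centre near −1,
non-essential near 0) and somatic mutation calls.

The central device is an unsupervised per-gene partition of the cell-line
panel. For each gene, expression values across cell lines are fitted with
univariate Gaussian mixtures by EM for every component count k ∈ {2, …, 5};
the Bayesian Information Criterion selects k. The one-component model is
deliberately never evaluated: a single cluster cannot support the
partition-based tests that follow, and genes whose expression is genuinely
unimodal simply yield a weak two-way split that carries little signal.
Components are relabelled so cluster 1 always has the lowest mean, and
every cell line receives a hard maximum-posterior assignment.

Two tests then run against the partition:

- **CRISPR dependency.** For a candidate pair (mRNA gene, CRISPR gene),
  CERES scores of the CRISPR gene are compared between *neighbouring*
  expression clusters (i, i+1) of the mRNA gene with a two-tailed Welch
  t-test. The effect is the difference of cluster means
  (mean(cluster i+1) − mean(cluster i)); the output column is named
  `log2FC` for compatibility with the results-table convention this format
  mirrors, but it is a difference, not a ratio — CERES scores are signed
  and centred near zero, so a fold ratio would be ill-defined. With k > 2
  every adjacent pair with ≥ 3 scored lines per side is tested and the
  smallest-p comparison is reported (ties broken toward larger |effect|);
  a verbose mode retains all comparisons, and an extreme-cluster (1 vs k)
  comparison is kept for reference. Screening keeps pairs with
  |effect| > 0.1 and p < 0.1.
- **Mutation dependency.** For a (mRNA gene, mutation gene) pair, a
  clusters × {wild-type, mutated} contingency table is tested with
  Pearson's chi-squared (no continuity correction); an optional `by_class`
  mode resolves variant classes, pooling classes with all expected counts
  < 1 into `other`. Screening keeps pairs with p < 0.05 and ≥ 5 mutated
  cell lines. A cell line with several records of one gene counts once,
  in `by_class` mode under its most deleterious class
  (nonsense/frameshift > splice > missense > in-frame > other). Wild-type
  labels reflect somatic calls only; undetected germline variants are a
  documented limitation, not something the test corrects.

q-values (Benjamini-Hochberg by default; Storey's π0-based estimate as an
option, π0 from a cubic fit over a λ grid of 0.05–0.95) are computed over
all tested pairs *within a scan scope* (one tissue, one run) before
threshold filtering, and never pooled across scopes.

For benchmarking, a pair's prediction score is −log10 p of its dependency
test; a pair covered by both tests keeps the larger score.

## Comparators

Two comparator methods calibrate performance and coverage claims (details
and deviations in `DAISY_NOTES.md`):

- a **DAISY-style predictor** (copy-number + expression inactivation
  calls, one-sided rank-sum survival-of-the-fittest test, coexpression
  test, Fisher combination), which emits nothing for genes lacking ≥ 2
  copy-number-loss cell lines;
- a **bimodality-gated surrogate** for two-cluster methods (two-component
  BIC gate at margin 10, CRISPR group-mean-difference score).

## Benchmarking protocol

Gold standards follow the database-intersection design: positives are
pairs from a SynLethDB-format score table above a confidence threshold
(0.7 high-confidence, 0.1 low-confidence) that have a prediction from the
evaluated method; negatives are resampled uniformly from the prediction
universe, excluding any pair present in the database at any score.
Balanced sets draw one negative per positive. Resampled negatives can
contain unannotated true pairs; true dependencies are rare enough that
this contamination is a small fraction, and on synthetic cohorts the
generator's truth ledger quantifies it exactly (planted pairs are excluded
from resampling, so it is zero there).

AUROC is computed as the normalised Mann–Whitney U (ties at half weight);
AUROC differences use DeLong's paired test, with a paired-bootstrap
cross-check. FDR at a score threshold is estimated after re-weighting the
two classes to a chosen prevalence (deterministic, the default) or
re-sampling to it (seed-controlled); the "real-world" prevalence default
of 0.0375 matches the frequency of negative genetic dependencies observed
in large-scale yeast genetic-interaction screens.

## Synthetic cohorts

The generator produces DepMap-shaped inputs whose statistical structure is
exactly what the tests assume, with every planted signal recorded in a
truth ledger:

- expression: per-gene Gaussian mixtures with planted k ∈ {2, 3, 4}
  (probabilities 0.5/0.3/0.2), component separation 6 sd, mixture weights
  floored at 0.15; 30% of non-planted genes are generated with separation
  1 sd ("weak" genes) to mimic the near-unimodal expression that dominates
  real panels and to exercise bimodality gating;
- CRISPR: per-gene baselines at −1 (20% essential genes) or 0 with noise
  sd 0.2, echoing the CERES convention; planted pairs shift the partner's
  score down by the effect size (default 1.0) in the mRNA gene's
  lowest-expression cluster;
- mutations: Bernoulli per (line, gene) at marginal rate 0.15; planted
  exclusivity pairs depress the mutation gene's log-odds by 3.0 in the
  partner's low cluster;
- copy number: Gaussian noise (sd 0.1) around 0, with ~5% of lines deleted
  (−0.8) for half the genes — deletions placed in each gene's
  lowest-expression lines so inactivation calls are coherent; the other
  half of genes have no losses, which drives the DAISY coverage gap;
- protein: expression plus Gaussian noise targeting a configurable
  mRNA–protein correlation (default 0.8);
- tissues: one fixed 40-line tissue (for tissue-subset tests) plus evenly
  spread remaining groups; tissue-specific planted pairs confine the
  CRISPR shift to the fixed tissue.

The default cohort is 400 cell lines × 200 genes over 10 tissues with five
planted CRISPR pairs and five planted mutation pairs — large enough that
the scans are well powered and null calibration can be measured on
thousands of pairs, small enough that a full generate–cluster–scan cycle
runs in about a minute on one CPU. What the generator does *not* emulate:
gene–gene correlation beyond the planted pairs, copy-number segment
structure, mutational hotspots, or germline variation — so green tests
demonstrate correctness of the machinery and calibration under the model's
own assumptions, not performance on real DepMap data.

## Numerical choices

- EM: k-means++ seeding, 10 restarts per k (best final log-likelihood
  kept), per-component variances floored at 1e-4 × the gene's total
  variance, convergence at relative log-likelihood change < 1e-8 or 500
  iterations. The inner loop is compiled with numba when available, with
  an equivalent vectorised numpy path otherwise; both are exact (no
  fast-math reassociation), so results are bit-reproducible for a given
  seed.
- BIC = −2·loglik + p·log n with p = 3k − 1; lower is better; ties across
  k break toward the smaller k. Posterior ties in assignment break toward
  the lower-mean cluster; component ordering ties (equal means) break by
  weight, then original index, making the canonical ordering total.
- Cell lines with missing expression for a gene are excluded from that
  gene's model and all downstream tests involving it; missing CRISPR
  entries are dropped per comparison (explicitly counted, never imputed
  as zero).
- Degenerate inputs: constant (or near-constant) expression raises a
  specific error rather than producing an arbitrary split; scans skip and
  report such genes.
- All randomness flows from one user-visible seed per invocation, fanned
  out through `numpy.random.SeedSequence` so per-gene fits are independent
  of which other genes are present.

## Design choices where the design was open

- **Which comparison to report for k > 2:** all adjacent pairs are tested
  and the minimum-p row reported. Minimum-p matches the screening intent
  (any neighbouring-cluster shift is a candidate); the selection does make
  the *reported* per-pair p anti-conservative under the null, which is why
  null-calibration checks run on the verbose all-comparisons output while
  screening uses the selected row.
- **Contingency structure:** binary (wild-type vs mutated) is the default;
  `by_class` reproduces class-resolved enrichment literally. Binary is the
  more powerful test for the exclusivity signature and keeps expected
  counts healthy.
- **q-value method:** BH is the default; Storey is available. BH is the
  conservative, assumption-light choice.
- **AUROC comparison test:** DeLong's paired test, with a bootstrap
  cross-check flag, since the two score sets are evaluated on the same
  gold pairs.
- **Welch rather than pooled t:** cluster sizes and variances are
  routinely unequal between expression clusters.
- **No GO ancestor propagation** in shared-term counting: annotation files
  typically already include high-level terms, which makes the GO filter
  permissive as-is; propagation is left to the annotation file supplied.

## Limitations

- The reported CRISPR row's p-value is the minimum over adjacent
  comparisons (see above); treat the q-value as a screening rank, not a
  calibrated error rate, when k > 2.
- Chi-squared is asymptotic; tables with expected counts < 5 in > 20% of
  cells are flagged (and counted per scan) but still tested, never
  switched to an exact test.
- The expression loader applies no filtering; near-constant genes fail
  with a clear error, and a minimum-variance pre-filter is available as an
  option rather than a default.
- Synthetic benchmarks validate machinery and calibration; absolute AUROC,
  coverage folds or pair counts on real DepMap/SynLethDB releases depend
  on those releases and are out of scope.
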