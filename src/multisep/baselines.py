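"""Comparator methods: a DAISY-style predictor and a bimodality-gated surrogate.

The DAISY-style predictor follows the published data-mining protocol
restricted to copy number and expression: gene A is called *inactive* in a
cell line when its copy number shows a loss (log2 ratio below a threshold)
AND its expression falls in the lowest decile. Genes inactive in fewer than
2 cell lines yield no prediction at all — they are absent from the output,
not zero-scored, which is the source of DAISY's lower coverage. For an
(A, B) pair, a one-sided rank-sum "survival of the fittest" test asks
whether B's copy number (or expression) is higher in A-inactive lines than
in the rest, a Pearson correlation test measures A-B coexpression, and the
two component p-values combine by Fisher's method into a single
score = -log10(combined p). The shRNA-essentiality component of the
original protocol is omitted (no shRNA input in scope).

The bimodal surrogate reproduces the behaviour of two-cluster,
bimodality-gated methods: gene A must pass a bimodality gate (a
two-component mixture beating one component by a BIC margin); cell lines
then split into the two clusters and the score is the CRISPR fold-change
(difference of group means) for gene B. It emulates that class of method's
gating and scoring, not any specific bimodality statistic. See
docs/DAISY_NOTES.md for deviations from the original protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NotPredictableError
from .io import Dataset

logger = logging.getLogger(__name__)


@dataclass
class BaselineScore:
    """A comparator's ranking score for one gene pair (higher = more dependent)."""

    gene_a: str
    gene_b: str
    method: str
    score: float
    components: dict


def _one_gauss_loglik(x: np.ndarray) -> float:
    var = max(x.var(), 1e-12)
    return float(-0.5 * len(x) * (np.log(2 * np.pi * var) + 1.0))


def daisy_inactive_mask(
    gene: str,
    copy_number: pd.DataFrame,
    expression: pd.DataFrame,
    loss_threshold: float = -0.3,
    loss_quantile: float = 0.1,
    min_lines: int = 2,
) -> pd.Series:
    """Boolean mask of cell lines where ``gene`` is called inactive.

    Inactive = copy-number value below ``loss_threshold`` AND expression in
    the lowest ``loss_quantile`` of that gene's distribution. Raises
    ``NotPredictableError`` when fewer than ``min_lines`` lines show a
    copy-number loss, or when fewer than ``min_lines`` satisfy both calls.
    """
    if gene not in copy_number.columns or gene not in expression.columns:
        raise NotPredictableError(f"gene {gene!r} missing from copy number or expression")
    cn = copy_number[gene]
    expr = expression[gene].reindex(cn.index)
    loss = cn < loss_threshold
    if int(loss.sum()) < min_lines:
        raise NotPredictableError(
            f"gene {gene!r}: copy-number losses in {int(loss.sum())} cell lines < {min_lines}"
        )
    low_expr = expr <= expr.quantile(loss_quantile)
    mask = loss & low_expr
    if int(mask.sum()) < min_lines:
        raise NotPredictableError(
            f"gene {gene!r}: only {int(mask.sum())} lines are both lost and low-expressed"
        )
    return mask


def daisy_pair_score(
    a: str,
    b: str,
    dataset: Dataset,
    loss_threshold: float = -0.3,
    loss_quantile: float = 0.1,
) -> BaselineScore:
    """DAISY-style score for the pair (A, B).

    components: ``sof_p`` — one-sided rank-sum p that B's copy number is
    higher in A-inactive lines (survival of the fittest); ``coexpr_p`` —
    Pearson correlation test p between A and B expression; ``combined_p`` —
    Fisher's combination. score = -log10(combined p).
    """
    if a == b:
        raise NotPredictableError("self-pairs are rejected")
    if dataset.copy_number is None:
        raise NotPredictableError("dataset has no copy-number matrix")
    mask = daisy_inactive_mask(
        a, dataset.copy_number, dataset.expression,
        loss_threshold=loss_threshold, loss_quantile=loss_quantile,
    )
    if b not in dataset.copy_number.columns or b not in dataset.expression.columns:
        raise NotPredictableError(f"gene {b!r} missing from copy number or expression")
    b_cn = dataset.copy_number[b].reindex(mask.index)
    inactive = b_cn[mask].dropna().to_numpy()
    rest = b_cn[~mask].dropna().to_numpy()
    if len(inactive) < 2 or len(rest) < 2 or (np.ptp(b_cn.dropna()) == 0):
        raise NotPredictableError(f"gene {b!r}: degenerate copy-number values")
    sof_p = float(sps.mannwhitneyu(inactive, rest, alternative="greater").pvalue)

    ea = dataset.expression[a]
    eb = dataset.expression[b].reindex(ea.index)
    ok = ea.notna() & eb.notna()
    if ok.sum() < 3 or ea[ok].std() == 0 or eb[ok].std() == 0:
        raise NotPredictableError(f"pair ({a},{b}): degenerate expression values")
    coexpr = sps.pearsonr(ea[ok], eb[ok])
    coexpr_p = float(coexpr.pvalue)

    combined = sps.combine_pvalues([sof_p, coexpr_p], method="fisher")
    combined_p = float(combined.pvalue)
    return BaselineScore(
        gene_a=a, gene_b=b, method="daisy",
        score=float(-np.log10(max(combined_p, 1e-300))),
        components={
            "sof_p": sof_p,
            "coexpr_p": coexpr_p,
            "coexpr_r": float(coexpr.statistic),
            "combined_p": combined_p,
            "n_inactive": int(mask.sum()),
        },
    )


def bimodality_gate(
    values: pd.Series | np.ndarray, bic_margin: float = 10.0, seed: int = 0
) -> pd.Series:
    """Two-cluster split of a gene's expression, gated on clear bimodality.

    A two-component mixture must beat the single-Gaussian fit by at least
    ``bic_margin`` BIC units; otherwise ``NotPredictableError``. Returns a
    cell-line -> {1, 2} assignment with group 1 = lower mean.
    """
    from .clustering import fit_gene_mixture

    if isinstance(values, pd.Series):
        x = values.dropna()
    else:
        x = pd.Series(np.asarray(values, dtype=float)).dropna()
    model = fit_gene_mixture(x, k_min=2, k_max=2, seed=seed)
    bic1 = -2.0 * _one_gauss_loglik(x.to_numpy(dtype=float)) + 2.0 * np.log(len(x))
    if bic1 - model.bic_by_k[2] < bic_margin:
        raise NotPredictableError(
            f"bimodality gate failed (BIC margin {bic1 - model.bic_by_k[2]:.2f} < {bic_margin})"
        )
    return model.assignments


def bisep_surrogate_score(
    a: str,
    b: str,
    dataset: Dataset,
    bic_margin: float = 10.0,
    min_group: int = 3,
    seed: int = 0,
) -> BaselineScore:
    """Bimodality-gated two-group CRISPR fold-change score for the pair (A, B).

    score = mean CRISPR score of B in A's high-expression group minus its
    mean in A's low-expression group (difference of group means).
    """
    if a == b:
        raise NotPredictableError("self-pairs are rejected")
    if dataset.crispr is None:
        raise NotPredictableError("dataset has no CRISPR matrix")
    if a not in dataset.expression.columns:
        raise NotPredictableError(f"gene {a!r} missing from expression")
    if b not in dataset.crispr.columns:
        raise NotPredictableError(f"gene {b!r} missing from CRISPR matrix")
    assignments = bimodality_gate(dataset.expression[a], bic_margin=bic_margin, seed=seed)
    scores = dataset.crispr[b]
    lo = scores.reindex(assignments.index[assignments == 1]).dropna()
    hi = scores.reindex(assignments.index[assignments == 2]).dropna()
    if len(lo) < min_group or len(hi) < min_group:
        raise NotPredictableError("a two-cluster group is too small to compare")
    effect = float(hi.mean() - lo.mean())
    return BaselineScore(
        gene_a=a, gene_b=b, method="bisep_surrogate", score=effect,
        components={"n_lo": int(len(lo)), "n_hi": int(len(hi))},
    )


def score_pairs(
    pairs: list[tuple[str, str]],
    dataset: Dataset,
    method: str,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Score a list of gene pairs with one comparator; unpredictable pairs are absent.

    Returns columns gene_a, gene_b, method, score plus component columns.
    """
    scorer = {"daisy": daisy_pair_score, "bisep": bisep_surrogate_score}[method]
    rows = []
    n_skipped = 0
    for a, b in pairs:
        try:
            if method == "bisep":
                res = scorer(a, b, dataset, seed=seed, **kwargs)
            else:
                res = scorer(a, b, dataset, **kwargs)
        except NotPredictableError:
            n_skipped += 1
            continue
        rows.append({"gene_a": res.gene_a, "gene_b": res.gene_b,
                     "method": res.method, "score": res.score, **res.components})
    if n_skipped:
        logger.info("%s emitted no prediction for %d/%d pairs", method, n_skipped, len(pairs))
    return pd.DataFrame(rows)
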