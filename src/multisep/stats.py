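"""Statistical primitives shared by the dependency tests and benchmarking.

Welch's t-test is implemented directly from the unequal-variance formula so
it vectorises over many genes at once; q-values offer both Benjamini-
Hochberg step-up adjustment and Storey's pi0-based estimate; AUROC is the
normalised Mann-Whitney U statistic (ties counted half); AUROC differences
are compared with DeLong's paired test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def welch_ttest(
    n1: np.ndarray, m1: np.ndarray, v1: np.ndarray,
    n2: np.ndarray, m2: np.ndarray, v2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-tailed Welch t-test from summary statistics (vectorised).

    ``v1``/``v2`` are unbiased sample variances. Returns (t, df, p) with
    the Welch-Satterthwaite degrees of freedom. Zero pooled variance gives
    p = 1 when the means agree and p = 0 otherwise.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    se1, se2 = v1 / n1, v2 / n2
    denom = se1 + se2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(denom)
        df = denom**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    zero = denom == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero, np.where(m1 == m2, 0.0, np.inf * np.sign(m2 - m1)), t)
    df = np.where(zero | ~np.isfinite(df), 1.0, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, np.clip(p, 0.0, 1.0)


def welch_from_samples(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t-test on two samples; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df, p = welch_ttest(
        len(x), x.mean(), x.var(ddof=1), len(y), y.mean(), y.var(ddof=1)
    )
    return float(t), float(df), float(p)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    _check_unit(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def storey_qvalues(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with pi0 estimated on a lambda grid (0.05..0.95).

    pi0 is estimated by a cubic fit of pi0_hat(lambda) evaluated at the
    largest lambda, clamped to (0, 1]; with fewer than 4 grid points the
    plain estimate at the largest lambda is used.
    """
    p = np.asarray(pvals, dtype=float)
    _check_unit(p)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_hat = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if len(lambdas) >= 4:
        coeffs = np.polyfit(lambdas, pi0_hat, 3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    else:
        pi0 = float(pi0_hat[-1])
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compute_qvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: ``method`` is "bh" or "storey"."""
    if method == "bh":
        return bh_qvalues(pvals)
    if method == "storey":
        return storey_qvalues(pvals)
    raise ValueError(f"unknown q-value method {method!r}")


def _check_unit(p: np.ndarray) -> None:
    if len(p) and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the normalised Mann-Whitney U; tied scores count 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC curve points (fpr, tpr) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.where(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / y.sum()]
    fpr = np.r_[0.0, fps / (~y).sum()]
    return np.column_stack([fpr, tpr])


def _midrank_structure(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive), V01 (per negative), and AUC."""
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.r_[pos, neg])
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """DeLong paired two-tailed test for the AUROC difference.

    Both score vectors must be aligned to the same ``labels``. Returns
    (auc_a, auc_b, p). A zero-variance difference (e.g. identical scores)
    yields p = 1.
    """
    labels = np.asarray(labels, dtype=bool)
    a_pos, a_neg = np.asarray(scores_a, float)[labels], np.asarray(scores_a, float)[~labels]
    b_pos, b_neg = np.asarray(scores_b, float)[labels], np.asarray(scores_b, float)[~labels]
    v10a, v01a, auc_a = _midrank_structure(a_pos, a_neg)
    v10b, v01b, auc_b = _midrank_structure(b_pos, b_neg)
    m, n = len(a_pos), len(a_neg)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return auc_a, auc_b, float(2.0 * sps.norm.sf(abs(z)))


def bootstrap_auroc_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Paired bootstrap two-tailed p-value for an AUROC difference."""
    rng = np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, bool)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.r_[rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        diffs[i] = auroc(scores_a[idx], labels[idx]) - auroc(scores_b[idx], labels[idx])
    observed = auroc(scores_a, labels) - auroc(scores_b, labels)
    se = diffs.std(ddof=1)
    if se == 0:
        return 1.0
    z = observed / se
    return float(2.0 * sps.norm.sf(abs(z)))
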