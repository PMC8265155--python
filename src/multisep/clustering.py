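"""Per-gene Gaussian-mixture partitioning of cell-line expression.

Each gene's expression profile across cell lines is fitted with univariate
Gaussian mixtures by Expectation-Maximization for every component count k in
[2, 5]; the Bayesian Information Criterion selects k. Unimodal (k = 1) models
are never evaluated: downstream dependency tests require a partition, and a
single cluster cannot support one. Components are relabelled in ascending
order of mean so that cluster 1 is always the lowest-expression group, and
every cell line with a finite expression value receives a hard
maximum-posterior cluster assignment.

BIC convention used throughout: ``BIC = -2*loglik + p*log(n)`` with
``p = 3k - 1`` free parameters (k means, k variances, k-1 weights); lower is
better. Ties across k are broken toward the smaller (more parsimonious) k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeneError,
    InsufficientDataError,
    TissueTooSmallError,
)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _em_run_jit(x, means0, var0, w0, var_floor, tol, max_iter):  # pragma: no cover
    """Single-restart EM inner loop (compiled); returns (ll, means, var, w)."""
    n = x.shape[0]
    k = means0.shape[0]
    means = means0.copy()
    var = var0.copy()
    w = w0.copy()
    resp = np.empty((n, k))
    const = np.empty(k)
    inv2v = np.empty(k)
    log2pi = np.log(2.0 * np.pi)
    prev_ll = -np.inf
    for _ in range(max_iter):
        for j in range(k):
            const[j] = -0.5 * (log2pi + np.log(var[j])) + np.log(w[j])
            inv2v[j] = 0.5 / var[j]
        ll = 0.0
        for i in range(n):
            mx = -1e308
            for j in range(k):
                d = x[i] - means[j]
                lp = const[j] - d * d * inv2v[j]
                resp[i, j] = lp
                if lp > mx:
                    mx = lp
            s = 0.0
            for j in range(k):
                s += np.exp(resp[i, j] - mx)
            ln = mx + np.log(s)
            ll += ln
            for j in range(k):
                resp[i, j] = np.exp(resp[i, j] - ln)
        for j in range(k):
            nk = 0.0
            mu = 0.0
            for i in range(n):
                nk += resp[i, j]
                mu += resp[i, j] * x[i]
            if nk < 1e-300:
                nk = 1e-300
            mu /= nk
            v = 0.0
            for i in range(n):
                d = x[i] - mu
                v += resp[i, j] * d * d
            v /= nk
            if v < var_floor:
                v = var_floor
            w[j] = nk / n
            means[j] = mu
            var[j] = v
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    for j in range(k):
        const[j] = -0.5 * (log2pi + np.log(var[j])) + np.log(w[j])
        inv2v[j] = 0.5 / var[j]
    ll = 0.0
    for i in range(n):
        mx = -1e308
        for j in range(k):
            d = x[i] - means[j]
            lp = const[j] - d * d * inv2v[j]
            resp[i, j] = lp
            if lp > mx:
                mx = lp
        s = 0.0
        for j in range(k):
            s += np.exp(resp[i, j] - mx)
        ll += mx + np.log(s)
    return ll, means, var, w


@dataclass
class ClusterModel:
    """A fitted per-gene mixture with canonically ordered components.

    ``assignments`` maps cell line -> 1-based cluster index; cluster 1 has
    the lowest mean. ``bic_by_k`` records every evaluated component count.
    """

    gene: str
    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    assignments: pd.Series
    bic_by_k: dict[int, float]
    n_cells: int

    def cluster_members(self, cluster: int) -> pd.Index:
        """Cell lines assigned to a given 1-based cluster index."""
        return self.assignments.index[self.assignments == cluster]


def _log_gauss(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    # x: (n,), mean/var: (k,) -> (n, k)
    d = x[:, None] - mean[None, :]
    return -0.5 * (_LOG2PI + np.log(var)[None, :] + d * d / var[None, :])


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on a 1-D sample; returns k initial centres."""
    centres = [x[rng.integers(len(x))]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.asarray(centres)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:  # all points coincide with a centre
            centres.append(x[rng.integers(len(x))])
            continue
        centres.append(x[rng.choice(len(x), p=d2 / total)])
    return np.asarray(centres, dtype=float)


def _em_best_of_restarts(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    var_floor: float,
    tol: float,
    max_iter: int,
    n_restarts: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM from ``n_restarts`` k-means++ seedings in parallel (batched).

    With numba available each restart runs through the compiled inner loop;
    otherwise all restarts iterate together as (R, n, k) arrays, stopping
    when every restart's relative log-likelihood change falls below ``tol``.
    Either way the restart with the best final log-likelihood wins.
    """
    n = len(x)
    means = np.stack([_kmeanspp_init(x, k, rng) for _ in range(n_restarts)])
    if _HAVE_NUMBA:
        var0 = np.full(k, max(x.var(), var_floor))
        w0 = np.full(k, 1.0 / k)
        best = None
        for r in range(n_restarts):
            ll, mu, var, w = _em_run_jit(x, means[r], var0, w0, var_floor, tol, max_iter)
            if best is None or ll > best[0]:
                best = (float(ll), mu, var, w)
        return best
    variances = np.full((n_restarts, k), max(x.var(), var_floor))
    weights = np.full((n_restarts, k), 1.0 / k)
    prev_ll = np.full(n_restarts, -np.inf)
    xb = x[None, :, None]  # (1, n, 1)
    for _ in range(max_iter):
        d2 = (xb - means[:, None, :]) ** 2
        log_p = (
            -0.5 * (_LOG2PI + np.log(variances)[:, None, :] + d2 / variances[:, None, :])
            + np.log(weights)[:, None, :]
        )
        m = log_p.max(axis=2, keepdims=True)
        log_norm = m[..., 0] + np.log(np.exp(log_p - m).sum(axis=2))  # (R, n)
        ll = log_norm.sum(axis=1)
        resp = np.exp(log_p - log_norm[..., None])  # (R, n, k)
        nk = np.maximum(resp.sum(axis=1), 1e-300)
        weights = nk / n
        means = (resp * xb).sum(axis=1) / nk
        variances = np.maximum(
            (resp * (xb - means[:, None, :]) ** 2).sum(axis=1) / nk, var_floor
        )
        converged = np.isfinite(prev_ll) & (np.abs(ll - prev_ll) <= tol * np.abs(prev_ll))
        if converged.all():
            break
        prev_ll = ll
    d2 = (xb - means[:, None, :]) ** 2
    log_p = (
        -0.5 * (_LOG2PI + np.log(variances)[:, None, :] + d2 / variances[:, None, :])
        + np.log(weights)[:, None, :]
    )
    m = log_p.max(axis=2, keepdims=True)
    ll = (m[..., 0] + np.log(np.exp(log_p - m).sum(axis=2))).sum(axis=1)
    best = int(np.argmax(ll))
    return float(ll[best]), means[best], variances[best], weights[best]


def _canonical_order(means, variances, weights):
    """Total ordering: ascending mean, ties broken by weight then index."""
    order = np.lexsort((np.arange(len(means)), weights, means))
    return means[order], variances[order], weights[order]


def fit_gene_mixture(
    values: pd.Series | np.ndarray,
    k_min: int = 2,
    k_max: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
    var_floor_frac: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 500,
    gene: str = "",
) -> ClusterModel:
    """Fit mixtures for k in [k_min, k_max] and keep the BIC-optimal one.

    ``values`` may carry a cell-line index (pandas Series); otherwise
    positional indices are used. Cell lines with non-finite values are
    excluded from the fit and receive no assignment.

    Raises ``InsufficientDataError`` with fewer than ``k_max + 1`` finite
    values and ``DegenerateGeneError`` on (near-)constant input.
    """
    if isinstance(values, pd.Series):
        index = values.index
        x_all = values.to_numpy(dtype=float)
    else:
        x_all = np.asarray(values, dtype=float)
        index = pd.RangeIndex(len(x_all))
    finite = np.isfinite(x_all)
    x = x_all[finite]
    if len(x) < k_max + 1:
        raise InsufficientDataError(
            f"gene {gene!r}: {len(x)} finite values < required {k_max + 1}"
        )
    total_var = float(x.var())
    if total_var < 1e-12 * max(1.0, abs(float(x.mean()))) or np.ptp(x) == 0:
        raise DegenerateGeneError(f"gene {gene!r}: expression is (near-)constant")
    var_floor = var_floor_frac * total_var

    rng = np.random.default_rng(seed)
    best = None
    bic_by_k: dict[int, float] = {}
    n = len(x)
    for k in range(k_min, k_max + 1):
        best_ll, mu, var, w = _em_best_of_restarts(
            x, k, rng, var_floor, tol, max_iter, n_restarts
        )
        best_params = (mu, var, w)
        p_free = 3 * k - 1
        bic = -2.0 * best_ll + p_free * np.log(n)
        bic_by_k[k] = float(bic)
        # strict '<' keeps the smallest k on ties (parsimony)
        if best is None or bic < best[0]:
            best = (bic, k, best_params)

    _, k, (mu, var, w) = best
    mu, var, w = _canonical_order(mu, var, w)

    log_post = _log_gauss(x, mu, var) + np.log(w)[None, :]
    # argmax returns the first (lowest-mean) cluster on exact posterior ties
    labels = np.argmax(log_post, axis=1) + 1
    assignments = pd.Series(labels, index=index[finite], dtype=int)

    return ClusterModel(
        gene=gene,
        k=k,
        means=mu,
        variances=var,
        weights=w,
        assignments=assignments,
        bic_by_k=bic_by_k,
        n_cells=n,
    )


def cluster_all_genes(
    expression: pd.DataFrame,
    tissues: pd.Series | None = None,
    tissue_subset: str | None = None,
    seed: int = 0,
    min_tissue_lines: int = 10,
    **fit_kwargs,
) -> tuple[dict[str, ClusterModel], dict[str, str]]:
    """Fit one mixture per gene; returns (models, failures-with-reason).

    With ``tissue_subset`` the expression matrix is first restricted to that
    tissue's cell lines; fewer than ``min_tissue_lines`` raises
    ``TissueTooSmallError``. Per-gene seeds are derived deterministically
    from ``seed`` and the gene's column position, so results do not depend
    on which other genes are present.
    """
    if tissue_subset is not None:
        if tissues is None:
            raise ValueError("tissue_subset requires a tissue annotation")
        lines = tissues.index[tissues == tissue_subset]
        lines = expression.index.intersection(lines)
        if len(lines) < min_tissue_lines:
            raise TissueTooSmallError(tissue_subset, len(lines), min_tissue_lines)
        expression = expression.loc[lines]

    models: dict[str, ClusterModel] = {}
    failures: dict[str, str] = {}
    ss = np.random.SeedSequence(seed)
    gene_seeds = ss.generate_state(expression.shape[1])
    for j, gene in enumerate(expression.columns):
        try:
            models[gene] = fit_gene_mixture(
                expression[gene], seed=int(gene_seeds[j]) % (2**31), gene=gene, **fit_kwargs
            )
        except (DegenerateGeneError, InsufficientDataError) as exc:
            failures[gene] = str(exc)
    if failures:
        logger.info("clustering skipped %d/%d genes", len(failures), expression.shape[1])
    return models, failures


def models_to_table(models: dict[str, ClusterModel]) -> pd.DataFrame:
    """Export fitted models as a long (gene, cell_line, cluster, k, cluster_mean) table."""
    rows = []
    for gene, m in models.items():
        for cell_line, cluster in m.assignments.items():
            rows.append((gene, cell_line, int(cluster), m.k, float(m.means[cluster - 1])))
    return pd.DataFrame(rows, columns=["gene", "cell_line", "cluster", "k", "cluster_mean"])


def table_to_assignments(table: pd.DataFrame) -> dict[str, pd.Series]:
    """Round-trip reader for ``models_to_table`` output: gene -> assignments."""
    out = {}
    for gene, grp in table.groupby("gene"):
        out[str(gene)] = pd.Series(
            grp["cluster"].to_numpy(dtype=int), index=pd.Index(grp["cell_line"])
        )
    return out
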