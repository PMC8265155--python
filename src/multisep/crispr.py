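"""CRISPR essentiality dependency tests over expression clusters.

For a candidate pair (mRNA gene, CRISPR gene), the mRNA gene's expression
clusters partition the cell lines and CERES-like knockout scores of the
CRISPR gene are compared between *neighbouring* clusters with a two-tailed
Welch t-test. With k > 2 clusters every adjacent pair (i, i+1) meeting the
minimum group size is tested and the smallest-p comparison is reported
(ties broken toward the larger absolute effect); an extreme-cluster
(first vs last) comparison is also retained for reference.

The effect column is named ``log2FC`` for compatibility with the results
tables this format mirrors, but it is a *difference of cluster means* of
CERES scores: essentiality scores are signed and centred near zero, so a
ratio would be ill-defined. Genome-wide scans retain pairs with
|effect| > 0.1 and p < 0.1 by default, and q-values are computed over all
tested pairs within the scan scope before threshold filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterModel, cluster_all_genes
from .errors import ConfigError, NotTestableError
from .io import Dataset
from .stats import compute_qvalues, welch_ttest

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "mRNA_gene", "crispr_gene", "tissue", "cluster_lo", "cluster_hi",
    "n_lo", "n_hi", "log2FC", "p_value", "q_value",
]


@dataclass
class CrisprDependencyResult:
    """Best adjacent-cluster comparison for one (mRNA, CRISPR) gene pair."""

    mrna_gene: str
    crispr_gene: str
    tissue: str
    cluster_lo: int
    cluster_hi: int
    effect: float  # mean(cluster_hi) - mean(cluster_lo) of CERES scores
    p: float
    q: float | None
    n_lo: int
    n_hi: int
    all_comparisons: list[dict] | None = None

    @property
    def score(self) -> float:
        """Ranking score used in benchmarking: -log10 p."""
        return float(-np.log10(max(self.p, 1e-300)))


def test_pair(
    model: ClusterModel,
    crispr_scores: pd.Series,
    min_group: int = 3,
    crispr_gene: str = "",
    tissue: str = "all",
    include_extreme: bool = True,
) -> CrisprDependencyResult:
    """Welch-test CERES scores between every adjacent cluster pair.

    ``crispr_scores`` is indexed by cell line; lines without a finite score
    are ignored. Raises ``NotTestableError`` when no adjacent pair has at
    least ``min_group`` scored lines on both sides.
    """
    comparisons = []
    groups = {}
    for c in range(1, model.k + 1):
        vals = crispr_scores.reindex(model.cluster_members(c)).to_numpy(dtype=float)
        groups[c] = vals[np.isfinite(vals)]
    pairs = [(c, c + 1) for c in range(1, model.k)]
    if include_extreme and model.k > 2:
        pairs.append((1, model.k))
    for lo, hi in pairs:
        x, y = groups[lo], groups[hi]
        if len(x) < min_group or len(y) < min_group:
            continue
        _, _, p = welch_ttest(len(x), x.mean(), x.var(ddof=1),
                              len(y), y.mean(), y.var(ddof=1))
        comparisons.append({
            "cluster_lo": lo, "cluster_hi": hi,
            "effect": float(y.mean() - x.mean()), "p": float(p),
            "n_lo": len(x), "n_hi": len(y),
            "adjacent": hi == lo + 1,
        })
    adjacent = [c for c in comparisons if c["adjacent"]]
    if not adjacent:
        raise NotTestableError(
            f"no adjacent cluster pair with >= {min_group} scored lines each"
        )
    best = min(adjacent, key=lambda c: (c["p"], -abs(c["effect"])))
    return CrisprDependencyResult(
        mrna_gene=model.gene, crispr_gene=crispr_gene, tissue=tissue,
        cluster_lo=best["cluster_lo"], cluster_hi=best["cluster_hi"],
        effect=best["effect"], p=best["p"], q=None,
        n_lo=best["n_lo"], n_hi=best["n_hi"], all_comparisons=comparisons,
    )


def _scan_one_mrna_gene(
    model: ClusterModel, crispr: pd.DataFrame, min_group: int, best_only: bool = True
) -> pd.DataFrame | None:
    """Vectorised adjacent-cluster Welch tests of one model against all CRISPR genes.

    ``best_only`` keeps the minimum-p adjacent comparison per CRISPR gene;
    otherwise every adjacent comparison is emitted (verbose mode).
    """
    stats_by_cluster = {}
    for c in range(1, model.k + 1):
        sub = crispr.reindex(model.cluster_members(c))
        vals = sub.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        n = finite.sum(axis=0).astype(float)
        safe = np.where(finite, vals, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = safe.sum(axis=0) / n
            var = np.where(
                n > 1,
                (np.where(finite, (vals - mean) ** 2, 0.0)).sum(axis=0) / np.maximum(n - 1, 1),
                np.nan,
            )
        stats_by_cluster[c] = (n, mean, var)

    n_genes = crispr.shape[1]
    best_p = np.full(n_genes, np.inf)
    best_eff = np.zeros(n_genes)
    best_lo = np.zeros(n_genes, dtype=int)
    best_nlo = np.zeros(n_genes, dtype=int)
    best_nhi = np.zeros(n_genes, dtype=int)
    verbose_frames = []
    for lo in range(1, model.k):
        n1, m1, v1 = stats_by_cluster[lo]
        n2, m2, v2 = stats_by_cluster[lo + 1]
        ok = (n1 >= min_group) & (n2 >= min_group)
        if not ok.any():
            continue
        _, _, p = welch_ttest(n1, m1, v1, n2, m2, v2)
        eff = m2 - m1
        if not best_only:
            verbose_frames.append(pd.DataFrame({
                "crispr_gene": crispr.columns[ok],
                "cluster_lo": lo,
                "cluster_hi": lo + 1,
                "n_lo": n1[ok].astype(int),
                "n_hi": n2[ok].astype(int),
                "log2FC": eff[ok],
                "p_value": p[ok],
            }))
            continue
        p = np.where(ok, p, np.inf)
        better = (p < best_p) | ((p == best_p) & (np.abs(eff) > np.abs(best_eff)))
        upd = ok & better
        best_p[upd] = p[upd]
        best_eff[upd] = eff[upd]
        best_lo[upd] = lo
        best_nlo[upd] = n1[upd]
        best_nhi[upd] = n2[upd]
    if not best_only:
        return pd.concat(verbose_frames, ignore_index=True) if verbose_frames else None
    tested = np.isfinite(best_p)
    if not tested.any():
        return None
    return pd.DataFrame({
        "crispr_gene": crispr.columns[tested],
        "cluster_lo": best_lo[tested],
        "cluster_hi": best_lo[tested] + 1,
        "n_lo": best_nlo[tested],
        "n_hi": best_nhi[tested],
        "log2FC": best_eff[tested],
        "p_value": best_p[tested],
    })


def scan_crispr(
    dataset: Dataset,
    tissue: str | None = None,
    effect_min: float = 0.1,
    p_max: float = 0.1,
    min_group: int = 3,
    q_method: str = "bh",
    models: dict[str, ClusterModel] | None = None,
    mrna_genes: list[str] | None = None,
    crispr_genes: list[str] | None = None,
    seed: int = 0,
    include_unfiltered: bool = False,
    best_only: bool = True,
) -> pd.DataFrame:
    """Genome-wide scan of (mRNA gene x CRISPR gene) dependency candidates.

    q-values are computed over *all* tested pairs in this scan scope, then
    rows failing |effect| > ``effect_min`` or p >= ``p_max`` are dropped and
    the survivors sorted by q ascending. ``include_unfiltered`` returns the
    full tested table instead (used for benchmarking score export), and
    ``best_only=False`` emits every adjacent-cluster comparison per pair
    instead of the minimum-p one. Self-pairs (mRNA gene == CRISPR gene) are
    excluded.
    """
    if dataset.crispr is None:
        raise ConfigError("dataset has no CRISPR matrix")
    expr = dataset.expression
    if mrna_genes is not None:
        expr = expr[[g for g in mrna_genes if g in expr.columns]]
    crispr = dataset.crispr
    if crispr_genes is not None:
        crispr = crispr[[g for g in crispr_genes if g in crispr.columns]]
    if models is None:
        models, _ = cluster_all_genes(
            expr, tissues=dataset.tissues, tissue_subset=tissue, seed=seed
        )
    if tissue is not None:
        lines = dataset.tissues.index[dataset.tissues == tissue]
        crispr = crispr.loc[crispr.index.intersection(lines)]

    frames = []
    for gene in expr.columns:
        if gene not in models:
            continue
        tbl = _scan_one_mrna_gene(models[gene], crispr, min_group, best_only=best_only)
        if tbl is not None:
            tbl.insert(0, "mRNA_gene", gene)
            frames.append(tbl)
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out[out["mRNA_gene"] != out["crispr_gene"]].reset_index(drop=True)
    out.insert(2, "tissue", tissue if tissue is not None else "all")
    out["q_value"] = compute_qvalues(out["p_value"].to_numpy(), method=q_method)
    logger.info("crispr scan tested %d pairs", len(out))
    if include_unfiltered:
        return out[RESULT_COLUMNS]
    out = out[(out["log2FC"].abs() > effect_min) & (out["p_value"] < p_max)]
    return out.sort_values("q_value", kind="mergesort").reset_index(drop=True)[RESULT_COLUMNS]
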