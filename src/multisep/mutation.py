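"""Mutation-class enrichment tests over expression clusters.

A candidate pair (mRNA gene, mutation gene) is tested by asking whether the
mutation gene's somatic calls are distributed independently of the mRNA
gene's expression clusters. The default ``binary`` mode builds a
clusters x {wild-type, mutated} contingency table; ``by_class`` mode
resolves mutated lines into variant classes (clusters x classes table),
pooling classes whose expected count falls below 1 into ``other``. Either
table is tested with Pearson's chi-squared without continuity correction.

Screening defaults follow the p < 0.05 and >= 5 mutated cell lines
inclusion rule. A cell line with several records for one gene counts once;
in ``by_class`` mode it contributes its most deleterious class under the
severity ranking nonsense/frameshift > splice > missense > in-frame > other.
Wild-type labels reflect somatic calls only — a line annotated wild-type may
carry an undetected germline variant; that is a documented limitation, not
something the test corrects for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterModel, cluster_all_genes
from .errors import ConfigError, NotTestableError
from .io import Dataset
from .stats import compute_qvalues

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "mutation_gene", "mRNA_gene", "tissue", "chi2", "dof",
    "p_value", "q_value", "n_mutations",
]

#: Most-deleterious-first ordering used to collapse multi-record lines.
SEVERITY_ORDER = (
    "nonsense",
    "frameshift_insertion",
    "frameshift_deletion",
    "splice_site",
    "start_lost",
    "nonstop",
    "missense",
    "inframe_insertion",
    "inframe_deletion",
)


@dataclass
class MutationDependencyResult:
    """Chi-squared enrichment of one mutation gene across one gene's clusters."""

    mrna_gene: str
    mutation_gene: str
    tissue: str
    chi2: float
    dof: int
    p: float
    q: float | None
    n_mutations: int
    counts: pd.DataFrame  # clusters x status contingency table
    low_expected: bool = False  # expected < 5 in >20% of cells

    @property
    def score(self) -> float:
        """Ranking score used in benchmarking: -log10 p."""
        return float(-np.log10(max(self.p, 1e-300)))


def _severity_rank(cls: str) -> int:
    try:
        return SEVERITY_ORDER.index(cls)
    except ValueError:
        return len(SEVERITY_ORDER)


def collapse_statuses(
    mutations: pd.DataFrame, gene: str, cell_lines: pd.Index
) -> pd.Series:
    """Per-cell-line mutation status for one gene: class label or "wild-type".

    Multiple records for a line collapse to the most deleterious class.
    """
    sub = mutations[(mutations["gene"] == gene) & mutations["cell_line"].isin(cell_lines)]
    status = pd.Series("wild-type", index=cell_lines, dtype=object)
    if len(sub):
        best = (
            sub.assign(_rank=sub["mutation_class"].map(_severity_rank))
            .sort_values(["cell_line", "_rank"], kind="mergesort")
            .drop_duplicates("cell_line")
            .set_index("cell_line")["mutation_class"]
        )
        status.loc[best.index] = best
    return status


def chi2_independence(
    table: np.ndarray, warn_low_expected: bool = True
) -> tuple[float, int, float, bool]:
    """Pearson chi-squared test of independence, no continuity correction.

    Zero-margin rows/columns are dropped before testing. Degenerate tables
    (fewer than 2 non-empty rows or columns) raise ``NotTestableError``.
    Returns (chi2, dof, p, low_expected) where ``low_expected`` flags
    expected counts < 5 in more than 20% of cells — logged, never an
    automatic switch to an exact test.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise NotTestableError("contingency table collapses below 2x2")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    low_expected = bool(np.mean(expected < 5) > 0.2)
    if low_expected and warn_low_expected:
        logger.warning(
            "chi-squared approximation: expected count < 5 in >20%% of cells"
        )
    return float(chi2), int(dof), float(p), low_expected


def test_mutation_pair(
    model: ClusterModel,
    statuses: pd.Series,
    mode: str = "binary",
    min_mutations: int = 5,
    mutation_gene: str = "",
    tissue: str = "all",
    warn_low_expected: bool = True,
) -> MutationDependencyResult:
    """Chi-squared test of mutation status across a gene's clusters.

    ``statuses`` maps cell line -> variant class or "wild-type". Only lines
    with a cluster assignment are considered. Raises ``NotTestableError``
    with fewer than ``min_mutations`` mutated lines, or when every line is
    mutated or every line is wild-type.
    """
    statuses = statuses.reindex(model.assignments.index).dropna()
    mutated = statuses != "wild-type"
    n_mut = int(mutated.sum())
    if n_mut < min_mutations:
        raise NotTestableError(
            f"{n_mut} mutated cell lines < required {min_mutations}"
        )
    if n_mut == len(statuses):
        raise NotTestableError("all assigned cell lines are mutated")

    clusters = model.assignments.reindex(statuses.index)
    if mode == "binary":
        status_col = np.where(mutated, "mutated", "wild-type")
    elif mode == "by_class":
        status_col = statuses.to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = pd.crosstab(clusters.to_numpy(), status_col)
    counts.index.name = "cluster"
    if mode == "by_class" and counts.shape[1] > 2:
        # pool variant classes whose expected counts are uniformly tiny
        col_tot = counts.sum(axis=0)
        row_tot = counts.sum(axis=1)
        expected_max = np.outer(row_tot, col_tot).max(axis=0) / counts.to_numpy().sum()
        rare = [
            c for c, e in zip(counts.columns, expected_max)
            if c != "wild-type" and e < 1.0
        ]
        if rare:
            counts["other"] = counts[rare].sum(axis=1)
            counts = counts.drop(columns=rare)
    chi2, dof, p, low_exp = chi2_independence(
        counts.to_numpy(), warn_low_expected=warn_low_expected
    )
    return MutationDependencyResult(
        mrna_gene=model.gene, mutation_gene=mutation_gene, tissue=tissue,
        chi2=chi2, dof=dof, p=p, q=None, n_mutations=n_mut, counts=counts,
        low_expected=low_exp,
    )


def scan_mutations(
    dataset: Dataset,
    mutation_genes: list[str],
    tissue: str | None = None,
    p_max: float = 0.05,
    min_mutations: int = 5,
    mode: str = "binary",
    q_method: str = "bh",
    models: dict[str, ClusterModel] | None = None,
    mrna_genes: list[str] | None = None,
    seed: int = 0,
    include_unfiltered: bool = False,
) -> pd.DataFrame:
    """Scan mutation genes against every expression gene's clusters.

    Unknown mutation genes are skipped with a warning. q-values are computed
    over all tested pairs in the scan scope; retained rows then satisfy
    p < ``p_max`` and the minimum-mutation rule, sorted by q ascending.
    """
    if dataset.mutations is None:
        raise ConfigError("dataset has no mutation table")
    if not mutation_genes:
        raise ConfigError("mutation_genes must be non-empty")
    expr = dataset.expression
    if mrna_genes is not None:
        expr = expr[[g for g in mrna_genes if g in expr.columns]]
    if models is None:
        models, _ = cluster_all_genes(
            expr, tissues=dataset.tissues, tissue_subset=tissue, seed=seed
        )
    known = set(dataset.mutations["gene"])
    lines = expr.index
    if tissue is not None:
        lines = dataset.tissues.index[dataset.tissues == tissue].intersection(lines)

    rows = []
    n_low_expected = 0
    for mut_gene in mutation_genes:
        if mut_gene not in known:
            logger.warning("mutation gene %r absent from mutation table; skipped", mut_gene)
            continue
        statuses = collapse_statuses(dataset.mutations, mut_gene, lines)
        for mrna_gene, model in models.items():
            if mrna_gene == mut_gene:
                continue
            try:
                res = test_mutation_pair(
                    model, statuses, mode=mode, min_mutations=min_mutations,
                    mutation_gene=mut_gene,
                    tissue=tissue if tissue is not None else "all",
                    warn_low_expected=False,
                )
            except NotTestableError:
                continue
            n_low_expected += int(res.low_expected)
            rows.append((
                res.mutation_gene, res.mrna_gene, res.tissue, res.chi2,
                res.dof, res.p, np.nan, res.n_mutations,
            ))
    if n_low_expected:
        logger.info(
            "chi-squared expected count < 5 in >20%% of cells for %d/%d tested pairs",
            n_low_expected, len(rows),
        )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(out):
        out["q_value"] = compute_qvalues(out["p_value"].to_numpy(), method=q_method)
    logger.info("mutation scan tested %d pairs", len(out))
    if include_unfiltered:
        return out
    out = out[out["p_value"] < p_max]
    return out.sort_values(
        ["tissue", "q_value", "n_mutations"], kind="mergesort"
    ).reset_index(drop=True)
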