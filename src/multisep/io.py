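"""Dataset model and delimited-text readers/writers.

All tabular inputs follow DepMap-style conventions: omics matrices are wide
delimited text (first column = cell line, header row = gene symbols), the
mutation table is long-format with one row per variant call, annotations are
two-column edge lists / long tables, and the benchmarking gold standard is a
three-column ``gene_a, gene_b, score`` table. Comma and tab separators are
auto-detected from the first line of each file.

On load, all sources are aligned to the shared cell-line universe (set
intersection); cell lines present in the expression matrix but missing from
the tissue table are kept under the reserved tissue label ``"unannotated"``
rather than being dropped, so pan-cancer analyses retain them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DuplicateIdentifierError, EmptyIntersectionError

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"

#: Non-silent somatic variant classes recognised by the mutation loader
#: (MAF-style names). Silent calls are dropped on load with a logged count:
#: they do not support loss-of-function semantics.
MUTATION_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_insertion",
    "frameshift_deletion",
    "inframe_insertion",
    "inframe_deletion",
    "splice_site",
    "nonstop",
    "start_lost",
)

_MAF_ALIASES = {
    "tumor_sample_barcode": "cell_line",
    "hugo_symbol": "gene",
    "variant_classification": "mutation_class",
}

_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "frame_shift_ins": "frameshift_insertion",
    "frame_shift_del": "frameshift_deletion",
    "in_frame_ins": "inframe_insertion",
    "in_frame_del": "inframe_deletion",
    "splice_site": "splice_site",
    "nonstop_mutation": "nonstop",
    "translation_start_site": "start_lost",
    "start_codon_snp": "start_lost",
    "silent": "silent",
}


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _check_unique(values: Iterable[str], what: str, path) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique())
        raise DuplicateIdentifierError(
            f"duplicate {what} identifier(s) in {path}: {', '.join(map(str, dups))}"
        )


def read_matrix(path: str | Path, log2_transform: bool = False) -> pd.DataFrame:
    """Read a wide cell-line x gene matrix (CSV/TSV, auto-detected).

    ``log2_transform`` applies log2(x+1) for raw-count-scale inputs; by
    default values are assumed pre-transformed.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "gene", path)  # pandas would silently mangle these
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "cell-line", path)
    df = df.astype(float)
    if log2_transform:
        df = np.log2(df + 1.0)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="," if str(path).endswith(".csv") else "\t")


def read_tissue_table(path: str | Path) -> pd.Series:
    """Read a two-column cell_line -> tissue table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "cell_line" not in cols or "tissue" not in cols:
        df.columns = ["cell_line", "tissue"] + list(df.columns[2:])
    _check_unique(df["cell_line"], "cell-line", path)
    return df.set_index("cell_line")["tissue"].astype(str)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a long mutation table; MAF column/class aliases accepted.

    Returns columns ``cell_line, gene, mutation_class``. Silent variants are
    dropped (count logged); unknown class labels are retained with a warning
    so validation can surface them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = [_MAF_ALIASES.get(c.lower(), c.lower()) for c in df.columns]
    missing = {"cell_line", "gene", "mutation_class"} - set(df.columns)
    if missing:
        raise ConfigError(f"mutation table {path} lacks column(s): {sorted(missing)}")
    cls = df["mutation_class"].astype(str).str.lower()
    cls = cls.map(lambda c: _MAF_CLASS_MAP.get(c, c))
    df = df.assign(mutation_class=cls)[["cell_line", "gene", "mutation_class"]]
    n_silent = int((df["mutation_class"] == "silent").sum())
    if n_silent:
        logger.info("dropped %d silent mutation records from %s", n_silent, path)
        df = df[df["mutation_class"] != "silent"]
    unknown = sorted(set(df["mutation_class"]) - set(MUTATION_CLASSES))
    for label in unknown:
        logger.warning("unknown mutation class label %r in %s", label, path)
    return df.reset_index(drop=True)


def read_pair_list(path: str | Path) -> set[frozenset[str]]:
    """Read a two-column gene-pair edge list into a symmetric set.

    Self-pairs are dropped; (A,B) and (B,A) collapse to one entry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    a, b = df.columns[:2]
    pairs = {
        frozenset((str(x), str(y)))
        for x, y in zip(df[a], df[b])
        if str(x) != str(y)
    }
    return pairs


def read_go_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a long two-column gene -> GO-term table into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    gene_col, term_col = df.columns[:2]
    grouped = df.groupby(df[gene_col].astype(str))[term_col].apply(
        lambda s: frozenset(map(str, s))
    )
    return dict(grouped)


def read_gold_standard(path: str | Path) -> pd.DataFrame:
    """Read a SynLethDB-format three-column ``gene_a, gene_b, score`` table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    df.columns = ["gene_a", "gene_b", "score"] + list(df.columns[3:])
    return df[["gene_a", "gene_b", "score"]].astype(
        {"gene_a": str, "gene_b": str, "score": float}
    )


@dataclass
class AnnotationSets:
    """Functional-similarity annotation sources for gene pairs."""

    go_terms: Mapping[str, frozenset[str]] = field(default_factory=dict)
    ppi_edges: set[frozenset[str]] = field(default_factory=set)
    paralogue_pairs: set[frozenset[str]] = field(default_factory=set)


@dataclass
class Dataset:
    """Aligned multi-omics dataset over a shared cell-line universe.

    ``expression`` (cell lines x genes, log2-scale) and ``tissues`` are
    mandatory; the CRISPR essentiality matrix (CERES-like scores, more
    negative = more essential), mutation table, annotations, protein matrix
    and copy-number matrix are optional components used by specific analyses.
    """

    expression: pd.DataFrame
    tissues: pd.Series
    crispr: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    annotations: AnnotationSets | None = None
    protein: pd.DataFrame | None = None
    copy_number: pd.DataFrame | None = None

    @property
    def cell_lines(self) -> pd.Index:
        return self.expression.index

    def subset_tissue(self, tissue: str) -> "Dataset":
        """Restrict all matrices to cell lines of one tissue."""
        lines = self.tissues.index[self.tissues == tissue]
        if len(lines) == 0:
            raise ConfigError(f"no cell lines annotated with tissue {tissue!r}")
        return align_dataset(
            replace(self, expression=self.expression.loc[self.expression.index.intersection(lines)])
        )


def align_dataset(ds: Dataset) -> Dataset:
    """Intersect and align every matrix to the shared cell-line universe.

    Idempotent: re-aligning an aligned dataset returns an equal dataset.
    Raises ``EmptyIntersectionError`` if no cell line is shared.
    """
    universe = pd.Index(ds.expression.index)
    for mat in (ds.crispr, ds.protein, ds.copy_number):
        if mat is not None:
            dropped = universe.difference(mat.index)
            if len(dropped):
                logger.info("alignment drops %d cell lines absent from a matrix", len(dropped))
            universe = universe.intersection(mat.index)
    if len(universe) == 0:
        raise EmptyIntersectionError("cell-line intersection across sources is empty")
    universe = ds.expression.index[ds.expression.index.isin(universe)]  # keep order

    tissues = ds.tissues.reindex(universe).fillna(UNANNOTATED).astype(str)

    def _sub(mat):
        return None if mat is None else mat.loc[universe]

    mutations = ds.mutations
    if mutations is not None:
        mutations = mutations[mutations["cell_line"].isin(universe)].reset_index(drop=True)

    return Dataset(
        expression=ds.expression.loc[universe],
        tissues=tissues,
        crispr=_sub(ds.crispr),
        mutations=mutations,
        annotations=ds.annotations,
        protein=_sub(ds.protein),
        copy_number=_sub(ds.copy_number),
    )


def load_dataset(config: str | Path | Mapping) -> Dataset:
    """Load and align a dataset from a config mapping or YAML file path.

    Recognised keys: ``expression`` (required), ``tissues`` (required),
    ``crispr``, ``mutations``, ``protein``, ``copy_number``, ``ppi``,
    ``paralogues``, ``go``, ``log2_transform`` (bool, expression only).
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        with open(config) as fh:
            config = yaml.safe_load(fh)
        config = {
            k: (v if isinstance(v, bool) else str(base / v)) for k, v in config.items()
        }
    if "expression" not in config or "tissues" not in config:
        raise ConfigError("config must name an expression matrix and a tissue table")
    log2 = bool(config.get("log2_transform", False))
    ann = None
    if any(k in config for k in ("ppi", "paralogues", "go")):
        ann = AnnotationSets(
            go_terms=read_go_table(config["go"]) if "go" in config else {},
            ppi_edges=read_pair_list(config["ppi"]) if "ppi" in config else set(),
            paralogue_pairs=read_pair_list(config["paralogues"])
            if "paralogues" in config
            else set(),
        )
    ds = Dataset(
        expression=read_matrix(config["expression"], log2_transform=log2),
        tissues=read_tissue_table(config["tissues"]),
        crispr=read_matrix(config["crispr"]) if "crispr" in config else None,
        mutations=read_mutation_table(config["mutations"]) if "mutations" in config else None,
        annotations=ann,
        protein=read_matrix(config["protein"]) if "protein" in config else None,
        copy_number=read_matrix(config["copy_number"]) if "copy_number" in config else None,
    )
    return align_dataset(ds)


def validate_dataset(ds: Dataset) -> dict:
    """Summarise a dataset without mutating it.

    Returns per-source counts, NaN rates, tissue-group sizes, the
    mutation-class frequency table, and any unknown class labels.
    """
    report: dict = {
        "n_cell_lines": int(len(ds.cell_lines)),
        "n_genes_expression": int(ds.expression.shape[1]),
        "nan_rate": {"expression": float(ds.expression.isna().mean().mean())},
        "tissue_groups": ds.tissues.value_counts().to_dict(),
    }
    for name in ("crispr", "protein", "copy_number"):
        mat = getattr(ds, name)
        if mat is not None:
            report["nan_rate"][name] = float(mat.isna().mean().mean())
            report[f"n_genes_{name}"] = int(mat.shape[1])
    if ds.mutations is not None:
        freq = ds.mutations["mutation_class"].value_counts().to_dict()
        report["mutation_class_frequencies"] = freq
        report["unknown_mutation_classes"] = sorted(
            set(freq) - set(MUTATION_CLASSES)
        )
        report["n_mutation_records"] = int(len(ds.mutations))
    return report
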