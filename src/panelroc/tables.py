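"""Marker-table data model, file I/O, and single-cell harmonization.

The central container is :class:`MarkerTable`: one row per sample (or cell),
an ID, an optional two-level case/control class, and one numeric signal
column per marker.  Signals are arbitrary non-negative assay units —
proteomic intensities or rescaled expression values alike.

Single-cell expression matrices (10x MTX triplets or dense gene-by-cell
text) are converted into marker tables by :func:`harmonize_expression_matrix`:
min-max rescaling of the signals to a fixed range (0–10 by default),
subsetting to an alphabetically ordered marker-gene panel, transposition so
cells become rows, and optional class assignment from a cell-annotation
table.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    ClassLabelError,
    DegenerateScaleError,
    FormatError,
    GeneSubsetError,
    ParseError,
)

logger = logging.getLogger(__name__)

ID_COLUMN = "ID"
CLASS_COLUMN = "Class"

#: Canonical internal encoding: case = 1, control = 0.
CASE, CONTROL = 1, 0


@dataclass
class MarkerTable:
    """Samples-by-markers signal matrix with IDs and optional class labels.

    Parameters
    ----------
    signals
        DataFrame indexed by unique sample IDs, one numeric column per
        marker.  No missing values are allowed after ingestion.
    classes
        Optional per-sample labels (original strings), aligned with
        ``signals.index``.  Exactly two levels, both present.
    case_label, control_label
        Which original label maps to the positive (case) class and which to
        the control class.
    """

    signals: pd.DataFrame
    classes: pd.Series | None = None
    case_label: str | None = None
    control_label: str | None = None

    def __post_init__(self) -> None:
        if self.signals.index.has_duplicates:
            dup = self.signals.index[self.signals.index.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        if self.signals.columns.has_duplicates:
            dup = self.signals.columns[self.signals.columns.duplicated()][0]
            raise FormatError(f"duplicate marker name: {dup!r}")
        if self.signals.isna().any().any():
            raise ParseError("signal matrix contains missing values")
        if self.classes is not None:
            self.classes = self.classes.reindex(self.signals.index)
            if self.classes.isna().any():
                raise ClassLabelError("class labels missing for some samples")
            levels = set(self.classes.unique())
            if levels != {self.case_label, self.control_label}:
                raise ClassLabelError(
                    f"class levels {sorted(map(str, levels))} do not match "
                    f"case={self.case_label!r} / control={self.control_label!r}, "
                    "or one level is absent"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def markers(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def n_samples(self) -> int:
        return len(self.signals)

    @property
    def is_labeled(self) -> bool:
        return self.classes is not None

    def class_binary(self) -> pd.Series:
        """Per-sample 0/1 encoding (case = 1, control = 0)."""
        if self.classes is None:
            raise ClassLabelError("table is unlabeled")
        return (self.classes == self.case_label).astype(int)

    def require_labeled(self) -> None:
        if not self.is_labeled:
            raise ClassLabelError("operation requires a labeled table")


@dataclass
class HarmonizationSpec:
    """How to turn a gene-by-cell expression matrix into a marker table.

    ``scale_scope`` controls whether one min/max is taken over the whole
    matrix (``"global"``, the default — preserves relative gene magnitudes,
    which the positivity rule depends on) or per gene (``"per_gene"``).
    Scaling is computed before gene subsetting, matching the step order
    transposition → scaling → subsetting.
    """

    gene_subset: Sequence[str]
    scale_min: float = 0.0
    scale_max: float = 10.0
    case_annotation: str | None = None
    drop_missing_genes: bool = True
    scale_scope: Literal["global", "per_gene"] = "global"
    control_name: str = "Other"

    def __post_init__(self) -> None:
        if len(self.gene_subset) == 0:
            raise GeneSubsetError("gene_subset must be non-empty")
        if not self.scale_min < self.scale_max:
            raise DegenerateScaleError(
                f"scale_min ({self.scale_min}) must be < scale_max ({self.scale_max})"
            )


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_marker_table(
    path: str | os.PathLike,
    labeled: bool = True,
    case_class: str | None = None,
    control_class: str | None = None,
    on_missing: Literal["error", "drop"] = "error",
) -> MarkerTable:
    """Read a wide case/control marker table from delimited text.

    Expected header: ``ID,Class,<marker1>,...`` (Class column only when
    labeled).  Comma vs tab is auto-detected from the file extension
    (.csv → comma, anything else → tab).

    If ``labeled`` and ``case_class`` is None, the alphabetically first class
    level is taken as the case class (with a warning); pass it explicitly for
    unambiguous mapping.

    ``on_missing="drop"`` removes samples with any missing signal instead of
    rejecting the file.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if ID_COLUMN not in df.columns:
        raise FormatError(f"{path}: missing required {ID_COLUMN!r} column")

    classes = None
    if labeled:
        if CLASS_COLUMN not in df.columns:
            raise FormatError(f"{path}: labeled table lacks a {CLASS_COLUMN!r} column")
        levels = sorted(df[CLASS_COLUMN].dropna().unique())
        if len(levels) != 2:
            raise ClassLabelError(
                f"{path}: {CLASS_COLUMN!r} column has {len(levels)} levels "
                f"({levels}); exactly 2 required"
            )
        if case_class is None:
            case_class = levels[0]
            warnings.warn(
                f"case_class not given; using alphabetically first level {case_class!r}",
                stacklevel=2,
            )
        if case_class not in levels:
            raise ClassLabelError(f"case class {case_class!r} not among levels {levels}")
        inferred_control = next(l for l in levels if l != case_class)
        if control_class is None:
            control_class = inferred_control
        elif control_class != inferred_control:
            raise ClassLabelError(
                f"control class {control_class!r} not found (levels: {levels})"
            )
        classes = df[CLASS_COLUMN]
    elif CLASS_COLUMN in df.columns:
        warnings.warn(
            f"{path}: {CLASS_COLUMN!r} column present but labeled=False; ignoring it",
            stacklevel=2,
        )

    marker_cols = [c for c in df.columns if c not in (ID_COLUMN, CLASS_COLUMN)]
    if not marker_cols:
        raise FormatError(f"{path}: no marker columns found")

    signals = pd.DataFrame(index=pd.Index(df[ID_COLUMN], name=ID_COLUMN))
    for col in marker_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.loc[bad, ID_COLUMN].iloc[0]
            raise ParseError(
                f"{path}: non-numeric signal in column {col!r}, sample {row!r}"
            )
        signals[col] = numeric.to_numpy()

    if classes is not None:
        classes = pd.Series(classes.to_numpy(), index=signals.index)

    missing = signals.isna().any(axis=1)
    if missing.any():
        if on_missing == "drop":
            logger.info("dropping %d sample(s) with missing signals", int(missing.sum()))
            signals = signals.loc[~missing]
            if classes is not None:
                classes = classes.loc[~missing]
        else:
            row = signals.index[missing][0]
            raise ParseError(f"{path}: missing signal value in sample {row!r}")

    return MarkerTable(
        signals=signals,
        classes=classes,
        case_label=case_class if labeled else None,
        control_label=control_class if labeled else None,
    )


def write_marker_table(table: MarkerTable, path: str | os.PathLike) -> None:
    """Write a marker table as delimited text (round-trips with
    :func:`read_marker_table` up to numeric text precision).  Unlabeled
    tables are written without a Class column."""
    out = table.signals.copy()
    out.insert(0, ID_COLUMN, table.signals.index)
    if table.is_labeled:
        out.insert(1, CLASS_COLUMN, table.classes.to_numpy())
    try:
        out.to_csv(path, sep=_sep_for(path), index=False)
    except OSError as exc:
        raise OSError(f"cannot write marker table to {path}: {exc}") from exc


def pool_signals_long(table: MarkerTable) -> pd.DataFrame:
    """Melt a labeled table into long records (sample_id, class, marker,
    signal) — one record per (sample, marker) pair.  Pooling every marker's
    signals into one column is the first step of global threshold finding."""
    table.require_labeled()
    wide = table.signals.copy()
    wide.insert(0, "sample_id", table.signals.index)
    wide.insert(1, "class", table.classes.to_numpy())
    long = wide.melt(
        id_vars=["sample_id", "class"], var_name="marker", value_name="signal"
    )
    return long.reset_index(drop=True)


def harmonize_expression_matrix(
    genes_by_cells: pd.DataFrame,
    annotations: pd.Series | Mapping[str, str] | None,
    spec: HarmonizationSpec,
) -> MarkerTable:
    """Convert a gene-by-cell expression matrix into a marker table.

    Signals are linearly rescaled so the matrix minimum maps to
    ``spec.scale_min`` and the maximum to ``spec.scale_max`` (computed before
    gene subsetting; per-gene optionally).  Markers are the alphabetically
    ordered intersection of ``spec.gene_subset`` with the matrix genes;
    requested genes absent from the matrix are dropped with a warning (or
    raise, if ``drop_missing_genes`` is False).  Cells become rows; when
    annotations and ``case_annotation`` are given, cells annotated with
    ``case_annotation`` become cases and all others controls.
    """
    if genes_by_cells.index.has_duplicates:
        raise FormatError("gene names are not unique")

    values = genes_by_cells.to_numpy(dtype=float)
    if spec.scale_scope == "global":
        lo, hi = values.min(), values.max()
        if hi == lo:
            raise DegenerateScaleError("matrix is constant; min-max scale undefined")
        scaled = spec.scale_min + (values - lo) * (
            (spec.scale_max - spec.scale_min) / (hi - lo)
        )
    else:
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        if np.any(hi == lo):
            gene = genes_by_cells.index[np.nonzero((hi == lo).ravel())[0][0]]
            raise DegenerateScaleError(f"gene {gene!r} is constant; per-gene scale undefined")
        scaled = spec.scale_min + (values - lo) * (
            (spec.scale_max - spec.scale_min) / (hi - lo)
        )
    scaled_df = pd.DataFrame(
        scaled, index=genes_by_cells.index, columns=genes_by_cells.columns
    )

    requested = sorted(dict.fromkeys(spec.gene_subset))
    present = [g for g in requested if g in scaled_df.index]
    absent = [g for g in requested if g not in scaled_df.index]
    if not present:
        raise GeneSubsetError("no requested gene found in the matrix")
    if absent:
        if not spec.drop_missing_genes:
            raise GeneSubsetError(f"genes absent from matrix: {', '.join(absent)}")
        warnings.warn(
            f"dropping {len(absent)} requested gene(s) absent from the matrix: "
            + ", ".join(absent),
            stacklevel=2,
        )

    cells_by_genes = scaled_df.loc[present].T
    cells_by_genes.index = cells_by_genes.index.astype(str)
    cells_by_genes.index.name = ID_COLUMN

    classes = None
    case_label = control_label = None
    if annotations is not None and spec.case_annotation is not None:
        ann = pd.Series(annotations)
        ann.index = ann.index.astype(str)
        missing_cells = cells_by_genes.index.difference(ann.index)
        if len(missing_cells) > 0:
            raise ClassLabelError(
                f"{len(missing_cells)} cell(s) lack an annotation "
                f"(first: {missing_cells[0]!r})"
            )
        case_label = spec.case_annotation
        control_label = spec.control_name
        ann = ann.reindex(cells_by_genes.index)
        classes = pd.Series(
            np.where(ann == case_label, case_label, control_label),
            index=cells_by_genes.index,
        )
        if (classes == case_label).sum() == 0:
            raise ClassLabelError(
                f"no cell annotated as {case_label!r}; cannot form the case class"
            )

    return MarkerTable(
        signals=cells_by_genes,
        classes=classes,
        case_label=case_label,
        control_label=control_label,
    )


# -- single-cell matrix readers ------------------------------------------------


def read_mtx_triplet(
    directory: str | os.PathLike,
    gene_subset: Iterable[str] | None = None,
    matrix_file: str = "matrix.mtx",
    features_file: str = "features.tsv",
    barcodes_file: str = "barcodes.tsv",
) -> pd.DataFrame:
    """Read a 10x-style MTX triplet into a dense gene-by-cell DataFrame.

    When ``gene_subset`` is given, only the matching rows are densified —
    the full sparse matrix is never expanded, so atlas-scale inputs stay
    memory-safe.  Features file may have one column (symbols) or the usual
    id/symbol/type layout, in which case the second column is used.
    """
    directory = os.fspath(directory)
    mat = scipy.io.mmread(os.path.join(directory, matrix_file))
    feats = pd.read_csv(
        os.path.join(directory, features_file), sep="\t", header=None, dtype=str
    )
    genes = feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]
    genes = genes.to_numpy()
    barcodes = pd.read_csv(
        os.path.join(directory, barcodes_file), sep="\t", header=None, dtype=str
    ).iloc[:, 0].to_numpy()
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )
    mat = scipy.sparse.csr_matrix(mat)
    if gene_subset is not None:
        wanted = set(gene_subset)
        keep = np.nonzero(np.isin(genes, list(wanted)))[0]
        if keep.size == 0:
            raise GeneSubsetError("no requested gene found in the MTX features")
        mat = mat[keep]
        genes = genes[keep]
    return pd.DataFrame(mat.toarray(), index=genes, columns=barcodes)


def read_dense_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dense gene-by-cell matrix from delimited text (first column =
    gene symbols, header row = cell IDs)."""
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_annotations(path: str | os.PathLike) -> pd.Series:
    """Read a per-cell annotation table with columns ``barcode`` and
    ``label`` into a Series indexed by barcode."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "barcode" not in cols or "label" not in cols:
        raise FormatError(f"{path}: annotation table needs 'barcode' and 'label' columns")
    return pd.Series(
        df[cols["label"]].to_numpy(), index=df[cols["barcode"]].to_numpy()
    )


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text gene list, one symbol per line; blanks skipped."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes
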