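"""Weighted interaction matrices: the single data carrier for the pipeline.

Two kinds of networks share this container:

* ``occurrence`` — rows are community samples (site × date), columns are
  consumer species/stages, cells are abundance counts;
* ``foodweb`` — rows are prey items, columns are predator species/stages,
  cells are frequencies of occurrence in stomach contents.

The orientation is fixed: rows are resources, columns are consumers. The
food web's directed (prey→predator) view is derived where needed rather
than stored separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

Kind = Literal["occurrence", "foodweb"]
Side = Literal["rows", "cols"]

__all__ = [
    "WeightedMatrix",
    "NodeMetadata",
    "MatrixFormatError",
    "MatrixValidationError",
    "load_matrix",
    "write_matrix",
    "load_metadata",
    "degree",
    "marginal_totals",
]


class MatrixFormatError(ValueError):
    """A cell or header in an input file could not be parsed."""


class MatrixValidationError(ValueError):
    """The parsed matrix violates a structural invariant."""


@dataclass(frozen=True)
class WeightedMatrix:
    """A labelled non-negative interaction matrix.

    Parameters
    ----------
    values : (n_rows, n_cols) array of non-negative finite weights.
    row_labels, col_labels : unique node labels for each side.
    kind : ``"occurrence"`` or ``"foodweb"``.

    Invariants (enforced at construction): all cells finite and >= 0, at
    least one positive cell, no duplicate labels, and — unless
    ``allow_empty_nodes`` — no all-zero row or column, since zero-degree
    nodes break degree-probabilistic null models.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    kind: Kind = "occurrence"

    def __init__(
        self,
        values,
        row_labels,
        col_labels,
        kind: Kind = "occurrence",
        *,
        allow_empty_nodes: bool = False,
    ) -> None:
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 2:
            raise MatrixValidationError("matrix must be two-dimensional")
        rows = tuple(str(r) for r in row_labels)
        cols = tuple(str(c) for c in col_labels)
        if vals.shape != (len(rows), len(cols)):
            raise MatrixValidationError(
                f"shape {vals.shape} does not match {len(rows)} row and "
                f"{len(cols)} column labels"
            )
        if len(set(rows)) != len(rows):
            dup = sorted({r for r in rows if rows.count(r) > 1})
            raise MatrixValidationError(f"duplicate row labels: {dup}")
        if len(set(cols)) != len(cols):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise MatrixValidationError(f"duplicate column labels: {dup}")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise MatrixValidationError(
                f"non-finite cell at row {rows[i]!r}, column {cols[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise MatrixValidationError(
                f"negative cell at row {rows[i]!r}, column {cols[j]!r}: {vals[i, j]}"
            )
        if not np.any(vals > 0):
            raise MatrixValidationError("matrix has no positive cell")
        empty_rows = np.flatnonzero(vals.sum(axis=1) == 0)
        empty_cols = np.flatnonzero(vals.sum(axis=0) == 0)
        if empty_rows.size or empty_cols.size:
            if not allow_empty_nodes:
                names = [rows[i] for i in empty_rows] + [cols[j] for j in empty_cols]
                raise MatrixValidationError(
                    f"all-zero rows/columns not allowed: {names} "
                    "(pass allow_empty_nodes=True to drop them)"
                )
            warnings.warn(
                f"dropping {empty_rows.size} empty row(s) and "
                f"{empty_cols.size} empty column(s)",
                stacklevel=2,
            )
            keep_r = np.setdiff1d(np.arange(len(rows)), empty_rows)
            keep_c = np.setdiff1d(np.arange(len(cols)), empty_cols)
            vals = vals[np.ix_(keep_r, keep_c)]
            rows = tuple(rows[i] for i in keep_r)
            cols = tuple(cols[j] for j in keep_c)
        if not np.allclose(vals, np.round(vals)):
            warnings.warn(
                "non-integer cell weights: null models redistribute integer "
                "interaction events and will rescale",
                stacklevel=2,
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)
        object.__setattr__(self, "kind", kind)

    # -- basic descriptors -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def total_weight(self) -> float:
        """W, the sum of all interaction events."""
        return float(self.values.sum())

    @property
    def n_links(self) -> int:
        """Number of nonzero cells (realized links)."""
        return int(np.count_nonzero(self.values))

    @property
    def connectance(self) -> float:
        return self.n_links / (self.shape[0] * self.shape[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.row_labels), columns=list(self.col_labels)
        )

    def with_values(self, values: np.ndarray) -> "WeightedMatrix":
        """Same labels and kind, new cell values (used by null models)."""
        return WeightedMatrix(values, self.row_labels, self.col_labels, self.kind)

    def submatrix(self, rows, cols) -> "WeightedMatrix":
        """Extract a labelled submatrix, keeping zero rows/cols if present."""
        ri = [self.row_labels.index(r) for r in rows]
        ci = [self.col_labels.index(c) for c in cols]
        return WeightedMatrix(
            self.values[np.ix_(ri, ci)],
            [self.row_labels[i] for i in ri],
            [self.col_labels[j] for j in ci],
            self.kind,
            allow_empty_nodes=True,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.shape
        return (
            f"WeightedMatrix(kind={self.kind!r}, {r}x{c}, W={self.total_weight:g}, "
            f"links={self.n_links})"
        )


@dataclass(frozen=True)
class NodeMetadata:
    """Categorical annotations for matrix nodes plus consumer abundances.

    ``row_category`` maps resource labels to a habitat type (occurrence
    networks) or a prey category (food webs). ``abundance`` maps consumer
    labels to positive counts.
    """

    row_category: Mapping[str, str] = field(default_factory=dict)
    abundance: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.abundance.items() if not v > 0}
        if bad:
            raise MatrixValidationError(f"non-positive abundances: {bad}")

    def validate_against(self, m: WeightedMatrix) -> None:
        missing = [r for r in m.row_labels if r not in self.row_category]
        if self.row_category and missing:
            raise MatrixValidationError(f"rows without category: {missing}")
        missing = [c for c in m.col_labels if c not in self.abundance]
        if self.abundance and missing:
            raise MatrixValidationError(f"consumers without abundance: {missing}")


# -- I/O -------------------------------------------------------------------

def load_matrix(
    path,
    format: Literal["matrix_tsv", "edge_list_tsv"] = "matrix_tsv",
    kind: Kind = "occurrence",
    *,
    allow_empty_nodes: bool = False,
) -> WeightedMatrix:
    """Read a weighted matrix from TSV.

    ``matrix_tsv``: first row holds consumer labels, first column resource
    labels. ``edge_list_tsv``: columns ``row_label``, ``col_label``,
    ``weight``; absent pairs become 0.
    """
    if format == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.to_numpy().dtype.kind not in "fiu":
            coerced = df.apply(pd.to_numeric, errors="coerce")
            bad = coerced.isna() & df.notna()
            if bad.to_numpy().any():
                i, j = np.argwhere(bad.to_numpy())[0]
                raise MatrixFormatError(
                    f"non-numeric cell at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: {df.iat[i, j]!r}"
                )
            df = coerced
        return WeightedMatrix(
            df.to_numpy(dtype=float), df.index, df.columns, kind,
            allow_empty_nodes=allow_empty_nodes,
        )
    if format == "edge_list_tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"row_label", "col_label", "weight"}
        if not required.issubset(df.columns):
            raise MatrixFormatError(
                f"edge list needs columns {sorted(required)}, got {list(df.columns)}"
            )
        w = pd.to_numeric(df["weight"], errors="coerce")
        if w.isna().any():
            k = int(w.isna().idxmax())
            raise MatrixFormatError(
                f"non-numeric weight for edge ({df.at[k, 'row_label']!r}, "
                f"{df.at[k, 'col_label']!r}): {df.at[k, 'weight']!r}"
            )
        pivot = df.assign(weight=w).pivot_table(
            index="row_label", columns="col_label", values="weight",
            aggfunc="sum", fill_value=0.0,
        )
        # keep first-appearance order of labels, not pivot's sort
        row_order = list(dict.fromkeys(df["row_label"].astype(str)))
        col_order = list(dict.fromkeys(df["col_label"].astype(str)))
        pivot.index = pivot.index.astype(str)
        pivot.columns = pivot.columns.astype(str)
        pivot = pivot.loc[row_order, col_order]
        return WeightedMatrix(
            pivot.to_numpy(dtype=float), pivot.index, pivot.columns, kind,
            allow_empty_nodes=allow_empty_nodes,
        )
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: WeightedMatrix, path, format: Literal["matrix_tsv", "edge_list_tsv"] = "matrix_tsv") -> None:
    """Write a matrix as TSV; round-trips bit-exactly through load_matrix."""
    if format == "matrix_tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="")
    elif format == "edge_list_tsv":
        ri, ci = np.nonzero(m.values)
        pd.DataFrame(
            {
                "row_label": [m.row_labels[i] for i in ri],
                "col_label": [m.col_labels[j] for j in ci],
                "weight": m.values[ri, ci],
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_metadata(category_path=None, abundance_path=None) -> NodeMetadata:
    """Read node categories and/or abundances from two-column TSVs
    (``node_label``, ``category`` / ``abundance``)."""
    cats: dict[str, str] = {}
    abun: dict[str, float] = {}
    if category_path is not None:
        df = pd.read_csv(category_path, sep="\t")
        cats = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if abundance_path is not None:
        df = pd.read_csv(abundance_path, sep="\t")
        abun = dict(zip(df.iloc[:, 0].astype(str), pd.to_numeric(df.iloc[:, 1])))
    return NodeMetadata(row_category=cats, abundance=abun)


# -- marginals -------------------------------------------------------------

def degree(m: WeightedMatrix, side: Side) -> np.ndarray:
    """Number of strictly positive cells per node: communities used
    (occurrence) or prey items eaten (food web) for ``side="cols"``."""
    axis = 1 if side == "rows" else 0
    return np.count_nonzero(m.values > 0, axis=axis)


def marginal_totals(m: WeightedMatrix, side: Side) -> np.ndarray:
    """Per-node sum of interaction weights; either side sums to W."""
    axis = 1 if side == "rows" else 0
    return m.values.sum(axis=axis)
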