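"""Reading expression matrices and labels, writing clustering results.

Delimited text (CSV/TSV, tab wins over comma when both appear in the header
line) and MatrixMarket ``.mtx`` with plain-text identifier sidecars
(``<file>.rows`` / ``<file>.cols``, one identifier per line) are supported.
The internal canonical orientation is cells-by-genes; files stored
genes-by-cells are transposed on read.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

Orientation = Literal["cells_by_genes", "genes_by_cells"]


class ValidationError(ValueError):
    """Input violates a documented contract (negative value, duplicate id, ...)."""


class ParseError(ValueError):
    """File is syntactically malformed."""


@dataclass
class ExpressionMatrix:
    """A cells-by-genes nonnegative expression matrix with identifiers.

    ``orientation_declared`` records the on-disk orientation before
    normalization; ``values`` is always cells-by-genes.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    orientation_declared: Orientation = "cells_by_genes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells < 2 or n_genes < 1:
            raise ValidationError(
                f"need at least 2 cells and 1 gene, got {n_cells} x {n_genes}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError("identifier lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVector:
    """Categorical labels for the cells of one expression matrix."""

    labels: list

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) == 0:
            raise ValidationError("label vector is empty")

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def as_codes(self) -> np.ndarray:
        """Integer codes in order of first appearance."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes


def _sniff_delimiter(header_line: str) -> str:
    # tab wins when both are present (documented precedence)
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return "\t"


def read_expression(
    path: str | os.PathLike,
    fmt: Literal["delimited", "matrix_market"] = "delimited",
    orientation: Orientation = "cells_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing to cells-by-genes.

    Parameters
    ----------
    path:
        Delimited file with a header row and an identifier first column, or a
        MatrixMarket ``.mtx`` file with ``<path>.rows`` / ``<path>.cols``
        identifier sidecars.
    fmt:
        ``delimited`` or ``matrix_market``.
    orientation:
        How the file is laid out on disk. ``genes_by_cells`` input is
        transposed so the returned matrix is always cells-by-genes.
    """
    path = os.fspath(path)
    if fmt == "delimited":
        with open(path) as fh:
            header = fh.readline()
        delim = _sniff_delimiter(header)
        try:
            df = pd.read_csv(path, sep=delim, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ParseError(f"non-numeric column(s) in {path}: {bad}")
        values = df.to_numpy(dtype=float)
        row_ids = [str(x) for x in df.index]
        col_ids = [str(x) for x in df.columns]
    elif fmt == "matrix_market":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_ids = _read_id_file(path + ".rows", values.shape[0])
        col_ids = _read_id_file(path + ".cols", values.shape[1])
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, orientation_declared=orientation)


def _read_id_file(path: str, expected: int) -> list[str]:
    if not os.path.exists(path):
        raise ParseError(f"missing identifier sidecar {path}")
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(ids) != expected:
        raise ValidationError(
            f"{path}: {len(ids)} identifiers for {expected} matrix rows/columns"
        )
    return ids


def read_labels(
    path: str | os.PathLike, matrix: Optional[ExpressionMatrix] = None
) -> LabelVector:
    """Read ground-truth labels, one per line or a (cell_id, label) table.

    Two-column input is re-aligned to ``matrix.cell_ids`` order when a matrix
    is given; a header line is detected by the first field matching no cell id.
    """
    path = os.fspath(path)
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise ValidationError(f"{path} contains no labels")
    delim = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    if delim is None:
        labels = [line.strip() for line in lines]
        if matrix is not None and len(labels) != matrix.n_cells:
            raise ValidationError(
                f"{len(labels)} labels for a {matrix.n_cells}-cell matrix"
            )
        return LabelVector(labels)

    rows = [line.split(delim) for line in lines]
    if any(len(r) < 2 for r in rows):
        raise ParseError(f"{path}: mixed one- and two-column label lines")
    mapping = {r[0].strip(): r[1].strip() for r in rows}
    if matrix is None:
        return LabelVector([r[1].strip() for r in rows])
    # drop a header line if its first field is not a cell id
    known = set(matrix.cell_ids)
    unknown = [k for k in mapping if k not in known]
    if len(unknown) == 1 and len(mapping) == matrix.n_cells + 1:
        del mapping[unknown[0]]
        unknown = []
    if unknown:
        raise ValidationError(f"{path}: unknown cell id(s) {unknown[:5]}")
    if len(mapping) != matrix.n_cells:
        raise ValidationError(
            f"{len(mapping)} labels for a {matrix.n_cells}-cell matrix"
        )
    return LabelVector([mapping[cid] for cid in matrix.cell_ids])


def write_result(result, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write assignments, metrics and objective traces for one run.

    Emits ``assignments.tsv`` (cell_id, cluster), ``metrics.json`` (the metric
    report, or ``{"status": "no_ground_truth"}``), and one two-column
    ``<stage>_trace.tsv`` per recorded objective trace. Returns the mapping of
    artifact name to path.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}

    apath = os.path.join(out_dir, "assignments.tsv")
    cell_ids = result.cell_ids if result.cell_ids is not None else [
        f"cell{i}" for i in range(len(result.labels))
    ]
    with open(apath, "w") as fh:
        fh.write("cell_id\tcluster\n")
        for cid, lab in zip(cell_ids, result.labels):
            fh.write(f"{cid}\t{int(lab)}\n")
    written["assignments"] = apath

    mpath = os.path.join(out_dir, "metrics.json")
    if result.metrics is None:
        payload = {"status": "no_ground_truth"}
    else:
        payload = result.metrics.as_dict()
    with open(mpath, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    written["metrics"] = mpath

    for name, trace in (
        ("attribute", result.attribute_trace),
        ("structure", result.structure_trace),
    ):
        if trace is None:
            continue
        tpath = os.path.join(out_dir, f"{name}_trace.tsv")
        with open(tpath, "w") as fh:
            fh.write("iteration\tobjective\n")
            for i, val in enumerate(trace, start=1):
                fh.write(f"{i}\t{float(val)!r}\n")
        written[f"{name}_trace"] = tpath
    return written
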