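"""Readers and writers for expression matrices, labels and run reports.

Expression matrices travel as dense TSV/CSV (genes in rows, first column =
gene ids, header = cell ids) or as a MatrixMarket MTX triplet (matrix +
``genes.txt`` + ``cells.txt``, one identifier per line).  Normalized
adjacencies persist the same way so smoothing kernels can be precomputed
off-line.  Gene identifier matching throughout the package is exact-string;
symbol/Ensembl mismatches are handled by an explicit user-supplied mapping
before loading, never by fuzzy matching.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pydantic import BaseModel, Field

from .graph import NormalizedAdjacency
from .smoothing import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "write_adjacency",
    "read_adjacency",
    "RunReport",
    "StageRecord",
    "run_report",
    "RUN_REPORT_SCHEMA",
]


def _read_ids(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(path, orientation: str = "genes-in-rows",
                    sep: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or an MTX triplet.

    For ``.mtx`` input, ``genes.txt`` and ``cells.txt`` are expected next to
    the matrix file.  ``orientation="cells-in-rows"`` transposes tabular
    input.  Duplicate gene ids and negative values are errors.
    """
    path = Path(path)
    if orientation not in ("genes-in-rows", "cells-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        mat = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        genes = _read_ids(path.with_name("genes.txt"))
        cells = _read_ids(path.with_name("cells.txt"))
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix is {mat.shape} but id files give "
                f"{len(genes)} genes x {len(cells)} cells")
        frame = pd.DataFrame(mat, index=genes, columns=cells)
    else:
        if sep is None:
            sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "cells-in-rows":
            frame = frame.T
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene identifiers, e.g. {dupes}")
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {frame.index[i]!r}, "
            f"cell {frame.columns[j]!r}")
    return ExpressionMatrix.from_frame(frame)


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write TSV/CSV (by extension) or an MTX triplet (``fmt='mtx'``)."""
    path = Path(path)
    if fmt == "mtx" or path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), sp.csr_matrix(expr.values))
        path.with_name("genes.txt").write_text("\n".join(expr.gene_ids) + "\n")
        path.with_name("cells.txt").write_text("\n".join(expr.cell_ids) + "\n")
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        expr.to_frame().to_csv(path, sep=sep)


def read_labels(path, sep: str = "\t") -> pd.Series:
    """Read a two-column (cell_id, label) table as a Series."""
    frame = pd.read_csv(path, sep=sep, index_col=0, header=None,
                        names=["cell_id", "label"], skiprows=_label_skiprows(path, sep))
    return frame["label"]


def _label_skiprows(path, sep) -> int:
    with open(path) as fh:
        first = fh.readline()
    head = first.strip().split(sep)
    return 1 if head[:1] == ["cell_id"] else 0


def write_labels(cell_ids, labels, path, sep: str = "\t") -> None:
    pd.Series(np.asarray(labels), index=cell_ids).to_csv(
        path, sep=sep, header=False)


def write_adjacency(adj: NormalizedAdjacency, path) -> None:
    """Persist a normalized adjacency as MTX plus a gene-order file."""
    path = Path(path)
    scipy.io.mmwrite(str(path), adj.matrix)
    path.with_name("adjacency_genes.txt").write_text(
        "\n".join(adj.gene_order) + "\n")


def read_adjacency(path) -> NormalizedAdjacency:
    path = Path(path)
    mat = scipy.io.mmread(path).tocsc()
    genes = _read_ids(path.with_name("adjacency_genes.txt"))
    if mat.shape != (len(genes), len(genes)):
        raise ValueError(f"{path}: matrix/gene-order size mismatch")
    return NormalizedAdjacency(mat, genes)


class StageRecord(BaseModel):
    """Per-stage provenance entry in a run report."""

    name: str
    wall_time_s: float = Field(ge=0)
    counts: dict[str, float] = Field(default_factory=dict)


class RunReport(BaseModel):
    """Machine-readable provenance for a pipeline run."""

    package_version: str
    config: dict
    stages: list[StageRecord]
    created_unix: float


#: JSON schema for run reports (shipped for external validators).
RUN_REPORT_SCHEMA = RunReport.model_json_schema()


def run_report(config: dict, stages: list[StageRecord]) -> dict:
    """Assemble and validate a run report; returns a JSON-ready dict."""
    from . import __version__

    report = RunReport(package_version=__version__, config=config,
                       stages=stages, created_unix=time.time())
    return json.loads(report.model_dump_json())
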