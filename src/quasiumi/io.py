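"""Readers and writers for the matrix formats the tool touches.

Supported formats:

* MatrixMarket coordinate files (``.mtx``), via :mod:`scipy.io`;
* 10x-style triplet directories (``matrix.mtx[.gz]`` plus
  ``features.tsv[.gz]`` / ``genes.tsv[.gz]`` and ``barcodes.tsv[.gz]``);
* dense CSV with genes as rows and a header of cell ids.

Writing is deterministic: sparse entries are emitted column-major with
ascending rows, integer layers as integers, real layers with 10 significant
digits, and gzip members carry a zeroed timestamp.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError
from .matrix import CountMatrix, default_ids

FORMATS = ("mtx", "tenx_dir", "csv")


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "tenx_dir"
    name = path.name
    if name.endswith(".mtx") or name.endswith(".mtx.gz"):
        return "mtx"
    if name.endswith(".csv") or name.endswith(".csv.gz"):
        return "csv"
    raise FormatError(f"cannot detect matrix format of {path}")


def _open_maybe_gzip(path: Path, mode: str):
    if str(path).endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps gzip output byte-stable.
            return gzip.GzipFile(filename="", mode=mode, fileobj=open(path, "wb"), mtime=0)
        return gzip.open(path, mode)
    return open(path, mode)


def _read_mm(path: Path) -> sp.csc_array:
    try:
        with _open_maybe_gzip(path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # scipy raises ValueError with line context
        raise FormatError(f"failed to parse MatrixMarket file {path}: {exc}") from exc
    return sp.csc_array(mat)


def _first_existing(directory: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FormatError(f"none of {names} found in {directory}")


def read_matrix(
    path,
    format: str = "auto",
    layer: str = "other",
    transpose: bool = False,
) -> CountMatrix:
    """Load a gene x cell matrix from ``mtx``, a 10x directory, or CSV.

    ``transpose`` applies to CSV files laid out cells-as-rows. Plain ``.mtx``
    files carry no identifiers, so synthetic gene/cell ids are generated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in FORMATS:
        raise InputError(f"unknown format {fmt!r}; expected one of {FORMATS}")

    if fmt == "mtx":
        values = _read_mm(path)
        if transpose:
            values = sp.csc_array(values.T)
        return CountMatrix(
            values,
            default_ids("gene", values.shape[0]),
            default_ids("cell", values.shape[1]),
            layer,
        )

    if fmt == "tenx_dir":
        mtx = _first_existing(path, ("matrix.mtx", "matrix.mtx.gz"))
        feats = _first_existing(
            path, ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
        )
        bars = _first_existing(path, ("barcodes.tsv", "barcodes.tsv.gz"))
        values = _read_mm(mtx)
        try:
            features = pd.read_csv(feats, sep="\t", header=None, dtype=str)
            barcodes = pd.read_csv(bars, sep="\t", header=None, dtype=str)
        except Exception as exc:
            raise FormatError(f"failed to parse 10x sidecar files in {path}: {exc}") from exc
        gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
        cell_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)
        return CountMatrix(values, gene_ids, cell_ids, layer)

    try:
        frame = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise FormatError(f"failed to parse CSV file {path}: {exc}") from exc
    if transpose:
        frame = frame.T
    return CountMatrix(
        frame.to_numpy(dtype=float),
        frame.index.to_numpy(dtype=object),
        frame.columns.to_numpy(dtype=object),
        layer,
    )


def _write_mm(matrix: CountMatrix, path: Path) -> None:
    coo = matrix.values.tocoo()
    order = np.lexsort((coo.row, coo.col))  # column-major, ascending row
    data = coo.data[order]
    canonical = sp.coo_matrix(
        (data, (coo.row[order], coo.col[order])), shape=matrix.shape
    )
    integer = matrix.layer in ("umi", "qumi") or np.issubdtype(data.dtype, np.integer)
    with _open_maybe_gzip(path, "wb") as fh:
        scipy.io.mmwrite(
            fh,
            canonical,
            field="integer" if integer else "real",
            precision=10,
            symmetry="general",
        )


def write_matrix(matrix: CountMatrix, path, format: str = "auto") -> None:
    """Write a matrix as ``mtx``, a 10x triplet directory, or CSV.

    Writing the same matrix twice produces byte-identical output.
    """
    path = Path(path)
    if format == "auto":
        name = path.name
        if name.endswith(".mtx") or name.endswith(".mtx.gz"):
            format = "mtx"
        elif name.endswith(".csv") or name.endswith(".csv.gz"):
            format = "csv"
        else:
            format = "tenx_dir"
    if format not in FORMATS:
        raise InputError(f"unknown format {format!r}; expected one of {FORMATS}")

    if format == "mtx":
        _write_mm(matrix, path)
        return

    if format == "tenx_dir":
        os.makedirs(path, exist_ok=True)
        _write_mm(matrix, path / "matrix.mtx")
        features = pd.DataFrame(
            {
                0: matrix.gene_ids,
                1: matrix.gene_ids,
                2: ["Gene Expression"] * matrix.n_genes,
            }
        )
        features.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({0: matrix.cell_ids}).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        return

    dense = matrix.toarray()
    frame = pd.DataFrame(dense, index=matrix.gene_ids, columns=matrix.cell_ids)
    if np.issubdtype(dense.dtype, np.integer):
        frame.to_csv(path)
    else:
        frame.to_csv(path, float_format="%.10g")
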