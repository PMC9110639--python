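"""Expression-matrix container and plain-text I/O.

The package's canonical orientation is genes as rows and cells as columns.
Counts or TPM values are admissible; entries must be finite and non-negative,
with dropout encoded as an explicit 0 (never NaN).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "sparsity",
    "log_transform",
    "inverse_log_transform",
]


@dataclass
class ExpressionMatrix:
    """A genes x cells non-negative expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Non-negative expression values (counts or TPM).
    gene_ids : list of str
        Unique row identifiers.
    cell_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default=None)
    cell_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        m, n = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = [f"gene{i + 1}" for i in range(m)]
        if self.cell_ids is None:
            self.cell_ids = [f"cell{j + 1}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} columns")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen, dup = set(), None
                for x in ids:
                    if x in seen:
                        dup = x
                        break
                    seen.add(x)
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at gene {self.gene_ids[i]!r}, "
                f"cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def sparsity(self) -> float:
        """Fraction of entries that are exactly zero."""
        return float(np.count_nonzero(self.values == 0) / self.values.size)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids), list(self.cell_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


_DELIMS = {"dense-csv": ",", "dense-tsv": "\t"}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        return "dense-csv"
    if ext in (".tsv", ".txt", ".tab"):
        return "dense-tsv"
    if ext == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from extension {ext!r}; pass format=")


def read_matrix(path, format: str | None = None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from dense CSV/TSV or Matrix Market.

    Dense files carry cell ids in the header row and gene ids in the first
    column. MTX files use standard 1-based coordinate format with one-id-per-line
    ``genes.txt`` and ``barcodes.txt`` sidecars in the same directory.

    Parameters
    ----------
    path : str or Path
    format : {"dense-csv", "dense-tsv", "mtx"}, optional
        Inferred from the extension when omitted.
    transpose : bool
        Set when the file stores cells as rows.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in _DELIMS:
        delim = _DELIMS[fmt]
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        ncol = len(header.split(delim))
        if ncol < 2:
            raise ValueError(f"malformed header line (needs >= 2 fields): {header!r}")
        try:
            df = pd.read_csv(path, sep=delim, index_col=0)
        except Exception as exc:  # surface pandas' line diagnostics
            raise ValueError(f"could not parse {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ValueError(f"no data columns found in {path}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
        em = ExpressionMatrix(values, list(df.index), list(df.columns))
    elif fmt == "mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        d = os.path.dirname(path)
        gene_ids = cell_ids = None
        gpath, cpath = os.path.join(d, "genes.txt"), os.path.join(d, "barcodes.txt")
        if os.path.exists(gpath):
            gene_ids = [ln.strip() for ln in open(gpath) if ln.strip()]
        if os.path.exists(cpath):
            cell_ids = [ln.strip() for ln in open(cpath) if ln.strip()]
        em = ExpressionMatrix(values, gene_ids, cell_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        em = ExpressionMatrix(em.values.T, em.cell_ids, em.gene_ids)
    return em


def write_matrix(matrix: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a matrix as dense CSV/TSV or Matrix Market with id sidecars."""
    path = str(path)
    fmt = format or _infer_format(path)
    if fmt in _DELIMS:
        matrix.to_frame().to_csv(path, sep=_DELIMS[fmt])
    elif fmt == "mtx":
        coo = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(path, coo)
        d = os.path.dirname(path)
        with open(os.path.join(d, "genes.txt"), "w") as fh:
            fh.write("\n".join(matrix.gene_ids) + "\n")
        with open(os.path.join(d, "barcodes.txt"), "w") as fh:
            fh.write("\n".join(matrix.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def sparsity(matrix: ExpressionMatrix | np.ndarray) -> float:
    """Exact zero-entry fraction of a matrix, in [0, 1]."""
    if isinstance(matrix, ExpressionMatrix):
        return matrix.sparsity()
    a = np.asarray(matrix)
    return float(np.count_nonzero(a == 0) / a.size)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise z = log(1 + y). Zeros map to zeros, so sparsity is preserved."""
    return ExpressionMatrix(np.log1p(matrix.values), list(matrix.gene_ids), list(matrix.cell_ids))


def inverse_log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise y = exp(z) - 1, with tiny negative round-off clipped to 0."""
    vals = np.expm1(matrix.values)
    vals[vals < 0] = 0.0
    return ExpressionMatrix(vals, list(matrix.gene_ids), list(matrix.cell_ids))
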