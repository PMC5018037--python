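"""Readers and writers for the standard on-disk formats.

Dense matrices travel as delimited text (TSV/CSV, optional header row with
feature names); sparse count matrices as MatrixMarket coordinate files
(1-based indices on disk per the MatrixMarket convention, 0-based in
memory).  Loadings are written as TSV at full precision, traces as CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .core import DataMatrix, InputError
from .solver import Trace

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "write_loadings",
    "write_trace",
]


class ParseError(ValueError):
    """A file could not be parsed as the requested format."""


_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv", "mtx"):
            raise InputError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx"):
        return suffix
    raise InputError(f"cannot infer format from suffix of {path.name!r}; pass format=")


def read_matrix(
    path: str | Path,
    format: str | None = None,
    orientation: str = "samples_by_features",
) -> DataMatrix:
    """Read a samples-by-features matrix from TSV/CSV (dense) or MTX (sparse).

    Dense files may carry a header row of feature names (detected when the
    first row has any non-numeric token); rows are samples.  Parse problems
    (ragged rows, non-numeric cells) raise :class:`ParseError` naming the
    offending line.
    """
    if orientation != "samples_by_features":
        raise InputError(f"unsupported orientation {orientation!r}")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        try:
            mat = spio.mmread(path)
        except (ValueError, TypeError, OSError) as exc:
            raise ParseError(f"{path.name}: invalid MatrixMarket file: {exc}") from exc
        return DataMatrix(sparse.csr_array(mat))

    delim = _DELIMS[fmt]
    rows: list[list[float]] = []
    names: list[str] | None = None
    width: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            tokens = line.split(delim)
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise ParseError(
                    f"{path.name}:{lineno}: ragged row ({len(tokens)} fields, expected {width})"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                if lineno == 1 and not rows:
                    names = [t.strip() for t in tokens]
                    continue
                bad = next(t for t in tokens if not _is_number(t))
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric cell {bad!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path.name}: no data rows")
    return DataMatrix(np.asarray(rows, dtype=np.float64), feature_names=names)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_matrix(path: str | Path, data: DataMatrix, format: str | None = None) -> None:
    """Write a DataMatrix: MTX for sparse storage, TSV/CSV for dense."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "mtx":
        if not data.is_sparse:
            raise InputError("MTX output is for sparse matrices; use tsv/csv for dense")
        spio.mmwrite(path, sparse.coo_array(data.values))
        return
    delim = _DELIMS[fmt]
    with open(path, "w", encoding="utf-8") as fh:
        if data.feature_names is not None:
            fh.write(delim.join(data.feature_names) + "\n")
        X = data.values.toarray() if data.is_sparse else data.values
        for row in X:
            fh.write(delim.join(f"{x:.17g}" for x in row) + "\n")


def _default_names(d: int) -> list[str]:
    width = max(4, len(str(d)))
    return [f"f{j + 1:0{width}d}" for j in range(d)]


def write_loadings(
    path: str | Path,
    loadings: np.ndarray,
    feature_names: list[str] | None = None,
) -> None:
    """Write a d-vector or d-by-p loading matrix as TSV at full precision.

    Columns: feature, loading_1, ..., loading_p; rows in input feature
    order, so the file supports feature-label + loading-value reporting.
    """
    L = np.asarray(loadings, dtype=np.float64)
    if L.ndim == 1:
        L = L[:, None]
    if L.ndim != 2:
        raise InputError("loadings must be a vector or a 2-D matrix")
    d, p = L.shape
    if feature_names is None:
        feature_names = _default_names(d)
    elif len(feature_names) != d:
        raise InputError(f"feature_names has length {len(feature_names)}, expected {d}")
    with open(path, "w", encoding="utf-8") as fh:
        header = ["feature"] + [f"loading_{j + 1}" for j in range(p)]
        fh.write("\t".join(header) + "\n")
        for name, row in zip(feature_names, L):
            fh.write(name + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write per-epoch diagnostics as CSV (epoch,objective,grad_norm,nnz,vk_variance)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(["epoch", "objective", "grad_norm", "nnz", "vk_variance"])
        for r in trace:
            wr.writerow(
                [r.epoch, f"{r.objective:.17g}", f"{r.grad_norm:.17g}", r.nnz,
                 f"{r.vk_variance:.17g}"]
            )
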