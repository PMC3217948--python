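"""Reading, writing and scale normalization of expression matrices.

Matrices are plain TSV/CSV: first column gene ids, header row sample ids,
numeric body. Writers prepend a ``#``-comment provenance header; readers
skip such lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, FractionTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_fraction_table",
    "write_fraction_table",
    "linearize",
    "trimmed_mean_scale",
    "trimmed_mean",
]


def _read_frame(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    # pandas silently renames duplicated header columns, so check the raw header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(delimiter)[1:]
                break
        else:
            raise ValueError(f"{path}: empty matrix body")
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise ValueError(f"{path}: duplicate sample ids {sorted(dups)[:5]}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    if frame.empty:
        raise ValueError(f"{path}: empty matrix body")
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(frame[col], errors="coerce")
        row = frame.index[coerced.isna().argmax()]
        raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_matrix(
    path: str | Path, delimiter: str = "\t", scale: str = "linear"
) -> ExpressionMatrix:
    """Read a gene-by-sample matrix; duplicate gene ids collapse by row-wise max."""
    frame = _read_frame(path, delimiter)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        logger.warning(
            "collapsing %d duplicated gene ids by per-sample max (e.g. %s)",
            len(dups),
            dups[:3],
        )
        frame = frame.groupby(level=0, sort=False).max()
    return ExpressionMatrix(frame, scale=scale)


def _provenance(note: str) -> str:
    return f"# qpdecon v{__version__} | {note}\n"


def write_matrix(
    X: ExpressionMatrix, path: str | Path, delimiter: str = "\t", note: str = ""
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(f"scale={X.scale}" + (f" | {note}" if note else "")))
        X.data.to_csv(fh, sep=delimiter, index_label="gene_id")


def read_fraction_table(
    path: str | Path, delimiter: str = "\t", simplex: bool = True
) -> FractionTable:
    frame = _read_frame(path, delimiter)
    return FractionTable(frame, simplex=simplex)


def write_fraction_table(
    table: FractionTable, path: str | Path, delimiter: str = "\t", note: str = ""
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance(f"simplex={table.simplex}" + (f" | {note}" if note else "")))
        table.data.to_csv(fh, sep=delimiter, index_label="sample_id")


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, type) table into a Series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly two columns (sample_id, type)")
    series = frame.iloc[:, 0].astype(str)
    series.index = series.index.astype(str)
    return series


def write_labels(labels: pd.Series, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance("sample type labels"))
        labels.rename("type").to_csv(fh, sep=delimiter, index_label="sample_id")


def read_signature(path: str | Path, delimiter: str = "\t"):
    from .containers import SignatureMatrix

    return SignatureMatrix(_read_frame(path, delimiter))


def write_signature(S, path: str | Path, delimiter: str = "\t", note: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(note or "signature matrix (genes x types)"))
        S.data.to_csv(fh, sep=delimiter, index_label="gene_id")


def write_fractions(A, path: str | Path, delimiter: str = "\t", note: str = "") -> None:
    """Write estimated fractions plus a trailing residual_norm column."""
    out = A.data.copy()
    out["residual_norm"] = A.residual_norm
    with open(path, "w") as fh:
        fh.write(_provenance(note or "estimated mixing fractions"))
        out.to_csv(fh, sep=delimiter, index_label="sample_id")


def read_fractions(path: str | Path, delimiter: str = "\t"):
    from .containers import FractionMatrix

    frame = _read_frame(path, delimiter)
    residual = None
    if "residual_norm" in frame.columns:
        residual = frame.pop("residual_norm")
    return FractionMatrix(frame, residual_norm=residual)


def read_aggregation_map(path: str | Path, delimiter: str = "\t") -> dict:
    """Read a two-column (subtype, major_type) mapping."""
    series = read_labels(path, delimiter)
    return dict(series)


def linearize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform log2 values to the linear scale (v -> 2**v).

    The deconvolution model is linear in intensities, so all mixing math
    operates on untransformed data. Applying to an already-linear matrix is
    an identity and warns.
    """
    if X.scale == "linear":
        logger.warning("linearize called on a linear-scale matrix; returning unchanged")
        return ExpressionMatrix(X.data.copy(), scale="linear")
    return ExpressionMatrix(np.exp2(X.data), scale="linear")


def trimmed_mean(values: np.ndarray, trim_frac: float = 0.02) -> float:
    """Mean after discarding ``floor(trim_frac * n)`` values from each tail."""
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(trim_frac * v.size))
    if 2 * k >= v.size:
        raise ValueError("trim fraction leaves no values")
    return float(v[k : v.size - k].mean())


def trimmed_mean_scale(
    X: ExpressionMatrix, trim_frac: float = 0.02, target: float = 150.0
) -> ExpressionMatrix:
    """Scale each sample so its trimmed mean equals ``target``.

    This is the per-array normalization applied after summarization: each
    column is multiplied by ``target / trimmed_mean(column)``, equating a
    robust mean intensity across arrays. Idempotent up to float round-off.
    """
    if X.scale != "linear":
        raise ValueError("trimmed_mean_scale requires a linear-scale matrix")
    scaled = X.data.copy()
    for sample in scaled.columns:
        tm = trimmed_mean(scaled[sample].to_numpy(), trim_frac)
        if tm <= 0:
            raise ValueError(f"sample {sample!r}: trimmed mean {tm} <= 0, cannot scale")
        scaled[sample] *= target / tm
    return ExpressionMatrix(scaled, scale="linear")
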