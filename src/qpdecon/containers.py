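"""Core data containers for expression deconvolution.

All containers wrap a labelled :class:`pandas.DataFrame` and validate the
invariants the deconvolution math relies on (unique ids, matching shapes,
non-negativity on the linear scale, simplex rows for fractions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PureProfileSet",
    "FractionTable",
    "SignatureMatrix",
    "FractionMatrix",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression intensities.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns.
    scale
        ``"linear"`` for untransformed intensities (all values must be >= 0)
        or ``"log2"`` for log2-transformed values.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "linear" and values.size and values.min() < 0:
            raise ValueError("linear-scale expression matrix has negative values")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PureProfileSet:
    """Replicated pure-cell-type reference profiles.

    ``types`` maps every sample id of ``expr`` to a cell-type label; the
    labelled replicates are the training data from which the signature
    (basis) matrix is estimated.
    """

    expr: ExpressionMatrix
    types: pd.Series  # sample_id -> cell-type label

    def __post_init__(self) -> None:
        self.types = pd.Series(self.types)
        missing = [s for s in self.expr.sample_ids if s not in self.types.index]
        if missing:
            raise ValueError(f"samples without a cell-type label: {missing[:5]}")
        self.types = self.types.loc[self.expr.sample_ids]
        if self.types.nunique() < 2:
            raise ValueError("need at least 2 distinct cell types")

    @property
    def type_labels(self) -> list[str]:
        # first-appearance order of labels across samples
        return list(dict.fromkeys(self.types))

    def samples_of(self, label: str) -> list[str]:
        sel = self.types[self.types == label]
        if sel.empty:
            raise KeyError(f"unknown cell type {label!r}")
        return list(sel.index)

    def type_means(self) -> pd.DataFrame:
        """Mean linear-scale expression per type (genes x types)."""
        cols = {
            lab: self.expr.data[self.samples_of(lab)].mean(axis=1)
            for lab in self.type_labels
        }
        return pd.DataFrame(cols)


@dataclass
class FractionTable:
    """Known/design mixing fractions or reference counts (samples x types).

    ``simplex`` states whether rows are expected to lie on the unit simplex;
    reference count tables (e.g. CBC-style) may not sum to one and are
    flagged ``simplex=False``.
    """

    data: pd.DataFrame
    simplex: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "type labels")
        values = self.data.to_numpy(dtype=float)
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValueError("fraction entries must lie in [0, 1]")
        if self.simplex:
            sums = values.sum(axis=1)
            if values.size and not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.index[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"row {bad!r} does not sum to 1 (got {sums.max():.6f}/{sums.min():.6f})")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def type_labels(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SignatureMatrix:
    """Basis matrix S: mean linear-scale expression per cell type (genes x types).

    Serves as the design matrix of the linear mixing model; it must be
    overdetermined (more genes than types) and is expected to have full
    column rank (a warning is emitted otherwise).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "type labels")
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValueError("signature matrix has negative values")
        n_genes, n_types = values.shape
        if n_genes <= n_types:
            raise ValueError(
                f"signature must be overdetermined: {n_genes} genes <= {n_types} types"
            )
        if np.linalg.matrix_rank(values) < n_types:
            warnings.warn("signature matrix is rank-deficient", stacklevel=2)
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def type_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class FractionMatrix:
    """Estimated mixing fractions (samples x types), rows on the unit simplex."""

    data: pd.DataFrame
    residual_norm: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "type labels")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if values.min() < -1e-9:
                raise ValueError("fraction matrix has negative entries beyond round-off")
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("fraction matrix rows must sum to 1 within 1e-8")
        if self.residual_norm is None:
            self.residual_norm = pd.Series(np.nan, index=self.data.index)
        else:
            self.residual_norm = pd.Series(self.residual_norm).loc[self.data.index]
            finite = self.residual_norm.dropna()
            if (finite < 0).any():
                raise ValueError("residual norms must be non-negative")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def type_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()
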