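"""Per-sample deconvolution of mixed expression into cell-type fractions.

Each mixed sample is solved independently: its expression over the
signature genes is regressed on the basis matrix under sum-to-one and
non-negativity constraints, yielding mRNA mixing fractions directly.
Fine-grained fractions can then be aggregated into major cell classes
(e.g. 17 leukocyte subtypes into lymphocytes/monocytes/neutrophils) for
comparison with complete-blood-count style references.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FractionMatrix, SignatureMatrix
from .qp import solve_simplex_lsq

logger = logging.getLogger(__name__)

__all__ = ["solve_fractions", "deconvolve", "aggregate", "AggregationMap"]

#: subtype label -> major-type label; must cover every signature type exactly once
AggregationMap = dict


def solve_fractions(
    x: np.ndarray, S: SignatureMatrix
) -> tuple[np.ndarray, float]:
    """Estimate one sample's mixing fractions from its signature-gene vector.

    Thin, validated wrapper over the simplex-constrained QP; returns the
    globally optimal fraction vector and the residual norm ||S a - x||.
    """
    return solve_simplex_lsq(S.values, np.asarray(x, dtype=float))


def deconvolve(
    X: ExpressionMatrix,
    S: SignatureMatrix,
    min_overlap: float = 0.5,
    condition_warn: float = 1e6,
) -> FractionMatrix:
    """Estimate mixing fractions for every sample of ``X``.

    Genes are aligned by id; at least ``min_overlap`` of the signature's
    genes must be present in ``X``. Samples are solved independently, so
    results do not depend on sample order.
    """
    if X.scale != "linear":
        raise ValueError("deconvolution operates on linear-scale data; linearize first")
    shared = [g for g in S.gene_ids if g in X.data.index]
    frac = len(shared) / len(S.gene_ids)
    if frac < min_overlap:
        missing = len(S.gene_ids) - len(shared)
        raise ValueError(
            f"only {len(shared)}/{len(S.gene_ids)} signature genes present in the "
            f"expression matrix ({missing} missing); need >= {min_overlap:.0%}"
        )
    logger.info("gene overlap: %d/%d signature genes", len(shared), len(S.gene_ids))
    S_sub = SignatureMatrix(S.data.loc[shared])
    kappa = np.linalg.cond(S_sub.values)
    if kappa > condition_warn:
        logger.warning("aligned basis is ill-conditioned (condition number %.3g)", kappa)

    rows = {}
    residuals = {}
    X_sub = X.data.loc[shared]
    for sample in X.sample_ids:
        a, r = solve_simplex_lsq(S_sub.values, X_sub[sample].to_numpy())
        rows[sample] = a
        residuals[sample] = r
    data = pd.DataFrame.from_dict(rows, orient="index", columns=S.type_labels)
    data = data.loc[X.sample_ids]
    return FractionMatrix(data, residual_norm=pd.Series(residuals))


def aggregate(A: FractionMatrix, mapping: AggregationMap) -> FractionMatrix:
    """Sum subtype fractions into major-type fractions; rows stay on the simplex."""
    unmapped = [t for t in A.type_labels if t not in mapping]
    if unmapped:
        raise ValueError(f"subtypes without a major-type mapping: {unmapped[:5]}")
    majors = list(dict.fromkeys(mapping[t] for t in A.type_labels))
    out = pd.DataFrame(0.0, index=A.data.index, columns=majors)
    for subtype in A.type_labels:
        out[mapping[subtype]] += A.data[subtype]
    return FractionMatrix(out, residual_norm=A.residual_norm)
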