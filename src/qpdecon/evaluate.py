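"""Accuracy metrics, group tests and robustness simulation protocols.

The robustness protocols stress the signature matrix the way real data
would: (a) random subsets of the differentially expressed pool, (b) a
sweep of signature sizes, and (c) multiplicative fold-change distortion
of a percentage of basis genes. Each records, per replicate and grid
point, the Pearson correlation between estimated and true fractions
pooled over all (sample, type) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    FractionMatrix,
    FractionTable,
    PureProfileSet,
    SignatureMatrix,
)
from .deconvolve import deconvolve
from .signature import build_basis, condition_number

__all__ = [
    "pearson",
    "rmsd",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "RobustnessResult",
    "robustness_subset",
    "robustness_size_sweep",
    "robustness_perturbation",
]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in input")
    return float(stats.pearsonr(a, b).statistic)


def _align(est: FractionMatrix, truth: FractionTable) -> tuple[np.ndarray, np.ndarray]:
    if set(est.sample_ids) != set(truth.sample_ids):
        raise ValueError("sample ids of estimate and truth do not match")
    if set(est.type_labels) != set(truth.type_labels):
        raise ValueError("type labels of estimate and truth do not match")
    t = truth.data.loc[est.sample_ids, est.type_labels]
    return est.data.to_numpy(), t.to_numpy()


def rmsd(est: FractionMatrix, truth: FractionTable) -> float:
    """Root mean square deviation over all (sample, type) cells."""
    e, t = _align(est, truth)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def pooled_pearson(est: FractionMatrix, truth: FractionTable) -> float:
    """Pearson correlation with all (sample, type) cells pooled."""
    e, t = _align(est, truth)
    return pearson(e.ravel(), t.ravel())


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 when there are no ties among |differences|; otherwise the
    normal approximation with continuity correction and average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney/rank-sum p-value (unpaired variant)."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


@dataclass
class RobustnessResult:
    """Per-replicate correlations over a protocol's parameter grid."""

    protocol: str
    grid: list  # one entry per grid point (size, or (pct, fold))
    correlations: np.ndarray  # shape (reps, len(grid))
    condition_numbers: np.ndarray | None = None  # same shape, perturbation only
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        q1, med, q3 = np.percentile(self.correlations, [25, 50, 75], axis=0)
        out = pd.DataFrame(
            {"grid": [str(g) for g in self.grid], "q1": q1, "median": med, "q3": q3}
        )
        if self.condition_numbers is not None:
            out["median_condition_number"] = np.median(self.condition_numbers, axis=0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Full per-replicate table (no summary-only output)."""
        records = []
        reps = self.correlations.shape[0]
        for j, g in enumerate(self.grid):
            for r in range(reps):
                rec = {"grid": str(g), "replicate": r, "correlation": self.correlations[r, j]}
                if self.condition_numbers is not None:
                    rec["condition_number"] = self.condition_numbers[r, j]
                records.append(rec)
        return pd.DataFrame.from_records(records)


def robustness_subset(
    pool: list[str],
    pure: PureProfileSet,
    data: ExpressionMatrix,
    truth: FractionTable,
    sizes: tuple[int, ...] = (100, 200),
    reps: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Random-subset protocol: rebuild the basis from random draws of the
    differentially expressed pool and measure recovery correlation."""
    if max(sizes) > len(pool):
        raise ValueError(f"pool of {len(pool)} genes smaller than size {max(sizes)}")
    rng = np.random.default_rng(seed)
    corrs = np.empty((reps, len(sizes)))
    for j, size in enumerate(sizes):
        for r in range(reps):
            subset = list(rng.choice(pool, size=size, replace=False))
            basis = build_basis(pure, subset)
            est = deconvolve(data, basis)
            corrs[r, j] = pooled_pearson(est, truth)
    return RobustnessResult(
        protocol="subset",
        grid=list(sizes),
        correlations=corrs,
        metadata={"reps": reps, "seed": seed, "pool_size": len(pool)},
    )


def robustness_size_sweep(
    ranking: list[str],
    pure: PureProfileSet,
    data: ExpressionMatrix,
    truth: FractionTable,
    sizes: list[int] | None = None,
) -> RobustnessResult:
    """Size-sweep protocol: top-m bases for increasing m (deterministic)."""
    import warnings as _warnings

    if sizes is None:
        sizes = list(range(40, 1001, 20))
    sizes = sorted(sizes)
    if sizes[-1] > len(ranking):
        _warnings.warn(
            f"sizes beyond ranking length {len(ranking)} truncated", stacklevel=2
        )
        sizes = [m for m in sizes if m <= len(ranking)]
        if not sizes:
            raise ValueError("ranking shorter than every requested size")
    corrs = np.empty((1, len(sizes)))
    kappas = np.empty((1, len(sizes)))
    for j, m in enumerate(sizes):
        basis = build_basis(pure, ranking[:m])
        kappas[0, j] = condition_number(basis)
        est = deconvolve(data, basis)
        corrs[0, j] = pooled_pearson(est, truth)
    return RobustnessResult(
        protocol="size_sweep",
        grid=sizes,
        correlations=corrs,
        condition_numbers=kappas,
        metadata={"ranking_length": len(ranking)},
    )


def perturb_basis(
    S: SignatureMatrix, pct: float, fold: float, rng: np.random.Generator
) -> SignatureMatrix:
    """Distort ceil(pct * n_genes) whole basis rows by a factor of
    ``fold`` or ``1/fold`` (equal probability) — a gene-level distortion
    applied across all types."""
    if not 0 < pct < 1:
        raise ValueError(f"pct must lie in (0, 1), got {pct}")
    n = len(S.gene_ids)
    k = math.ceil(pct * n)
    rows = rng.choice(n, size=k, replace=False)
    factors = rng.choice([fold, 1.0 / fold], size=k)
    values = S.data.copy()
    values.iloc[rows] = values.iloc[rows].mul(factors, axis=0)
    return SignatureMatrix(values)


def robustness_perturbation(
    S: SignatureMatrix,
    data: ExpressionMatrix,
    truth: FractionTable,
    pcts: tuple[float, ...] = (0.05, 0.10, 0.15),
    fold: float = 2.0,
    reps: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Fold-change perturbation protocol: distort a percentage of basis
    genes, deconvolve with the distorted basis, and record both recovery
    correlation and the distorted basis' condition number.

    Draws are coupled across percentages (common random numbers): each
    replicate fixes one random gene order and per-gene fold sequence, and
    every percentage distorts a prefix of it, so a larger percentage is a
    strict superset of a smaller one and the effect of increasing
    distortion is not confounded by resampling noise."""
    for pct in pcts:
        if not 0 < pct < 1:
            raise ValueError(f"pct must lie in (0, 1), got {pct}")
    rng = np.random.default_rng(seed)
    n = len(S.gene_ids)
    corrs = np.empty((reps, len(pcts)))
    kappas = np.empty((reps, len(pcts)))
    for r in range(reps):
        order = rng.permutation(n)
        factors = rng.choice([fold, 1.0 / fold], size=n)
        for j, pct in enumerate(pcts):
            k = math.ceil(pct * n)
            values = S.data.copy()
            values.iloc[order[:k]] = values.iloc[order[:k]].mul(factors[:k], axis=0)
            distorted = SignatureMatrix(values)
            kappas[r, j] = condition_number(distorted)
            est = deconvolve(data, distorted)
            corrs[r, j] = pooled_pearson(est, truth)
    return RobustnessResult(
        protocol="perturbation",
        grid=[(pct, fold) for pct in pcts],
        correlations=corrs,
        condition_numbers=kappas,
        metadata={
            "reps": reps,
            "seed": seed,
            "fold_rule": "whole basis row multiplied by fold or 1/fold, equal probability",
        },
    )
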