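"""Construction of the cell-type signature (basis) matrix from pure profiles.

The pipeline mirrors standard marker-based basis construction for
expression deconvolution:

1. range-filter genes whose per-type mean intensity falls outside the
   array's reliable linear range (default 0.1–5000);
2. pairwise empirical-Bayes moderated t-tests between pure types on the
   log2 scale, with Benjamini–Hochberg FDR control per contrast;
3. rank significant genes by their largest absolute moderated t;
4. sweep candidate signature sizes over the ranking and pick the size at
   the first local minimum of the basis matrix's 2-norm condition number —
   a well-conditioned basis makes the downstream linear system least
   sensitive to measurement error.

The moderated t follows the empirical-Bayes variance-shrinkage model of
Smyth (2004): per-gene pooled variances s_g^2 with d_g degrees of freedom
are assumed to follow a scaled F distribution around a prior variance
s_0^2 with d_0 prior degrees of freedom; (d_0, s_0^2) are estimated by
moment-matching on log s_g^2, and the posterior variance

    s~_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

replaces s_g^2 in the t statistic, which then has d_0 + d_g degrees of
freedom.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, FractionTable, PureProfileSet, SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_expression_range",
    "moderated_t",
    "bh_fdr",
    "candidate_ranking",
    "build_basis",
    "condition_number",
    "select_signature",
    "BasisSelectionTrace",
    "fit_f_dist",
    "trigamma_inverse",
]

_LOG_FLOOR = 1e-8  # linear intensities are clipped here before log2


def filter_expression_range(
    pure: PureProfileSet, lo: float = 0.1, hi: float = 5000.0
) -> list[str]:
    """Genes whose per-type mean expression lies in [lo, hi] for every type.

    Extremely low or high intensities sit outside the microarray's linear
    response range and would distort the basis.
    """
    if pure.expr.scale != "linear":
        raise ValueError("range filter operates on linear-scale data")
    means = pure.type_means()
    keep = means.apply(lambda row: row.between(lo, hi).all(), axis=1)
    genes = list(means.index[keep])
    if not genes:
        raise ValueError(
            f"no gene has all type means within [{lo}, {hi}]; widen the bounds"
        )
    return genes


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if not np.isfinite(x) or x <= 0:
        raise ValueError(f"trigamma_inverse requires x > 0, got {x}")
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-14 * abs(y):
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F model to sample variances with common df.

    Returns (d0, s0_squared): the prior degrees of freedom and prior
    variance of the empirical-Bayes hierarchy. Under the model,
    log(s_g^2) has a shifted log-F distribution; matching its mean and
    variance through digamma/trigamma identities yields the prior.
    An underdispersed variance distribution gives d0 = inf (all variances
    shrunk to the common value).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size == 0:
        raise ValueError("all sample variances are zero; cannot fit prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    if s2.size < 2:
        return np.inf, float(np.mean(s2))
    e_var = float(np.var(e, ddof=1))
    rhs = e_var - polygamma(1, df / 2.0)
    if rhs <= 0:
        # no excess dispersion beyond sampling noise: all variances shrink to
        # their common mean (d0 = inf limit)
        warnings.warn(
            "variance distribution is underdispersed; using infinite prior df",
            stacklevel=2,
        )
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _log2_groups(
    pure: PureProfileSet, type_a: str, type_b: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    samples_a = pure.samples_of(type_a)
    samples_b = pure.samples_of(type_b)
    data = pure.expr.data
    if pure.expr.scale == "linear":
        log_data = np.log2(data.clip(lower=_LOG_FLOOR))
        lin_data = data
    else:
        log_data = data
        lin_data = np.exp2(data)
    means = pd.DataFrame(
        {
            "mean_a": lin_data[samples_a].mean(axis=1),
            "mean_b": lin_data[samples_b].mean(axis=1),
        }
    )
    return log_data[samples_a].to_numpy(), log_data[samples_b].to_numpy(), means


def moderated_t(pure: PureProfileSet, type_a: str, type_b: str) -> pd.DataFrame:
    """Per-gene moderated t-test between two pure cell types.

    Testing is done on the log2 scale regardless of the input scale (the
    linear scale is kept only for the reported group means, which feed the
    basis matrix). Returns a DataFrame indexed by gene id with columns
    mean_a, mean_b, t_mod, df_total, p, fdr and attrs ``contrast`` and
    ``prior`` (d0, s0_squared).
    """
    A, B, means = _log2_groups(pure, type_a, type_b)
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 and n_b < 2:
        raise ValueError(
            f"contrast ({type_a}, {type_b}): need >= 2 replicates in at least one group"
        )
    d_g = n_a + n_b - 2
    diff = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d_g
    if not np.any(s2 > 0):
        raise ValueError("zero variance for every gene; cannot test")
    stderr_unit = np.sqrt(1.0 / n_a + 1.0 / n_b)

    if min(n_a, n_b) < 2:
        warnings.warn(
            f"contrast ({type_a}, {type_b}): a group has < 2 replicates; "
            "falling back to the ordinary pooled t-test",
            stacklevel=2,
        )
        d0, s0_sq, s2_post, df_total = 0.0, np.nan, s2, float(d_g)
    else:
        d0, s0_sq = fit_f_dist(s2, d_g)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = diff / (np.sqrt(s2_post) * stderr_unit)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no evidence either way
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = means.copy()
    table["t_mod"] = t_mod
    table["df_total"] = df_total
    table["p"] = p
    table["fdr"] = bh_fdr(p)
    table.attrs["contrast"] = (type_a, type_b)
    table.attrs["prior"] = (float(d0), float(s0_sq))
    return table


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("p-values contain NaN")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def candidate_ranking(
    pure: PureProfileSet,
    fdr_threshold: float = 1e-5,
    lo: float = 0.1,
    hi: float = 5000.0,
) -> list[str]:
    """Rank marker-candidate genes by differential-expression strength.

    Runs the moderated t for every unordered pair of cell types on the
    range-filtered genes, keeps genes significant (BH FDR below threshold)
    in at least one contrast, and sorts them by their maximum |t| over all
    contrasts, descending; ties break by gene id.
    """
    genes = filter_expression_range(pure, lo, hi)
    sub = PureProfileSet(
        ExpressionMatrix(pure.expr.data.loc[genes], scale=pure.expr.scale), pure.types
    )
    labels = pure.type_labels
    best_t = pd.Series(0.0, index=pd.Index(genes))
    min_fdr = pd.Series(np.inf, index=pd.Index(genes))
    for a, b in itertools.combinations(labels, 2):
        table = moderated_t(sub, a, b)
        best_t = np.maximum(best_t, table["t_mod"].abs())
        min_fdr = np.minimum(min_fdr, table["fdr"])
    keep = min_fdr < fdr_threshold
    if not keep.any():
        raise ValueError(
            f"no gene reaches FDR < {fdr_threshold:g} in any contrast "
            f"(minimum observed FDR: {min_fdr.min():.3g})"
        )
    scores = best_t[keep]
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    logger.info("candidate ranking: %d significant genes of %d filtered", len(order), len(genes))
    return order


def build_basis(pure: PureProfileSet, genes: list[str]) -> SignatureMatrix:
    """Basis matrix S: mean linear-scale expression per type over ``genes``."""
    if pure.expr.scale != "linear":
        raise ValueError("basis construction operates on linear-scale data")
    missing = [g for g in genes if g not in pure.expr.data.index]
    if missing:
        raise KeyError(f"genes absent from the pure profiles: {missing[:5]}")
    means = pure.type_means().loc[genes]
    return SignatureMatrix(means)


def condition_number(S: SignatureMatrix | np.ndarray) -> float:
    """2-norm condition number sigma_max / sigma_min of the basis."""
    values = S.values if isinstance(S, SignatureMatrix) else np.asarray(S, dtype=float)
    if values.shape[0] < values.shape[1]:
        raise ValueError("condition number expects n_genes >= n_types")
    sv = np.linalg.svd(values, compute_uv=False)
    rank_tol = sv[0] * max(values.shape) * np.finfo(float).eps
    if sv[-1] <= rank_tol:
        warnings.warn("rank-deficient basis: condition number is infinite", stacklevel=2)
        return np.inf
    return float(sv[0] / sv[-1])


@dataclass
class BasisSelectionTrace:
    """Condition-number sweep over candidate signature sizes."""

    sizes: list[int]
    condition_numbers: list[float]
    chosen_size: int
    rmsd_per_size: list[float] | None = None
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"size": self.sizes, "condition_number": self.condition_numbers}
        )
        if self.rmsd_per_size is not None:
            frame["rmsd"] = self.rmsd_per_size
        return frame


def _first_local_minimum(values: list[float]) -> tuple[int, str]:
    for i in range(1, len(values) - 1):
        if values[i] < values[i - 1] and values[i] < values[i + 1]:
            return i, ""
    return int(np.argmin(values)), "no local minimum; using global minimum"


def select_signature(
    pure: PureProfileSet,
    ranking: list[str],
    size_grid: list[int] | None = None,
    known_fractions: FractionTable | None = None,
    data: ExpressionMatrix | None = None,
) -> tuple[SignatureMatrix, BasisSelectionTrace]:
    """Choose the signature size minimizing the basis condition number.

    For each candidate size m the basis is built from the top-m ranked
    genes and its condition number recorded; the chosen size is the first
    local minimum along the ascending grid (global minimum if the trace is
    monotone). When ``known_fractions`` and the mixture matrix ``data`` are
    both given, the per-size deconvolution RMSD against the known fractions
    is recorded alongside.
    """
    from .deconvolve import deconvolve  # local import to avoid a cycle
    from .evaluate import rmsd

    n_types = len(pure.type_labels)
    if size_grid is None:
        size_grid = list(range(40, 1001, 20))
    size_grid = sorted(size_grid)
    if size_grid[0] <= n_types:
        raise ValueError(f"minimum signature size must exceed n_types={n_types}")
    if size_grid[-1] > len(ranking):
        warnings.warn(
            f"size grid exceeds ranking length {len(ranking)}; truncating",
            stacklevel=2,
        )
        size_grid = [m for m in size_grid if m <= len(ranking)]
        if not size_grid:
            raise ValueError("ranking shorter than every requested signature size")

    kappas: list[float] = []
    rmsds: list[float] | None = None
    if known_fractions is not None:
        if data is None:
            raise ValueError("per-size RMSD requires the mixture matrix `data`")
        rmsds = []
    for m in size_grid:
        basis = build_basis(pure, ranking[:m])
        kappas.append(condition_number(basis))
        if rmsds is not None:
            est = deconvolve(data, basis)
            rmsds.append(rmsd(est, known_fractions))

    idx, note = _first_local_minimum(kappas)
    chosen = size_grid[idx]
    if note:
        logger.info("signature size selection: %s (size %d)", note, chosen)
    trace = BasisSelectionTrace(
        sizes=list(size_grid),
        condition_numbers=kappas,
        chosen_size=chosen,
        rmsd_per_size=rmsds,
        note=note,
    )
    return build_basis(pure, ranking[:chosen]), trace
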