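"""Independent oracle implementations used to cross-check the package.

Everything here is written directly from first principles / published
closed forms and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist


def bh_step_up(pvals):
    """Benjamini-Hochberg by the literal step-up definition.

    adjusted p_(i) = min over j >= i of min(1, m * p_(j) / j)  (1-based ranks
    on the sorted p-values), mapped back to the input order.
    """
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted_sorted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, m * p[i] / rank_from_top)
        running_min = min(running_min, value)
        adjusted_sorted[rank_from_top - 1] = running_min
    out = [None] * m
    for rank, i in enumerate(order):
        out[i] = adjusted_sorted[rank]
    return np.array(out)


def wilcoxon_signed_rank_exact(x, y):
    """Two-sided exact signed-rank p by full enumeration of 2^n sign vectors.

    Zero differences are dropped; assumes no ties among |differences|.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2.0
    w_min = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= w_min:
            count += 1
    return min(1.0, count / 2.0**n)


def moderated_t_reference(log_a: np.ndarray, log_b: np.ndarray):
    """Second, independent coding of the empirical-Bayes moderated t.

    Follows the published closed forms step by step with explicit loops
    and a bracketing root-finder for the trigamma inverse (the package
    uses Newton iteration). Returns (t, p, d0, s0_sq).
    """
    n_a, n_b = log_a.shape[1], log_b.shape[1]
    d_g = n_a + n_b - 2
    n_genes = log_a.shape[0]
    s2 = np.empty(n_genes)
    diff = np.empty(n_genes)
    for g in range(n_genes):
        ma, mb = log_a[g].mean(), log_b[g].mean()
        diff[g] = ma - mb
        ss = ((log_a[g] - ma) ** 2).sum() + ((log_b[g] - mb) ** 2).sum()
        s2[g] = ss / d_g

    # moment-match the scaled-F prior on log variances
    positive = s2[s2 > 0]
    z = np.log(positive)
    e = z - float(digamma(d_g / 2.0)) + math.log(d_g / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    rhs = e_var - float(polygamma(1, d_g / 2.0))
    if rhs > 0:
        # trigamma is decreasing on (0, inf): bracket and bisect
        f = lambda y: float(polygamma(1, y)) - rhs
        lo, hi = 1e-8, 1e8
        while f(hi) > 0:
            hi *= 10.0
        root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
        d0 = 2.0 * root
        s0_sq = math.exp(e_mean + float(digamma(root)) - math.log(root))
    else:
        # underdispersed: infinite prior df, variances shrink to their mean
        d0 = math.inf
        s0_sq = float(positive.mean())

    t = np.empty(n_genes)
    p = np.empty(n_genes)
    se_unit = math.sqrt(1.0 / n_a + 1.0 / n_b)
    for g in range(n_genes):
        if math.isinf(d0):
            post = s0_sq
        else:
            post = (d0 * s0_sq + d_g * s2[g]) / (d0 + d_g)
        t[g] = diff[g] / (math.sqrt(post) * se_unit)
        df = d0 + d_g
        if math.isinf(df):
            from scipy.stats import norm

            p[g] = 2.0 * norm.sf(abs(t[g]))
        else:
            p[g] = 2.0 * t_dist.sf(abs(t[g]), df)
    return t, p, d0, s0_sq


def simplex_grid_minimizer(S: np.ndarray, x: np.ndarray, step: float = 0.001):
    """Brute-force minimizer of ||S a - x||^2 over a simplex lattice.

    Enumerates every lattice point with coordinates that are multiples of
    ``step`` summing to 1, evaluating the residual norm directly.
    Returns (best_a, best_objective). Only practical for <= 3 types.
    """
    n = S.shape[1]
    k = int(round(1.0 / step))
    if n == 2:
        i = np.arange(k + 1)
        grid = np.column_stack([i, k - i]) / k
    elif n == 3:
        pts = []
        for i in range(k + 1):
            j = np.arange(k - i + 1)
            block = np.column_stack([np.full(j.size, i), j, k - i - j])
            pts.append(block)
        grid = np.vstack(pts) / k
    else:
        raise NotImplementedError("grid oracle supports 2 or 3 types")
    best_obj = np.inf
    best_a = None
    chunk = 200_000
    for start in range(0, grid.shape[0], chunk):
        G = grid[start : start + chunk]
        resid = G @ S.T - x
        obj = np.einsum("ij,ij->i", resid, resid)
        j = int(np.argmin(obj))
        if obj[j] < best_obj:
            best_obj = float(obj[j])
            best_a = G[j].copy()
    return best_a, best_obj
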