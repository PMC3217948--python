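"""Synthetic pure profiles, replicate noise and designed mixtures.

The generator emulates the structure of controlled mixing experiments on
expression microarrays: a small number of pure types measured in
replicate, marker genes strongly up-regulated in exactly one type, and
mixture samples formed at designed fractions. Intensities follow a
log-normal baseline (positive, right-skewed, heteroscedastic); replicate
noise is Gaussian on the log2 scale; mixture noise is multiplicative
log-normal with a given coefficient of variation (an additive-Gaussian
option exists for oracle-equivalence checks).

The mixing step here is an independent implementation of the linear
mixing model — the solver never reuses this code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FractionTable, PureProfileSet

__all__ = [
    "SimulationConfig",
    "generate_pure_profiles",
    "generate_mixtures",
    "benchmark_design",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression model.

    marker_fold is a log2-scale effect: each type's markers are
    ``2**marker_fold`` times higher in that type than baseline.
    replicate_sd is the log2-scale standard deviation of replicate noise.
    """

    n_genes: int = 2000
    n_types: int = 2
    n_replicates: int = 3
    markers_per_type: int = 50
    marker_fold: float = 3.0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    replicate_sd: float = 0.15
    seed: int = 0
    type_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_types < 2 or self.n_replicates < 1:
            raise ValueError("invalid simulation dimensions")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("markers_per_type * n_types exceeds n_genes")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be > 0 (log2-scale effect)")
        if not self.type_labels:
            self.type_labels = [f"T{i+1:02d}" for i in range(self.n_types)]
        if len(self.type_labels) != self.n_types:
            raise ValueError("type_labels length must equal n_types")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i+1:05d}" for i in range(n)]


def generate_pure_profiles(cfg: SimulationConfig) -> PureProfileSet:
    """Replicated pure-type profiles with planted marker genes.

    Gene g's baseline is 2**Normal(baseline_log_mean, baseline_log_sd).
    Markers of type t (a disjoint block of ``markers_per_type`` genes per
    type) are multiplied by 2**marker_fold in type t only. Replicates add
    Normal(0, replicate_sd) noise on the log2 scale.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    baseline_log = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    type_log = np.tile(baseline_log[:, None], (1, cfg.n_types))
    for t in range(cfg.n_types):
        block = slice(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        type_log[block, t] += cfg.marker_fold

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for t, lab in enumerate(cfg.type_labels):
        for r in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, cfg.replicate_sd, cfg.n_genes)
                if cfg.replicate_sd > 0
                else 0.0
            )
            sample = f"{lab}_rep{r+1}"
            columns[sample] = np.exp2(type_log[:, t] + noise)
            labels[sample] = lab
    expr = ExpressionMatrix(pd.DataFrame(columns, index=genes), scale="linear")
    return PureProfileSet(expr, pd.Series(labels))


def marker_genes(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Ground-truth marker gene ids per type (by construction)."""
    genes = _gene_ids(cfg.n_genes)
    return {
        lab: genes[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]
        for t, lab in enumerate(cfg.type_labels)
    }


def generate_mixtures(
    pure: PureProfileSet,
    design: FractionTable,
    noise_cv: float = 0.0,
    seed: int = 0,
    noise_model: str = "lognormal",
) -> ExpressionMatrix:
    """Mixture samples at the design's fractions with multiplicative noise.

    Each mixture column is (type-mean matrix) @ (design row); with
    ``noise_model="lognormal"`` every entry is then multiplied by a unit-mean
    log-normal factor of coefficient of variation ``noise_cv``; with
    ``"additive"`` zero-mean Gaussian noise of sd ``noise_cv * mean(signal)``
    is added (clipped at zero). ``noise_cv=0`` gives exact linear mixtures.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_model not in ("lognormal", "additive"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    missing = [t for t in design.type_labels if t not in pure.type_labels]
    if missing:
        raise ValueError(f"design types absent from pure profiles: {missing}")
    means = pure.type_means()[design.type_labels].to_numpy()
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for sample in design.sample_ids:
        a = design.data.loc[sample].to_numpy()
        if abs(a.sum() - 1.0) > 1e-6:
            raise ValueError(f"design row {sample!r} is off the simplex")
        mu = means @ a
        if noise_cv == 0:
            columns[sample] = mu
        elif noise_model == "lognormal":
            sigma2 = np.log1p(noise_cv**2)
            factors = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), mu.size))
            columns[sample] = mu * factors
        else:
            sd = noise_cv * float(mu.mean())
            columns[sample] = np.clip(mu + rng.normal(0.0, sd, mu.size), 0.0, None)
    frame = pd.DataFrame(columns, index=pure.expr.gene_ids)
    return ExpressionMatrix(frame, scale="linear")


def benchmark_design(name: str) -> FractionTable:
    """Designed mixing-fraction tables of the controlled benchmark layouts.

    ``blood_breast``: 15 samples at 0/33/67/100% blood with 3/6/3/3
    replicates. ``liver_kidney``: 12 samples at 100/75/25/0% liver in
    triplicate. ``ten_type_rare``: ten 10-type mixtures, each holding one
    type at the rare fraction 0.05.
    """
    if name == "blood_breast":
        rows, idx = [], []
        for blood, reps in [(0.0, 3), (0.33, 6), (0.67, 3), (1.0, 3)]:
            for r in range(reps):
                idx.append(f"mix_blood{int(round(blood*100)):03d}_rep{r+1}")
                rows.append([blood, 1.0 - blood])
        return FractionTable(pd.DataFrame(rows, index=idx, columns=["blood", "breast"]))
    if name == "liver_kidney":
        rows, idx = [], []
        for liver in (1.0, 0.75, 0.25, 0.0):
            for r in range(3):
                idx.append(f"mix_liver{int(round(liver*100)):03d}_rep{r+1}")
                rows.append([liver, 1.0 - liver])
        return FractionTable(pd.DataFrame(rows, index=idx, columns=["liver", "kidney"]))
    if name == "ten_type_rare":
        labels = [f"T{i+1:02d}" for i in range(10)]
        rare, common = 0.05, 0.95 / 9.0
        rows, idx = [], []
        for t in range(10):
            row = [common] * 10
            row[t] = rare
            rows.append(row)
            idx.append(f"mix_rare_{labels[t]}")
        return FractionTable(pd.DataFrame(rows, index=idx, columns=labels))
    raise ValueError(
        f"unknown design {name!r}; options: blood_breast, liver_kidney, ten_type_rare"
    )
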