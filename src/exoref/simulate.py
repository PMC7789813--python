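"""Synthetic exosome-like count data with known ground truth.

Counts are negative-binomial with Var = mu + dispersion * mu^2
(gamma-Poisson sampling), heterogeneous library sizes, several case
groups plus one control group. A minority of planted stable features draw
their baseline means from the upper tail of the expression distribution,
carry no group effect and a low dispersion; the remaining features get
i.i.d. per-group log2 effects and higher dispersions.

One global seed drives a splittable stream per stage (baseline means,
dispersions, group effects, library sizes, counts), so datasets are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from exoref.expression_io import CtTable, ExpressionMatrix, SampleDesign, ValidationError

DEFAULT_GROUPS = [
    ("PAAD", "case", 8),
    ("CRC", "case", 8),
    ("HCC", "case", 8),
    ("HC", "control", 8),
]


@dataclass
class SimulationConfig:
    """Parameters of the count simulator; defaults give the standard scenario."""

    n_features: int = 2000
    n_stable: int = 5
    groups: list[tuple[str, str, int]] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    baseline_log2_mean: float = 5.0
    baseline_log2_spread: float = 2.0
    dispersion_range: tuple[float, float] = (0.05, 0.25)
    dispersion_stable: float = 0.01
    group_effect_scale: float = 1.0
    library_sigma: float = 0.3
    high_expression_quantile: float = 0.99
    seed: int = 42

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValidationError("n_features must be positive")
        if not (0 <= self.n_stable <= self.n_features):
            raise ValidationError("n_stable must lie in [0, n_features]")
        conds = {c for _, c, _ in self.groups}
        if "case" not in conds or "control" not in conds:
            raise ValidationError("groups must include at least one case and one control group")
        if any(n < 1 for _, _, n in self.groups):
            raise ValidationError("every group needs at least one sample")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ValidationError("dispersion_range must be positive and ordered")
        if self.dispersion_stable <= 0:
            raise ValidationError("dispersion_stable must be positive")
        if self.group_effect_scale < 0 or self.library_sigma < 0:
            raise ValidationError("scales must be nonnegative")
        if not (0.0 < self.high_expression_quantile < 1.0):
            raise ValidationError("high_expression_quantile must lie in (0, 1)")


@dataclass
class SimulatedDataset:
    counts: ExpressionMatrix
    design: SampleDesign
    truth: pd.Series  # bool per feature: is_planted_stable

    def __post_init__(self) -> None:
        if not self.truth.index.equals(self.counts.features):
            raise ValidationError("truth must cover exactly the count matrix features")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_counts(config: SimulationConfig) -> SimulatedDataset:
    """Draw a reproducible NB count matrix with planted stable features."""
    config.validate()
    rng_base, rng_disp, rng_eff, rng_lib, rng_counts, rng_pick = _streams(config.seed, 6)

    p = config.n_features
    features = pd.Index([f"F{i:05d}" for i in range(p)], name="feature")
    stable_idx = np.sort(rng_pick.choice(p, size=config.n_stable, replace=False))
    is_stable = np.zeros(p, dtype=bool)
    is_stable[stable_idx] = True

    # baseline log2 means: background from the full normal, planted from its
    # upper high_expression_quantile tail (truncated normal via inverse CDF)
    mu_log2 = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_spread, size=p)
    u = rng_base.uniform(config.high_expression_quantile, 1.0, size=config.n_stable)
    mu_log2[is_stable] = (
        config.baseline_log2_mean + config.baseline_log2_spread * stats.norm.ppf(u)
    )

    lo, hi = config.dispersion_range
    dispersion = rng_disp.uniform(lo, hi, size=p)
    dispersion[is_stable] = config.dispersion_stable

    samples: list[str] = []
    group_of: list[str] = []
    cond_of: list[str] = []
    effects_cols: list[np.ndarray] = []
    for label, condition, n_samples in config.groups:
        eff = np.zeros(p)
        if condition == "case" and config.group_effect_scale > 0:
            eff = rng_eff.normal(0.0, config.group_effect_scale, size=p)
            eff[is_stable] = 0.0
        for k in range(n_samples):
            samples.append(f"{label}_{k + 1:02d}")
            group_of.append(label)
            cond_of.append(condition)
            effects_cols.append(eff)
    m = len(samples)
    effects = np.column_stack(effects_cols)  # (p, m)

    lib = np.exp(rng_lib.normal(0.0, config.library_sigma, size=m)) if config.library_sigma > 0 else np.ones(m)
    mean = (2.0 ** (mu_log2[:, None] + effects)) * lib[None, :]

    # gamma-Poisson: lambda ~ Gamma(shape=1/a, scale=a*mu) gives Var = mu + a mu^2
    shape = 1.0 / dispersion
    lam = rng_counts.gamma(shape[:, None], dispersion[:, None] * mean)
    counts = rng_counts.poisson(lam).astype(float)

    design = SampleDesign(
        pd.DataFrame({"sample": samples, "group": group_of, "condition": cond_of})
    )
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=features, columns=samples), scale="count")
    truth = pd.Series(is_stable, index=features, name="is_planted_stable")
    return SimulatedDataset(matrix, design, truth)


CT_FLOOR = 1e-6


def simulate_ct(
    expr: ExpressionMatrix,
    noise_sd: float,
    control_feature: str,
    seed: int,
) -> CtTable:
    """Invert abundances to Ct values with optional Gaussian technical noise.

    Ct_ij = -log2(a_ij / column_total_i) + N(0, noise_sd^2); at
    noise_sd = 0 the table round-trips through 2^-Ct proportionally
    within each sample. Ct values are floored at a tiny positive value.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if control_feature not in expr.features:
        raise ValidationError(f"control feature {control_feature!r} not in matrix")
    arr = expr.values.to_numpy(dtype=float)
    if np.isnan(arr).any() or (arr <= 0).any():
        raise ValidationError("simulate_ct requires strictly positive abundances")
    rel = arr / arr.sum(axis=0, keepdims=True)
    ct = -np.log2(rel)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
    ct = np.maximum(ct, CT_FLOOR)
    return CtTable(pd.DataFrame(ct, index=expr.features, columns=expr.samples))
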