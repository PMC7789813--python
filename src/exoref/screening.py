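"""Candidate-identification cascade.

Per case group (subtype), a negative-binomial two-group Wald test against
the controls calls each feature differentially expressed or not; features
with p > threshold in *every* subtype are retained, then filtered for high
pooled expression and sorted by expression for top-N selection.

The NB test is a deliberately simple, calibrated substitute for a full
shrinkage-based DE framework: median-of-ratios size factors,
method-of-moments dispersion (floored) moderated toward a mean-dispersion
trend when enough features are available, Wald statistic on the log2 fold
change with a delta-method standard error, referred to a Student-t
distribution with n1 + n2 - 2 degrees of freedom (the small-sample
correction needed for calibrated type-I error at a dozen samples; with
large samples it coincides with the normal reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exoref.expression_io import ExpressionMatrix, SampleDesign, ValidationError, log2p1

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5
#: Minimum number of features before dispersion moderation kicks in.
MODERATION_MIN_FEATURES = 50
#: Number of mean-quantile bins used for the dispersion trend.
TREND_BINS = 20
#: Weight of the trend in the log-scale dispersion shrinkage.
TREND_SHRINKAGE = 0.75


@dataclass
class SizeFactors:
    """Per-sample scaling constants, normalized to geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if (vals <= 0).any() or not np.all(np.isfinite(vals)):
            raise ValidationError("size factors must be positive and finite")


def size_factors(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Computed over features with all-positive counts: each sample's factor
    is the median ratio of its counts to the per-feature geometric means,
    then the factors are rescaled to geometric mean 1. If no feature is
    positive in every sample, falls back to total-count ratios with a
    logged warning.
    """
    arr = counts.values.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        sub = arr[allpos]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "size_factors: no feature positive in all samples; "
            "falling back to total-count ratio normalization"
        )
        totals = arr.sum(axis=0)
        if (totals <= 0).any():
            raise ValidationError("cannot compute size factors: sample with zero total count")
        factors = totals.astype(float)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(pd.Series(factors, index=counts.samples, name="factor"))


def _moments_dispersion(q: np.ndarray, inv_sf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments mean and dispersion from normalized counts.

    With counts c ~ NB(mean mu*s_i, Var = m + a m^2) and q = c / s_i,
    Var(q_i) = mu / s_i + a * mu^2; averaging over samples gives the
    estimator solved for ``a`` below.
    """
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    u = inv_sf.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (v - m * u) / np.square(m)
    a = np.where(np.isfinite(a), a, DISPERSION_FLOOR)
    return m, np.maximum(a, DISPERSION_FLOOR)


def _moderate_dispersion(a: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Shrink per-feature dispersions (log scale) toward a fitted trend.

    The trend is the median method-of-moments dispersion within
    mean-quantile bins. Sharing dispersion information across features
    stabilizes the noisy per-feature estimate and — like the shrinkage DE
    frameworks this test substitutes for — makes the call conservative
    for features genuinely less dispersed than their expression peers.
    Matrices with fewer than MODERATION_MIN_FEATURES features keep the raw
    per-feature estimates.
    """
    p = a.shape[0]
    if p < MODERATION_MIN_FEATURES:
        return a
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, TREND_BINS)
    trend = np.empty(p)
    for idx in bins:
        trend[idx] = np.median(a[idx])
    trend = np.maximum(trend, DISPERSION_FLOOR)
    w = TREND_SHRINKAGE
    return np.exp((1.0 - w) * np.log(a) + w * np.log(trend))


def nb_two_group_test(
    counts: ExpressionMatrix,
    design: SampleDesign,
    subtype: str,
) -> pd.Series:
    """Two-sided per-feature NB Wald p-values, one case group vs controls.

    Size factors are estimated on the tested samples only. Per-feature
    dispersion is a pooled method-of-moments estimate across the two
    groups, floored at 1e-8. Features with zero counts in both groups get
    p = 1 (no evidence of differential expression).
    """
    case = [s for s in design.samples_in_group(subtype) if s in counts.samples]
    ctrl = [s for s in design.control_samples() if s in counts.samples]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError(
            f"subtype {subtype!r} needs >= 2 case and >= 2 control samples "
            f"(got {len(case)} and {len(ctrl)})"
        )
    sub = counts.subset(samples=case + ctrl)
    sf = size_factors(sub).factors.to_numpy()
    q = sub.values.to_numpy(dtype=float) / sf[None, :]
    n1 = len(case)
    q1, q0 = q[:, :n1], q[:, n1:]
    inv1, inv0 = 1.0 / sf[:n1], 1.0 / sf[n1:]

    m1, a1 = _moments_dispersion(q1, inv1)
    m0, a0 = _moments_dispersion(q0, inv0)
    n0 = q0.shape[1]
    a = ((n1 - 1) * a1 + (n0 - 1) * a0) / (n1 + n0 - 2)
    a = np.maximum(a, DISPERSION_FLOOR)
    a = _moderate_dispersion(a, q.mean(axis=1))

    lfc = np.log2((m1 + LFC_PSEUDOCOUNT) / (m0 + LFC_PSEUDOCOUNT))
    # Var(mean q_g) = mu * mean(1/s) / n + a * mu^2 / n, delta method on log2
    var_m1 = m1 * inv1.mean() / n1 + a * np.square(m1) / n1
    var_m0 = m0 * inv0.mean() / n0 + a * np.square(m0) / n0
    ln2sq = np.log(2.0) ** 2
    se2 = (var_m1 / np.square(m1 + LFC_PSEUDOCOUNT) + var_m0 / np.square(m0 + LFC_PSEUDOCOUNT)) / ln2sq
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pvals = 2.0 * stats.t.sf(np.abs(z), df=n1 + n0 - 2)
    allzero = (m1 == 0) & (m0 == 0)
    pvals = np.where(allzero | ~np.isfinite(z), 1.0, pvals)
    return pd.Series(np.clip(pvals, 0.0, 1.0), index=counts.features, name=f"p_{subtype}")


def nonde_filter(pvalues: pd.Series, threshold: float = 0.1) -> set[str]:
    """Features with p strictly greater than the threshold (non-DE call)."""
    arr = pvalues.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return set(pvalues.index[arr > threshold])


def intersect_subtypes(feature_sets: list[set[str]]) -> set[str]:
    """Features retained in every subtype; warns on an empty result."""
    if not feature_sets:
        raise ValidationError("need at least one subtype feature set")
    out = set(feature_sets[0])
    for s in feature_sets[1:]:
        out &= set(s)
    if not out:
        logger.warning("intersect_subtypes: empty intersection across subtypes")
    return out


def high_expression_filter(
    expr: ExpressionMatrix,
    design: SampleDesign,
    candidates: set[str],
) -> set[str]:
    """Keep candidates expressed above the pooled-transcriptome average.

    A candidate survives iff its mean log2(x+1) over case samples strictly
    exceeds the grand mean log2(x+1) over all features and case samples,
    and likewise within control samples.
    """
    if expr.scale not in ("TPM", "CPM", "abundance"):
        raise ValidationError(f"high_expression_filter expects normalized values, got {expr.scale!r}")
    if not candidates:
        return set()
    logx = log2p1(expr).values
    out = set(candidates)
    for samples in (design.case_samples(), design.control_samples()):
        cols = [s for s in samples if s in logx.columns]
        if not cols:
            raise ValidationError("high_expression_filter: design samples absent from matrix")
        block = logx[cols]
        grand = float(block.to_numpy().mean())
        means = block.mean(axis=1)
        out &= set(means.index[means > grand])
    return out


def select_top(expr: ExpressionMatrix, survivors: set[str], n: int = 10) -> list[str]:
    """Survivors sorted by mean log2(x+1) over all samples, descending.

    Truncated to ``n``; ties broken by feature identifier (ascending).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    surv = [f for f in expr.features if f in survivors]
    if len(surv) < n:
        logger.info("select_top: only %d survivors for top-%d request", len(surv), n)
    means = log2p1(expr.subset(features=surv)).values.mean(axis=1)
    order = sorted(surv, key=lambda f: (-means[f], f))
    return order[:n]


def screen(
    counts: ExpressionMatrix,
    expr: ExpressionMatrix,
    design: SampleDesign,
    p_threshold: float = 0.1,
    top_n: int = 10,
) -> tuple[pd.DataFrame, list[str], dict[str, int]]:
    """Run the full cascade; returns (per-feature table, candidates, stage counts).

    The table carries one p-value column per subtype plus the retention
    flags; ``candidates`` is the ordered top-N list (possibly empty when
    the subtype intersection is empty).
    """
    design.require_case_control()
    subtypes = design.case_groups
    ptable = pd.DataFrame(index=counts.features)
    sets = []
    counts_by_stage: dict[str, int] = {"input": counts.shape[0]}
    for g in subtypes:
        p = nb_two_group_test(counts, design, g)
        ptable[f"p_{g}"] = p
        kept = nonde_filter(p, p_threshold)
        counts_by_stage[f"non_de_{g}"] = len(kept)
        sets.append(kept)
    universal = intersect_subtypes(sets)
    counts_by_stage["non_de_all_subtypes"] = len(universal)
    high = high_expression_filter(expr, design, universal)
    counts_by_stage["above_average_both"] = len(high)
    selected = select_top(expr, high, top_n) if high else []
    counts_by_stage["selected"] = len(selected)

    logx = log2p1(expr).values
    ptable["mean_log_expr_case"] = logx[[s for s in design.case_samples()]].mean(axis=1)
    ptable["mean_log_expr_control"] = logx[[s for s in design.control_samples()]].mean(axis=1)
    ptable["pooled_mean_log_expr"] = logx.mean(axis=1)
    ptable["non_de_all_subtypes"] = ptable.index.isin(universal)
    ptable["above_average_both"] = ptable.index.isin(high)
    ptable["selected"] = ptable.index.isin(selected)
    return ptable, selected, counts_by_stage
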