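"""Stability scoring: CV, pairwise-variation M, combination AV, group-aware
(NormFinder-style) scores, and rank-sum aggregation.

All scores are computed on the linear normalized scale (TPM, CPM or
2^-Ct); logarithms (base 2) appear only inside the pairwise log-ratio. An
optional pseudocount (default 1 unit of the matrix's scale) is added when
zeros are present, with a loud log message. Sample standard deviations use
the n-1 denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exoref.expression_io import ExpressionMatrix, SampleDesign, ValidationError

logger = logging.getLogger(__name__)


def cv_stability(expr: ExpressionMatrix) -> pd.Series:
    """Per-feature coefficient of variation: sd / mean across samples.

    Missing cells (abundance scale only) are excluded per feature, with a
    logged count; every feature needs >= 2 observed samples and a strictly
    positive mean.
    """
    arr = expr.values.to_numpy(dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.warning("cv_stability: excluding %d missing cells", n_missing)
    n_obs = np.sum(~np.isnan(arr), axis=1)
    if (n_obs < 2).any():
        bad = expr.features[n_obs < 2].tolist()
        raise ValidationError(f"features with < 2 observed samples: {bad}")
    means = np.nanmean(arr, axis=1)
    if (means <= 0).any():
        bad = expr.features[means <= 0].tolist()
        raise ValidationError(f"zero-mean features, CV undefined: {bad}")
    sds = np.nanstd(arr, axis=1, ddof=1)
    return pd.Series(sds / means, index=expr.features, name="cv")


def _positive_values(expr: ExpressionMatrix, pseudocount: float) -> np.ndarray:
    arr = expr.values.to_numpy(dtype=float)
    if (np.nan_to_num(arr, nan=1.0) <= 0).any():
        if pseudocount > 0:
            logger.warning(
                "stability: zeros present; adding pseudocount %g before log ratios", pseudocount
            )
            arr = arr + pseudocount
        nonpos = np.nan_to_num(arr, nan=1.0) <= 0
        if nonpos.any():
            i, j = np.argwhere(nonpos)[0]
            raise ValidationError(
                f"nonpositive value after pseudocount at feature "
                f"{expr.features[i]!r}, sample {expr.samples[j]!r}"
            )
    return arr


def pairwise_variation(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Symmetric matrix of pairwise variations V_jk.

    V_jk is the sample standard deviation over samples of
    log2(a_ij / a_ik); zero exactly when two features are proportional
    across all samples. Missing cells are excluded pairwise (a sample
    contributes to V_jk only if both features are observed in it).
    """
    if expr.shape[1] < 2:
        raise ValidationError("pairwise variation needs >= 2 samples")
    arr = _positive_values(expr, pseudocount)
    logx = np.log2(arr)  # (n_features, m_samples); NaN marks missing
    n = logx.shape[0]
    if np.isnan(logx).any():
        v = np.empty((n, n))
        for j in range(n):
            d = logx[j][None, :] - logx  # (n, m)
            n_obs = np.sum(~np.isnan(d), axis=1)
            if (n_obs < 2).any():
                k = int(np.argmax(n_obs < 2))
                raise ValidationError(
                    f"pair ({expr.features[j]!r}, {expr.features[k]!r}) has < 2 complete samples"
                )
            v[j] = np.nanstd(d, axis=1, ddof=1)
    else:
        # sd of (x_j - x_k) over samples, expanded via the covariance matrix
        cov = np.cov(logx, ddof=1)
        cov = np.atleast_2d(cov)
        d = np.diag(cov)
        var = d[:, None] + d[None, :] - 2.0 * cov
        v = np.sqrt(np.maximum(var, 0.0))
    np.fill_diagonal(v, 0.0)
    v = (v + v.T) / 2.0
    return pd.DataFrame(v, index=expr.features, columns=expr.features)


def m_values(expr: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """Average expression stability M_j = mean of V_jk over all k != j.

    With exactly two features, M_1 = M_2 = V_12. Invariant under
    per-sample rescaling because the log ratios cancel sample factors.
    """
    if expr.shape[0] < 2:
        raise ValidationError("M undefined for a single feature")
    v = pairwise_variation(expr, pseudocount=pseudocount)
    n = v.shape[0]
    m = v.to_numpy().sum(axis=1) / (n - 1)
    return pd.Series(m, index=expr.features, name="m")


@dataclass(frozen=True)
class ComboStability:
    """Stability of a reference-feature combination: geometric mean of M."""

    members: tuple[str, ...]
    av: float


def av_combination(m: pd.Series, members: tuple[str, ...] | list[str]) -> ComboStability:
    """Geometric mean of member M values (order-invariant).

    Any member with M = 0 yields AV = 0 by the limit convention.
    """
    members = tuple(members)
    if len(members) < 2:
        raise ValidationError("a combination needs >= 2 members")
    missing = [f for f in members if f not in m.index]
    if missing:
        raise ValidationError(f"members without M values: {missing}")
    vals = m.loc[list(members)].to_numpy(dtype=float)
    if (vals < 0).any() or not np.all(np.isfinite(vals)):
        raise ValidationError("member M values must be finite and >= 0")
    if (vals == 0).any():
        logger.info("av_combination: member with M = 0, AV = 0 by convention")
        return ComboStability(members, 0.0)
    av = float(np.exp(np.mean(np.log(vals))))
    return ComboStability(members, av)


def _ordinal_rank(values: pd.Series) -> pd.Series:
    """Ordinal ranks, 1 = lowest value; ties broken by feature identifier."""
    order = sorted(values.index, key=lambda f: (values[f], f))
    return pd.Series({f: i + 1 for i, f in enumerate(order)}, name=values.name)


def rank_candidates(cv: pd.Series, m: pd.Series) -> pd.DataFrame:
    """Rank-sum aggregation of the CV and M stability indicators.

    Each indicator is ranked low-to-high (rank 1 = most stable, ties
    broken by identifier); the final rank orders features by ascending
    rank sum, breaking ties by lower M and then identifier.
    """
    if set(cv.index) != set(m.index):
        raise ValidationError("CV and M must cover the same feature set")
    m = m.reindex(cv.index)
    cv_rank = _ordinal_rank(cv)
    m_rank = _ordinal_rank(m)
    rank_sum = cv_rank + m_rank
    final_order = sorted(cv.index, key=lambda f: (rank_sum[f], m[f], f))
    final_rank = pd.Series({f: i + 1 for i, f in enumerate(final_order)})
    out = pd.DataFrame(
        {
            "cv": cv,
            "m": m,
            "cv_rank": cv_rank,
            "m_rank": m_rank,
            "rank_sum": rank_sum,
            "final_rank": final_rank,
        }
    )
    out.index.name = "feature"
    return out.sort_values("final_rank")


def normfinder_stability(
    expr: ExpressionMatrix,
    design: SampleDesign,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Group-aware stability score; lower = more stable.

    On log2 values with per-sample effects removed (each sample centred on
    its across-feature mean), the score decomposes a feature's variation
    into the intergroup deviation d_gj (group mean minus the feature's
    grand mean) and the intragroup variance: the score is the mean over
    groups of |d_gj| + sqrt(s2_gj / n_g).
    """
    groups = sorted(design.table["group"].unique().tolist())
    if len(groups) < 2:
        raise ValidationError("normfinder_stability needs >= 2 groups")
    for g in groups:
        if len(design.samples_in_group(g)) < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")
    arr = _positive_values(expr.subset(samples=design.samples), pseudocount)
    cols = list(design.samples)
    logx = np.log2(arr)
    if np.isnan(logx).any():
        raise ValidationError("normfinder_stability does not accept missing values")
    # remove sample effects: centre each sample (column) on its mean over features
    z = logx - logx.mean(axis=0, keepdims=True)
    grand = z.mean(axis=1)  # per-feature grand mean over samples
    score = np.zeros(z.shape[0])
    col_index = {s: i for i, s in enumerate(cols)}
    for g in groups:
        idx = [col_index[s] for s in design.samples_in_group(g)]
        block = z[:, idx]
        d = block.mean(axis=1) - grand
        s2 = block.var(axis=1, ddof=1)
        score += np.abs(d) + np.sqrt(s2 / len(idx))
    score /= len(groups)
    return pd.Series(score, index=expr.features, name="normfinder")


def compare_stability_groups(
    candidate_scores: list[float] | np.ndarray,
    housekeeping_scores: list[float] | np.ndarray,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score lists.

    Returns (statistic, p-value); exact null distribution for small
    tie-free samples, normal approximation otherwise. Degenerate inputs
    with zero rank variance give p = 1.
    """
    a = np.asarray(candidate_scores, dtype=float)
    b = np.asarray(housekeeping_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both score lists must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(res.statistic), min(p, 1.0)
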