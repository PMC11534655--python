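"""Pre/post training-response statistics.

Percent change, bias-corrected Hedge's g with a 95% confidence interval
and magnitude label, Pearson correlations with two-tailed p-values on the
Hopkins-modified Cohen scale, paired comparisons, change-score correlation
matrices, and assembly of summary tables in the conventional
"pre mean±SD / post mean±SD / % change / p / g (CI)" layout.

Hedge's g here treats the pre and post samples as two groups of equal size
n with a pooled SD,

    s_p = sqrt(((n-1)*s1^2 + (n-1)*s2^2) / (2n - 2)),
    g   = J * (m2 - m1) / s_p,   J = 1 - 3 / (4*(2n-2) - 1),

with the normal-approximation CI from SE^2 = (n1+n2)/(n1*n2) +
g^2/(2*(n1+n2)). This is the convention under which published group
summary tables of this kind reproduce exactly from their printed
means/SDs; a repeated-measures d is deliberately not used.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CorrelationResult, EffectSizeResult, ValidationError

RATIO_OF_MEANS = "ratio-of-means"
MEAN_OF_RATIOS = "mean-of-ratios"

#: |g| bins -> magnitude label (half-open, lower edge inclusive)
EFFECT_BINS = (
    (0.2, "trivial"),
    (0.6, "small"),
    (1.2, "moderate"),
    (2.0, "large"),
    (4.0, "very large"),
    (math.inf, "extremely large"),
)

#: |r| bins -> Hopkins-modified Cohen label (half-open, lower edge inclusive)
CORRELATION_BINS = (
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
    (math.inf, "almost perfect"),
)


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Group-level percent change, 100*(post - pre)/pre."""
    if pre_mean == 0:
        raise ValidationError("pre_mean: percent change undefined at zero baseline")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def percent_change_individual(pre: Sequence[float], post: Sequence[float]) -> float:
    """Mean of per-participant percent changes (the mean-of-ratios convention)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre/post: length mismatch")
    if np.any(pre == 0):
        raise ValidationError("pre: percent change undefined at zero baseline")
    return float(np.mean(100.0 * (post - pre) / pre))


def hedges_g(
    pre_mean: float,
    pre_sd: float,
    post_mean: float,
    post_sd: float,
    n_per_group: int,
) -> float:
    """Bias-corrected Hedge's g for two groups of equal size n."""
    if n_per_group < 2:
        raise ValidationError("n_per_group: must be >= 2")
    if pre_sd <= 0 or post_sd <= 0:
        raise ValidationError("pre_sd/post_sd: must be positive")
    n = n_per_group
    sp = math.sqrt(((n - 1) * pre_sd**2 + (n - 1) * post_sd**2) / (2 * n - 2))
    if sp == 0:
        raise ValidationError("pooled SD is zero; g undefined")
    d = (post_mean - pre_mean) / sp
    j = 1.0 - 3.0 / (4.0 * (2 * n - 2) - 1.0)
    return d * j


def hedges_ci(g: float, n_per_group: int, level: float = 0.95):
    """Normal-approximation confidence interval for Hedge's g."""
    if n_per_group < 2:
        raise ValidationError("n_per_group: must be >= 2")
    if not (0 < level < 1):
        raise ValidationError("level: must lie in (0, 1)")
    n1 = n2 = n_per_group
    se = math.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return g - z * se, g + z * se


def _label(value: float, bins) -> str:
    v = abs(value)
    for edge, name in bins:
        if v < edge:
            return name
    return bins[-1][1]


def label_effect(g: float) -> str:
    """Magnitude label for an effect size (trivial ... extremely large)."""
    return _label(g, EFFECT_BINS)


def label_correlation(r: float) -> str:
    """Hopkins-modified Cohen label for a correlation (trivial ... almost perfect)."""
    return _label(r, CORRELATION_BINS)


def effect_size(
    pre_mean: float,
    pre_sd: float,
    post_mean: float,
    post_sd: float,
    n_per_group: int,
    level: float = 0.95,
) -> EffectSizeResult:
    """Hedge's g with CI and magnitude label in one record."""
    g = hedges_g(pre_mean, pre_sd, post_mean, post_sd, n_per_group)
    lo, hi = hedges_ci(g, n_per_group, level)
    return EffectSizeResult(g=g, ci_low=lo, ci_high=hi, label=label_effect(g))


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x/y: length mismatch")
    if len(x) < 3:
        raise ValidationError("x: need n >= 3 for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("x/y: non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("x/y: zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    p = float(res.pvalue) if res.pvalue > 0 else float(np.finfo(float).tiny)
    return CorrelationResult(
        r=float(res.statistic), p=p, n=len(x), label=label_correlation(res.statistic)
    )


def paired_comparison(pre: Sequence[float], post: Sequence[float]):
    """Paired t-test on post - pre differences.

    A documented stand-in for a mixed-effects pre/post comparison: returns
    ``(mean_difference, t, p)`` with a two-tailed p. Zero-variance
    differences make the statistic degenerate and raise instead.
    """

    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre/post: length mismatch")
    if len(pre) < 3:
        raise ValidationError("pre: need n >= 3 paired observations")
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        raise ValidationError("differences have zero variance; t undefined")
    res = sps.ttest_rel(post, pre)
    return float(np.mean(diff)), float(res.statistic), float(res.pvalue)


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy (participant, timepoint, metric, value) -> wide per-timepoint frame."""
    required = {"participant", "timepoint", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValidationError(f"table: needs columns {sorted(required)}")
    dup = table.duplicated(["participant", "timepoint", "metric"])
    if dup.any():
        raise ValidationError("table: duplicate (participant, timepoint, metric) rows")
    return table.pivot_table(
        index="participant", columns=["metric", "timepoint"], values="value"
    )


def change_scores(
    table: pd.DataFrame, metrics: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-participant relative changes, 100*(post - pre)/pre, one column per metric.

    Participants missing either timepoint for a metric are dropped from
    that metric's column with a warning.
    """

    wide = _pivot(table)
    metric_names = metrics or sorted({m for m, _ in wide.columns})
    out = {}
    for m in metric_names:
        if (m, "pre") not in wide.columns or (m, "post") not in wide.columns:
            raise ValidationError(f"table: metric {m!r} missing a timepoint entirely")
        pre = wide[(m, "pre")]
        post = wide[(m, "post")]
        ok = pre.notna() & post.notna()
        if not ok.all():
            dropped = list(wide.index[~ok])
            warnings.warn(
                f"metric {m!r}: dropping participants missing a timepoint: {dropped}",
                stacklevel=2,
            )
        out[m] = 100.0 * (post[ok] - pre[ok]) / pre[ok]
    return pd.DataFrame(out)


def change_correlation_matrix(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcomes: Sequence[str],
) -> pd.DataFrame:
    """Correlations between relative changes in predictor and outcome metrics.

    For every (predictor, outcome) pair, Pearson r across participants'
    percent changes, with p, n and magnitude label. Mirrors the layout of a
    change-score correlation table.
    """

    deltas = change_scores(table, sorted(set(predictors) | set(outcomes)))
    rows = []
    for pred in predictors:
        for out in outcomes:
            pair = deltas[[pred, out]].dropna()
            if len(pair) < 3:
                raise ValidationError(
                    f"fewer than 3 complete participants for ({pred!r}, {out!r})"
                )
            res = pearson_corr(pair[pred].to_numpy(), pair[out].to_numpy())
            rows.append(
                {
                    "predictor": pred,
                    "outcome": out,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "label": res.label,
                }
            )
    return pd.DataFrame(rows)


def summary_from_moments(
    moments: pd.DataFrame, n_per_group: int, level: float = 0.95
) -> pd.DataFrame:
    """Summary-table statistics from per-metric printed moments.

    ``moments`` needs columns ``metric, pre_mean, pre_sd, post_mean,
    post_sd``. Returns % change (ratio-of-means — the only convention
    computable from moments), Hedge's g, CI and label; no p-value is
    possible without participant-level data.
    """

    rows = []
    for rec in moments.itertuples(index=False):
        es = effect_size(
            rec.pre_mean, rec.pre_sd, rec.post_mean, rec.post_sd, n_per_group, level
        )
        rows.append(
            {
                "metric": rec.metric,
                "pre_mean": rec.pre_mean,
                "pre_sd": rec.pre_sd,
                "post_mean": rec.post_mean,
                "post_sd": rec.post_sd,
                "pct_change": percent_change(rec.pre_mean, rec.post_mean),
                "g": es.g,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "label": es.label,
            }
        )
    return pd.DataFrame(rows)


def build_summary_table(
    table: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    pct_change_convention: str = RATIO_OF_MEANS,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-metric pre/post summary from a tidy participant-level table.

    One row per metric: pre and post mean±SD, % change (group ratio of
    means by default, or mean of per-participant ratios), paired-t p,
    Hedge's g with CI and magnitude label, and the paired n. Metrics with
    no data are omitted.
    """

    if pct_change_convention not in (RATIO_OF_MEANS, MEAN_OF_RATIOS):
        raise ValidationError(
            f"pct_change_convention: {pct_change_convention!r} not recognised"
        )
    wide = _pivot(table)
    metric_names = metrics or sorted({m for m, _ in wide.columns})
    rows = []
    for m in metric_names:
        if (m, "pre") not in wide.columns or (m, "post") not in wide.columns:
            continue
        pair = wide[[(m, "pre"), (m, "post")]].dropna()
        if len(pair) < 2:
            continue
        pre = pair[(m, "pre")].to_numpy()
        post = pair[(m, "post")].to_numpy()
        n = len(pre)
        if pct_change_convention == RATIO_OF_MEANS:
            pct = percent_change(float(np.mean(pre)), float(np.mean(post)))
        else:
            pct = percent_change_individual(pre, post)
        es = effect_size(
            float(np.mean(pre)),
            float(np.std(pre, ddof=1)),
            float(np.mean(post)),
            float(np.std(post, ddof=1)),
            n,
            level,
        )
        try:
            _, _, p = paired_comparison(pre, post)
        except ValidationError:
            p = float("nan")
        rows.append(
            {
                "metric": m,
                "n": n,
                "pre_mean": float(np.mean(pre)),
                "pre_sd": float(np.std(pre, ddof=1)),
                "post_mean": float(np.mean(post)),
                "post_sd": float(np.std(post, ddof=1)),
                "pct_change": pct,
                "p": p,
                "g": es.g,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "label": es.label,
            }
        )
    return pd.DataFrame(rows)
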