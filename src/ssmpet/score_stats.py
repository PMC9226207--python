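"""Statistics on pattern-expression scores.

Covers the four analyses run on subject scores: ROC classification of AD vs
HC with the Youden-index threshold and a 95% AUC confidence interval
(stratified bootstrap by default, DeLong optionally), one-way ANOVA across
the four clinical groups with Tukey HSD correction, a general linear model of
one method's scores on another's, and Bland–Altman agreement with its
1.96 x SD limits and a bias regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .comparison import RegressionResult


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    youden_j: float


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, se, p_unadjusted, p_adjusted


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_intercept: float
    pct_within_loa: float


def _roc_sweep(pos: np.ndarray, neg: np.ndarray):
    """Sensitivity/specificity at midpoint thresholds (plus +/- inf sentinels).

    A subject is called positive when its score is >= the threshold (the
    positive class scores higher).
    """
    values = np.unique(np.concatenate([pos, neg]))
    mids = 0.5 * (values[:-1] + values[1:]) if len(values) > 1 else np.array([])
    thresholds = np.concatenate([[-np.inf], values[:1] - 1.0, mids, values[-1:] + 1.0, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return thresholds, sens, spec


def _auc_trapezoid(sens: np.ndarray, spec: np.ndarray) -> float:
    # integrate along the threshold sweep: fpr runs monotonically from 1 to 0,
    # vertical segments contribute nothing and tie diagonals half-count
    fpr = 1.0 - spec
    return float(-np.trapezoid(sens, fpr))


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    _, sens, spec = _roc_sweep(pos, neg)
    return _auc_trapezoid(sens, spec)


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann–Whitney probability: (#concordant + 0.5 #ties) / (n1 n0)."""
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI from the structural components of the AUC estimator."""
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / len(neg) for p in pos])
    v01 = np.array([((pos > n).sum() + 0.5 * (pos == n).sum()) / len(pos) for n in neg])
    var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
    half = 1.959963984540054 * np.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_youden(
    scores: np.ndarray,
    labels,
    positive: str = "AD",
    negative: str = "HC",
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ROCResult:
    """ROC analysis of a two-class score set.

    The AUC is the trapezoidal area under the empirical curve (identical to
    the Mann–Whitney probability); the classification threshold maximises
    Youden's J = sensitivity + specificity - 1 (ties resolved to the lowest
    threshold).  The 95% AUC CI is a stratified percentile bootstrap
    (``n_boot`` resamples, seeded) or DeLong if requested.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels == negative]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"both {positive!r} and {negative!r} scores are required")
    thresholds, sens, spec = _roc_sweep(pos, neg)
    auc = _auc_trapezoid(sens, spec)
    j = sens + spec - 1.0
    best = np.flatnonzero(np.isclose(j, j.max()))
    finite = thresholds[best][np.isfinite(thresholds[best])]
    youden_threshold = float(finite.min()) if len(finite) else float(thresholds[best].min())
    if ci_method == "delong":
        ci = _delong_ci(pos, neg, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = mann_whitney_auc(
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            )
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        youden_threshold=youden_threshold,
        youden_j=float(j.max()),
    )


def anova_tukey(scores: np.ndarray, groups) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons.

    Every group needs >= 2 members; identical values in all groups leave F
    undefined and raise.  Pairwise rows carry the mean difference, its pooled
    standard error, the unadjusted t-test p (pooled MSE) and the Tukey
    adjusted p from the studentized-range distribution.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    samples = [scores[groups == g] for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    n_total = len(scores)
    k = len(names)
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if sse == 0:
        raise ValueError("zero within-group variance; F statistic undefined")
    f_stat, p_value = stats.f_oneway(*samples)
    df_w = n_total - k
    mse = sse / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = b.mean() - a.mean()
            se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
            t = diff / se
            p_unadj = 2.0 * stats.t.sf(abs(t), df_w)
            # studentized range uses q = |diff| / sqrt(MSE/2 * (1/na + 1/nb))
            q = abs(diff) / np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(diff),
                    "se": float(se),
                    "p_unadjusted": float(p_unadj),
                    "p_adjusted": min(1.0, p_adj),
                }
            )
    return AnovaTukeyResult(float(f_stat), float(p_value), pd.DataFrame(rows))


def score_regression(y_scores: np.ndarray, x_scores: np.ndarray) -> RegressionResult:
    """General linear model of one method's scores on another's (simple OLS)."""
    y = np.asarray(y_scores, dtype=float)
    x = np.asarray(x_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired scores")
    if x.std() == 0:
        raise ValueError("independent scores are constant")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        r=float(fit.rvalue),
    )


def bland_altman(
    y_scores: np.ndarray, x_scores: np.ndarray, bias_regressor: str = "mean"
) -> BlandAltmanResult:
    """Bland–Altman agreement between two paired score sets.

    Differences are y - x; the limits of agreement are mean +/- 1.96 x SD.
    The bias regression regresses the difference on the pair mean by default
    (``bias_regressor="mean"``), or on x (``"x"``) for the reference-anchored
    variant.
    """
    y = np.asarray(y_scores, dtype=float)
    x = np.asarray(x_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired score vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    diff = y - x
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa_low, loa_high = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    if bias_regressor == "mean":
        reg_x = 0.5 * (x + y)
    elif bias_regressor == "x":
        reg_x = x
    else:
        raise ValueError(f"unknown bias_regressor {bias_regressor!r}")
    if reg_x.std() == 0 or sd == 0:
        slope, intercept = 0.0, mean_diff
    else:
        fit = stats.linregress(reg_x, diff)
        slope, intercept = float(fit.slope), float(fit.intercept)
    within = float(((diff >= loa_low) & (diff <= loa_high)).mean() * 100.0)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        bias_slope=slope,
        bias_intercept=intercept,
        pct_within_loa=within,
    )
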