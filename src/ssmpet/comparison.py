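"""Voxel-level comparison of two disease patterns.

Three views of pattern agreement: the Pearson correlation over mask voxels,
a joint histogram (displayed on a log10 count scale), and an ordinary
least-squares regression of one pattern on the other — by convention the
metabolic (FDG) pattern is the independent variable and the blood-flow
surrogate the dependent one.  Voxels are treated as independent observations;
spatial autocorrelation is acknowledged but not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class JointHistogram:
    """2D histogram of paired voxel values, with a log10 display copy."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (n_bins, n_bins) integers
    log10_display: np.ma.MaskedArray  # log10(counts), empty bins masked


@dataclass
class RegressionResult:
    """Simple OLS summary: y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    r: float = float("nan")


def _pattern_values(dp, mask: np.ndarray | None) -> np.ndarray:
    """Accept a DiseasePattern, a 3D volume (+mask) or a 1D value vector."""
    from .ssm_pca import DiseasePattern
    from .types import ImageVolume

    if isinstance(dp, DiseasePattern):
        return dp.weights
    if isinstance(dp, ImageVolume):
        dp = dp.data
    dp = np.asarray(dp, dtype=float)
    if dp.ndim == 3:
        if mask is None:
            raise ValueError("a 3D pattern volume needs a mask")
        return dp[np.asarray(mask, dtype=bool)]
    if dp.ndim == 1:
        return dp
    raise ValueError(f"cannot interpret a {dp.ndim}D pattern input")


def pattern_correlation(dp_a, dp_b, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two patterns over the mask voxels."""
    a = _pattern_values(dp_a, mask)
    b = _pattern_values(dp_b, mask)
    if a.shape != b.shape:
        raise ValueError("patterns have different numbers of mask voxels")
    if len(a) < 3:
        raise ValueError("need at least 3 voxels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("a pattern has zero variance; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def joint_histogram(dp_x, dp_y, mask: np.ndarray | None = None, n_bins: int = 64) -> JointHistogram:
    """Joint histogram of paired voxel values.

    Equal-width bins span each pattern's own value range; the total count
    always equals the number of mask voxels.  The display copy is log10 of
    the counts with empty bins masked out.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = _pattern_values(dp_x, mask)
    y = _pattern_values(dp_y, mask)
    if x.shape != y.shape:
        raise ValueError("patterns have different numbers of mask voxels")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins)
    counts = counts.astype(int)
    display = np.ma.masked_where(counts == 0, np.log10(np.where(counts > 0, counts, 1)))
    return JointHistogram(x_edges, y_edges, counts, display)


def voxel_regression(dp_y, dp_x, mask: np.ndarray | None = None) -> RegressionResult:
    """OLS of the dependent pattern on the independent one over mask voxels."""
    y = _pattern_values(dp_y, mask)
    x = _pattern_values(dp_x, mask)
    if x.shape != y.shape:
        raise ValueError("patterns have different numbers of mask voxels")
    if len(x) < 3:
        raise ValueError("need at least 3 voxels")
    if x.std() == 0:
        raise ValueError("independent pattern has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        r=float(fit.rvalue),
    )
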