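"""Per-lens summaries, group statistics, and calibration-based estimates."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_LEVELS = (95.0, 99.0, 99.5)


@dataclass
class LensSummary:
    """Pixel-weighted feature means over all slices of one lens."""

    lens_id: str
    group: str
    means: dict = field(default_factory=dict)       # feature -> mean
    ci95: dict = field(default_factory=dict)        # feature -> CI half-width
    n_pixels: int = 0
    flags: dict = field(default_factory=dict)


@dataclass
class GroupComparison:
    """Two-sample comparison of one feature between two groups."""

    feature: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    percent_diff: float
    t_statistic: float
    dof: float
    p_value: float
    significant_at: tuple


@dataclass
class PercentEstimate:
    """Calibrated percent of amyloid-like structure with a CI interval."""

    percent: float
    lo: float
    hi: float
    clamped: bool = False


def mean_ci(values, confidence: float = 0.95) -> tuple[float, float, int]:
    """Mean and Student-t CI half-width of a sample of pixel values.

    Returns (mean, half_width, n); half_width is NaN for n < 2 (flag it).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        raise ValueError("no usable pixel values")
    m = float(v.mean())
    if n < 2:
        return m, math.nan, n
    se = float(v.std(ddof=1)) / math.sqrt(n)
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return m, tq * se, n


def summarize_lens(tables, lens_id: str, group: str,
                   features=("diag_ratio", "xpeak_intensity")) -> LensSummary:
    """Pool per-pixel feature tables from all slices of one lens.

    ``tables`` is a sequence of pandas DataFrames as produced by
    :func:`amide2d.imaging.feature_table`; only rows with ``qc_flag`` true
    contribute.
    """
    import pandas as pd

    frames = [t[t["qc_flag"]] for t in tables]
    pooled = pd.concat(frames, ignore_index=True) if frames else None
    if pooled is None or len(pooled) == 0:
        raise ValueError(f"lens {lens_id!r}: zero usable pixels")
    out = LensSummary(lens_id=lens_id, group=group, n_pixels=len(pooled))
    for feat in features:
        m, hw, n = mean_ci(pooled[feat].to_numpy())
        out.means[feat] = m
        out.ci95[feat] = hw
        if not np.isfinite(hw):
            out.flags[feat] = "ci-undefined (single pixel)"
    return out


def percent_difference(mean_a: float, mean_b: float, ndigits: int | None = 2) -> float:
    """(mean_a - mean_b) / mean_b x 100, the paper-style percent change."""
    if mean_b == 0:
        raise ValueError("reference mean is zero; percent difference undefined")
    pd_ = (mean_a - mean_b) / mean_b * 100.0
    return round(pd_, ndigits) if ndigits is not None else pd_


def compare_groups(
    values_a,
    values_b,
    levels=DEFAULT_LEVELS,
    equal_var: bool = False,
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-tailed two-sample t-test (Welch by default) at several levels.

    ``significant_at`` contains level L iff p < 1 - L/100; it is therefore
    downward-closed in the ordering of significance levels.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    dof = float(getattr(res, "df", a.size + b.size - 2))
    if not np.isfinite(t):  # identical constant groups: no evidence either way
        t, p = 0.0, 1.0
        dof = float(a.size + b.size - 2)
    sig = tuple(L for L in sorted(levels) if p < 1.0 - L / 100.0)
    return GroupComparison(
        feature=feature, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        percent_diff=percent_difference(float(a.mean()), float(b.mean()),
                                        ndigits=None),
        t_statistic=t, dof=dof, p_value=p, significant_at=sig,
    )


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear map between percent amyloid and a feature."""

    percents: np.ndarray
    feature_values: np.ndarray
    feature_name: str = "diag_ratio"
    increasing: bool = True

    def forward(self, percent: float) -> float:
        """Feature value predicted for a given percent (interpolated)."""
        return float(np.interp(percent, self.percents, self.feature_values))

    def inverse(self, value: float, with_flag: bool = False):
        """Percent for a feature value; clamped to the calibrated range."""
        f = self.feature_values if self.increasing else self.feature_values[::-1]
        p = self.percents if self.increasing else self.percents[::-1]
        clamped = bool(value < f[0] or value > f[-1])
        pct = float(np.clip(np.interp(value, f, p), 0.0, 100.0))
        return (pct, clamped) if with_flag else pct


def fit_calibration(standards, feature_name: str = "diag_ratio") -> CalibrationCurve:
    """Fit a monotone piecewise-linear calibration from known standards.

    ``standards`` is a sequence of (percent, feature_value) pairs, at least
    three, with strictly monotone feature values once sorted by percent.
    """
    arr = np.asarray(sorted((float(p), float(v)) for p, v in standards))
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 calibration standards")
    p, v = arr[:, 0], arr[:, 1]
    if np.unique(p).size != p.size:
        raise ValueError("duplicate percent values among standards")
    dv = np.diff(v)
    if np.all(dv > 0):
        increasing = True
    elif np.all(dv < 0):
        increasing = False
    else:
        raise ValueError(
            "standards are not monotone in the feature: "
            + ", ".join(f"({pi:g}%, {vi:.6g})" for pi, vi in arr)
        )
    return CalibrationCurve(p, v, feature_name, increasing)


def estimate_percent_amyloid(
    lens: LensSummary | float,
    curve: CalibrationCurve,
    ci95: float | None = None,
) -> PercentEstimate:
    """Map a lens feature mean (and its CI) through the calibration inverse.

    ``lens`` may be a LensSummary (the curve's feature column is used) or a
    bare mean value with an explicit ``ci95`` half-width.
    """
    if isinstance(lens, LensSummary):
        mean = lens.means[curve.feature_name]
        half = lens.ci95.get(curve.feature_name, math.nan)
    else:
        mean = float(lens)
        half = math.nan if ci95 is None else float(ci95)
    pct, clamped = curve.inverse(mean, with_flag=True)
    if np.isfinite(half):
        lo, c1 = curve.inverse(mean - half, with_flag=True)
        hi, c2 = curve.inverse(mean + half, with_flag=True)
        lo, hi = sorted((lo, hi))
        clamped = clamped or c1 or c2
    else:
        lo = hi = pct
    return PercentEstimate(percent=pct, lo=lo, hi=hi, clamped=clamped)
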