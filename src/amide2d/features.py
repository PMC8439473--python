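"""Per-spectrum feature extraction.

Diagonal slices, class normalization, diagonal ratios, peak frequencies,
baseline-subtracted cross-peak intensity and location, and anharmonic shift.
All features are invariant to an overall positive rescaling of the raw
spectrum once the class normalization is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import (
    DIAG_RATIO_DEN,
    DIAG_RATIO_NUM,
    FREQ_TOLERANCE,
    NORMALIZATION_FREQS,
    PEAK_BAND,
    XPEAK_PROBE_MOUSE,
    XPEAK_PUMP,
)
from .core import FeatureQCError, Spectrum2D, nearest_index


@dataclass
class DiagonalSlice:
    """Intensity along the pump=probe line, positive-sign convention.

    ``sign`` records whether the raw spectrum was globally flipped so the
    fundamental band reads positive.
    """

    freq: np.ndarray
    intensity: np.ndarray
    norm_freq: float | None = None
    normalized: bool = False
    sign: float = 1.0


@dataclass
class CrossPeakMeasurement:
    """Baseline-subtracted cross-peak readout at one probe frequency."""

    probe_freq: float
    pump_slice: np.ndarray
    pump_freqs: np.ndarray
    baseline: np.ndarray
    intensity: float
    max_coords: tuple[float, float]


@dataclass
class AnharmonicityMeasurement:
    """Probe separation between the fundamental maximum and overtone minimum."""

    pump_freq: float
    shift: float


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic interpolation of an extremum at index ``i``.

    Returns (position, value); falls back to the grid point at array edges.
    """
    if i <= 0 or i >= len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y1)
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1.0, 1.0))
    spacing = float(x[i + 1] - x[i]) if d >= 0 else float(x[i] - x[i - 1])
    return float(x[i] + d * spacing), float(y1 - 0.25 * (y0 - y2) * d)


def diagonal_slice(s: Spectrum2D, min_overlap: float = 20.0) -> DiagonalSlice:
    """Extract the amplitude along the pump=probe diagonal.

    For each probe grid frequency inside the pump/probe overlap, the value at
    the nearest pump grid point (within the probe resolution) is taken.  If
    the band maximum is globally negative the slice is sign-flipped so the
    fundamental reads positive.
    """
    lo = max(s.pump_axis[0], s.probe_axis[0])
    hi = min(s.pump_axis[-1], s.probe_axis[-1])
    if hi - lo < min_overlap:
        raise ValueError(
            f"pump/probe axis overlap [{lo}, {hi}] is narrower than "
            f"{min_overlap} cm^-1"
        )
    j_sel = np.nonzero((s.probe_axis >= lo) & (s.probe_axis <= hi))[0]
    freqs = s.probe_axis[j_sel]
    i_sel = np.array([nearest_index(s.pump_axis, f) for f in freqs])
    intensity = s.amplitude[i_sel, j_sel].astype(float)
    sign = 1.0
    if intensity.size and np.any(intensity != 0):
        if intensity[int(np.argmax(np.abs(intensity)))] < 0:
            sign = -1.0
            intensity = -intensity
    return DiagonalSlice(freqs.copy(), intensity, sign=sign)


def normalize_slice(
    d: DiagonalSlice, sample_class: str, qc_floor: float = 0.0
) -> DiagonalSlice:
    """Divide the slice by its intensity at the class normalization frequency.

    Raises :class:`FeatureQCError` when the normalization intensity does not
    exceed the QC floor (signal-void / torn pixel).  Idempotent.
    """
    try:
        norm_freq = NORMALIZATION_FREQS[sample_class]
    except KeyError:
        valid = ", ".join(sorted(NORMALIZATION_FREQS))
        raise ValueError(f"unknown sample class {sample_class!r}; valid: {valid}")
    idx = nearest_index(d.freq, norm_freq)
    denom = float(d.intensity[idx])
    if denom <= qc_floor:
        raise FeatureQCError(
            f"normalization intensity {denom:.3g} at {norm_freq} cm^-1 is "
            f"at/below the QC floor {qc_floor:.3g}"
        )
    return replace(d, intensity=d.intensity / denom, norm_freq=norm_freq,
                   normalized=True)


def diagonal_ratio(
    d: DiagonalSlice,
    f_num: float = DIAG_RATIO_NUM,
    f_den: float = DIAG_RATIO_DEN,
    qc_floor: float = 0.0,
) -> float:
    """Intensity ratio I(f_num)/I(f_den) on the (normalized) diagonal slice."""
    i_num = nearest_index(d.freq, f_num)
    i_den = nearest_index(d.freq, f_den)
    denom = float(d.intensity[i_den])
    if denom <= qc_floor:
        raise FeatureQCError(
            f"ratio denominator {denom:.3g} at {f_den} cm^-1 is at/below the "
            f"QC floor {qc_floor:.3g}"
        )
    return float(d.intensity[i_num]) / denom


def peak_frequency(d: DiagonalSlice, band: tuple[float, float] = PEAK_BAND) -> float:
    """Frequency of the slice maximum inside ``band``, to 0.1 cm^-1.

    The grid maximum is refined by 3-point parabolic interpolation; a maximum
    sitting on the band edge is flagged as unusable.
    """
    sel = np.nonzero((d.freq >= band[0]) & (d.freq <= band[1]))[0]
    if sel.size < 3:
        raise ValueError(f"band {band} contains fewer than 3 grid points")
    k = int(np.argmax(d.intensity[sel]))
    if k == 0 or k == sel.size - 1:
        raise FeatureQCError(f"diagonal maximum lies on the edge of band {band}")
    # parabolic sub-bin refinement over a 5-point window: a least-squares
    # parabola is linear in the intensities, which keeps the refined position
    # unbiased under additive noise (a bare 3-point vertex is not, because
    # noise toggles the argmax between near-equal neighbours)
    lo = max(0, k - 2)
    hi = min(sel.size, k + 3)
    idx = sel[lo:hi]
    x = d.freq[idx] - d.freq[sel[k]]
    c2, c1, _ = np.polyfit(x, d.intensity[idx], 2)
    if c2 >= 0:
        f = float(d.freq[sel[k]])
    else:
        f = float(d.freq[sel[k]]) + float(np.clip(-c1 / (2.0 * c2), -2.5, 2.5))
    return round(f, 1)


_DEFAULT_FLANKS = ((-25.0, -12.0), (12.0, 25.0))


def _resolve_flanks(pump_freq, flank_windows, spacing):
    if flank_windows is None:
        flanks = [(pump_freq + a, pump_freq + b) for a, b in _DEFAULT_FLANKS]
    else:
        flanks = [tuple(map(float, w)) for w in flank_windows]
    if len(flanks) != 2 or any(b <= a for a, b in flanks):
        raise ValueError("flank_windows must be two (lo, hi) intervals with lo < hi")
    guard = 3.0 * spacing
    for a, b in flanks:
        if a < pump_freq + guard and b > pump_freq - guard:
            raise ValueError(
                f"flank window ({a}, {b}) overlaps the peak window "
                f"[{pump_freq - guard}, {pump_freq + guard}]"
            )
    return flanks


def _fit_baseline(pump_axis, pump_slice, flanks):
    sel = np.zeros(pump_axis.size, dtype=bool)
    for a, b in flanks:
        sel |= (pump_axis >= a) & (pump_axis <= b)
    if sel.sum() < 2:
        raise ValueError("flank windows contain fewer than 2 grid points")
    coef = np.polyfit(pump_axis[sel], pump_slice[sel], 1)
    return np.polyval(coef, pump_axis)


def crosspeak_measure(
    s: Spectrum2D,
    probe_freq: float = XPEAK_PROBE_MOUSE,
    pump_freq: float = XPEAK_PUMP,
    flank_windows=None,
    row_average: int = 1,
    sign: float = 1.0,
) -> CrossPeakMeasurement:
    """Cross-peak intensity at (pump_freq, probe_freq) after baseline removal.

    The pump slice at the probe row nearest ``probe_freq`` (optionally
    averaged over ``row_average`` adjacent rows) is fitted with a straight
    baseline over two flank windows; the intensity is the baseline-subtracted
    value at ``pump_freq``.  Pass ``sign=-1`` for spectra recorded with the
    opposite instrument convention.
    """
    spacing = float(np.median(np.diff(s.probe_axis)))
    flanks = _resolve_flanks(pump_freq, flank_windows, spacing)
    j = nearest_index(s.probe_axis, probe_freq)
    half = (max(1, int(row_average)) - 1) // 2
    j0, j1 = max(0, j - half), min(s.probe_axis.size, j + half + 1)
    pump_slice = sign * s.amplitude[:, j0:j1].mean(axis=1)
    baseline = _fit_baseline(s.pump_axis, pump_slice, flanks)
    ip = nearest_index(s.pump_axis, pump_freq)
    residual = pump_slice - baseline
    inner = (s.pump_axis > flanks[0][1]) & (s.pump_axis < flanks[1][0])
    inner_idx = np.nonzero(inner)[0]
    k = inner_idx[int(np.argmax(residual[inner_idx]))]
    f_max, _ = _parabolic_refine(s.pump_axis, residual, k)
    return CrossPeakMeasurement(
        probe_freq=float(s.probe_axis[j]),
        pump_slice=pump_slice,
        pump_freqs=s.pump_axis.copy(),
        baseline=baseline,
        intensity=float(residual[ip]),
        max_coords=(f_max, float(s.probe_axis[j])),
    )


def crosspeak_locate(
    s: Spectrum2D,
    search_box=((1615.0, 1645.0), (1680.0, 1715.0)),
    noise_floor: float | None = None,
    sign: float = 1.0,
):
    """Coordinates of the baseline-subtracted cross-peak maximum, or None.

    Each probe row inside the box gets its own straight-line baseline (flanks
    placed relative to the box's pump center, as in
    :func:`crosspeak_measure`).  Returns ``None`` ("not detected") when no
    positive interior maximum exceeds the noise floor (default: 5x the robust
    noise estimate of the spectrum).
    """
    (p_lo, p_hi), (b_lo, b_hi) = search_box
    if p_lo < s.pump_axis[0] or p_hi > s.pump_axis[-1] or \
            b_lo < s.probe_axis[0] or b_hi > s.probe_axis[-1]:
        raise ValueError("search box extends beyond the spectrum axes")
    if noise_floor is None:
        noise_floor = 5.0 * robust_noise_sd(s)
    spacing = float(np.median(np.diff(s.probe_axis)))
    center = 0.5 * (p_lo + p_hi)
    flanks = _resolve_flanks(center, None, spacing)

    i_sel = np.nonzero((s.pump_axis >= p_lo) & (s.pump_axis <= p_hi))[0]
    j_sel = np.nonzero((s.probe_axis >= b_lo) & (s.probe_axis <= b_hi))[0]
    if i_sel.size < 3 or j_sel.size < 3:
        raise ValueError("search box contains fewer than 3 grid points per axis")
    residual = np.empty((i_sel.size, j_sel.size))
    for col, j in enumerate(j_sel):
        pump_slice = sign * s.amplitude[:, j]
        base = _fit_baseline(s.pump_axis, pump_slice, flanks)
        residual[:, col] = (pump_slice - base)[i_sel]
    ki, kj = np.unravel_index(int(np.argmax(residual)), residual.shape)
    if residual[ki, kj] <= max(noise_floor, 0.0):
        return None
    if ki in (0, i_sel.size - 1) or kj in (0, j_sel.size - 1):
        return None  # maximum on the box edge: no interior positive lobe
    f_pump, _ = _parabolic_refine(s.pump_axis[i_sel], residual[:, kj], ki)
    f_probe, _ = _parabolic_refine(s.probe_axis[j_sel], residual[ki, :], kj)
    return (round(f_pump, 1), round(f_probe, 1))


def anharmonicity(
    s: Spectrum2D, band: tuple[float, float] = PEAK_BAND
) -> AnharmonicityMeasurement:
    """Anharmonic shift at the pump frequency of the diagonal maximum.

    On the probe slice through the diagonal maximum, the shift is the probe
    frequency of the positive fundamental maximum minus that of the negative
    overtone minimum below it, each refined parabolically.
    """
    d = diagonal_slice(s)
    sel = np.nonzero((d.freq >= band[0]) & (d.freq <= band[1]))[0]
    if sel.size == 0:
        raise ValueError(f"band {band} is outside the diagonal slice")
    i_diag = sel[int(np.argmax(d.intensity[sel]))]
    ip = nearest_index(s.pump_axis, float(d.freq[i_diag]))
    probe_slice = d.sign * s.amplitude[ip, :]

    jmax = int(np.argmax(probe_slice))
    f_pos, _ = _parabolic_refine(s.probe_axis, probe_slice, jmax)
    below = np.nonzero(s.probe_axis < s.probe_axis[jmax])[0]
    if below.size == 0 or probe_slice[below].min() >= 0:
        raise FeatureQCError("no negative overtone lobe below the fundamental")
    jmin = below[int(np.argmin(probe_slice[below]))]
    f_neg, _ = _parabolic_refine(s.probe_axis, probe_slice, jmin)
    shift = f_pos - f_neg
    if shift < 0:
        raise FeatureQCError("overtone minimum found above the fundamental")
    return AnharmonicityMeasurement(pump_freq=float(s.pump_axis[ip]),
                                    shift=float(shift))


def robust_noise_sd(s: Spectrum2D, block: int = 8) -> float:
    """Robust noise estimate from a signal-free corner of the grid.

    Uses the scaled median absolute deviation of the (low-pump, high-probe)
    corner block, which the amide-I band presets never reach.
    """
    corner = s.amplitude[:block, -block:]
    mad = np.median(np.abs(corner - np.median(corner)))
    return 1.4826 * float(mad)


def pixel_features(
    s: Spectrum2D,
    sample_class: str,
    probe_freq: float = XPEAK_PROBE_MOUSE,
    pump_freq: float = XPEAK_PUMP,
    qc_floor: float = 0.0,
    band: tuple[float, float] = PEAK_BAND,
) -> dict:
    """All per-pixel scalar features, with a QC flag instead of exceptions.

    Returns a dict with keys diag_ratio, xpeak_intensity, peak_freq, anharm,
    qc_flag (True = usable) and qc_reason.  Cross-peak intensity is reported
    on the normalized scale (per unit of diagonal intensity at the class
    normalization frequency).
    """
    out = {k: math.nan for k in ("diag_ratio", "xpeak_intensity", "peak_freq", "anharm")}
    out["qc_flag"] = False
    out["qc_reason"] = ""
    d = diagonal_slice(s)
    try:
        dn = normalize_slice(d, sample_class, qc_floor=qc_floor)
    except FeatureQCError as e:
        out["qc_reason"] = str(e)
        return out
    out["diag_ratio"] = diagonal_ratio(dn)
    try:
        out["peak_freq"] = peak_frequency(dn, band=band)
    except FeatureQCError as e:
        out["qc_reason"] = str(e)
        return out
    norm_val = float(d.intensity[nearest_index(d.freq, dn.norm_freq)])
    cp = crosspeak_measure(s, probe_freq=probe_freq, pump_freq=pump_freq,
                           sign=d.sign)
    out["xpeak_intensity"] = cp.intensity / norm_val
    try:
        out["anharm"] = anharmonicity(s, band=band).shift
    except FeatureQCError as e:
        out["qc_reason"] = str(e)
        return out
    out["qc_flag"] = True
    return out
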