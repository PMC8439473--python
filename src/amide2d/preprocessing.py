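"""Raw stage data -> calibrated 2D spectra.

Implements the four-frame phase-cycling combination, the pump-delay Fourier
transform onto the pump frequency axis, and the affine probe-axis
calibration against known water-line absorption frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .constants import C_CM_PER_FS, FREQ_TOLERANCE, PHASE_CYCLE_COEFFS, N_PHASE_FRAMES
from .core import Spectrum2D
from .spectral_model import RawPixelRecord


def combine_phase_frames(frames: np.ndarray, frame_axis: int = 1) -> np.ndarray:
    """Background-suppressed linear combination of the four phase frames.

    Applies the fixed (+, -, -, +)/4 coefficients along ``frame_axis``;
    common-mode (frame-independent) contributions cancel exactly and the
    combination is linear in every frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[frame_axis] != N_PHASE_FRAMES:
        raise ValueError(
            f"expected {N_PHASE_FRAMES} phase frames along axis {frame_axis}, "
            f"got {frames.shape[frame_axis]}"
        )
    coeffs = np.asarray(PHASE_CYCLE_COEFFS)
    return np.tensordot(coeffs, np.moveaxis(frames, frame_axis, 0), axes=([0], [0]))


def transform_pump_axis(
    delays: np.ndarray,
    signal: np.ndarray,
    window: str | None = "hann",
    zero_pad: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Fourier transform pump-delay data into a pump-frequency spectrum.

    ``signal`` has the delay dimension first; the returned amplitudes are the
    real part of the discrete Fourier transform, normalized so a pure
    bin-centered cosine of amplitude A is recovered with amplitude A.
    Apodization (Hann by default) and zero padding are optional; disable both
    for exact round trips.
    """
    delays = np.asarray(delays, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if delays.ndim != 1 or delays.size < 2:
        raise ValueError("need at least two delays")
    steps = np.diff(delays)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise ValueError("delays must be uniformly spaced")
    if signal.shape[0] != delays.size:
        raise ValueError("signal first dimension must match the delay count")
    if zero_pad < 1:
        raise ValueError("zero_pad must be >= 1")

    n = delays.size
    if window is None:
        w = np.ones(n)
    elif window == "hann":
        w = windows.hann(n, sym=False)
    else:
        raise ValueError(f"unknown window {window!r} (use 'hann' or None)")
    shaped = signal * w.reshape((n,) + (1,) * (signal.ndim - 1))
    nfft = int(zero_pad) * n
    spec = 2.0 * np.real(np.fft.rfft(shaped, n=nfft, axis=0)) / w.sum()
    freqs = np.fft.rfftfreq(nfft, d=steps[0]) / C_CM_PER_FS
    return freqs, spec


@dataclass
class ProbeCalibration:
    """Affine detector-pixel -> frequency mapping fitted to reference lines."""

    pixels: np.ndarray
    freqs: np.ndarray
    slope: float
    intercept: float
    residuals: np.ndarray

    def axis(self, n_pixels: int = 64) -> np.ndarray:
        """Calibrated probe axis for an ``n_pixels``-element detector."""
        ax = self.intercept + self.slope * np.arange(n_pixels, dtype=float)
        return ax if self.slope > 0 else ax[::-1]

    def pixel_to_freq(self, pixel) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(pixel, dtype=float)


def calibrate_probe_axis(lines) -> ProbeCalibration:
    """Least-squares affine fit of detector pixel index to known frequencies.

    ``lines`` is a sequence of (pixel_index, frequency cm^-1) pairs; at least
    two distinct pixels are required and the fitted mapping must be strictly
    monotone (non-zero slope).
    """
    arr = np.asarray(list(lines), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (pixel, frequency) reference lines")
    px, fr = arr[:, 0], arr[:, 1]
    if np.unique(px).size < 2:
        raise ValueError("reference lines must span at least 2 distinct pixels")
    slope, intercept = np.polyfit(px, fr, 1)
    if slope == 0:
        raise ValueError("calibration fit is not monotone (zero slope)")
    residuals = fr - (intercept + slope * px)
    return ProbeCalibration(px, fr, float(slope), float(intercept), residuals)


def frequencies_equal(f1: float, f2: float, resolution: float = FREQ_TOLERANCE) -> bool:
    """True when two frequencies agree within the probe resolution."""
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise ValueError("frequencies must be finite")
    return abs(f1 - f2) <= resolution


def reconstruct_spectrum(
    record: RawPixelRecord,
    pump_axis: np.ndarray,
    window: str | None = None,
    zero_pad: int = 1,
) -> Spectrum2D:
    """Full preprocessing path: phase combination, pump FFT, axis selection.

    With no window and no zero padding this inverts
    :func:`amide2d.spectral_model.emit_time_domain` exactly when the delay
    grid is the aligned default.
    """
    combined = combine_phase_frames(record.frames, frame_axis=1)
    freqs, spec = transform_pump_axis(record.delays, combined,
                                      window=window, zero_pad=zero_pad)
    pump_axis = np.asarray(pump_axis, dtype=float)
    bin_spacing = freqs[1] - freqs[0]
    idx = np.rint((pump_axis - freqs[0]) / bin_spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= freqs.size):
        raise ValueError("requested pump axis outside the transformed range")
    off = np.max(np.abs(freqs[idx] - pump_axis))
    if off > bin_spacing / 2 + 1e-9:
        raise ValueError("pump axis does not align with the transform bins")
    return Spectrum2D(pump_axis, record.probe_axis, spec[idx, :],
                      meta=dict(record.meta))
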