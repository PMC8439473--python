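"""Core data containers: single 2D spectra and spatial cubes of spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import FREQ_TOLERANCE, PROBE_SPACING


class FrequencyMatchError(ValueError):
    """No axis grid point lies within the matching tolerance of a frequency."""


class FeatureQCError(RuntimeError):
    """A per-pixel measurement failed a quality-control criterion."""


def nearest_index(axis: np.ndarray, freq: float, tol: float = FREQ_TOLERANCE) -> int:
    """Index of the axis point closest to ``freq``.

    Raises :class:`FrequencyMatchError` if the nearest grid point is farther
    than ``tol`` (default: the probe resolution, under which two frequencies
    are considered the same).
    """
    axis = np.asarray(axis, dtype=float)
    idx = int(np.argmin(np.abs(axis - freq)))
    if abs(axis[idx] - freq) > tol:
        raise FrequencyMatchError(
            f"no grid point within {tol} cm^-1 of {freq} cm^-1 "
            f"(axis spans {axis[0]}..{axis[-1]})"
        )
    return idx


def default_axes(
    lo: float = 1580.0, n: int = 64, spacing: float = PROBE_SPACING
) -> tuple[np.ndarray, np.ndarray]:
    """Default calibrated (pump, probe) axes for a 64-element detector."""
    ax = lo + spacing * np.arange(n, dtype=float)
    return ax, ax.copy()


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} must be a 1-D array with >= 2 points")
    if not np.all(np.diff(axis) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return axis


@dataclass
class Spectrum2D:
    """A signed 2D amplitude grid over calibrated pump/probe frequency axes.

    ``amplitude`` is indexed ``[pump, probe]``; the sign convention is that
    fundamental (diagonal) lobes are positive and overtone lobes negative.
    """

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump_axis = _check_axis("pump_axis", self.pump_axis)
        self.probe_axis = _check_axis("probe_axis", self.probe_axis)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (self.pump_axis.size, self.probe_axis.size):
            raise ValueError(
                f"amplitude shape {self.amplitude.shape} does not match axes "
                f"({self.pump_axis.size}, {self.probe_axis.size})"
            )

    def value_at(self, pump: float, probe: float, tol: float = FREQ_TOLERANCE) -> float:
        """Amplitude at the grid point nearest (pump, probe), within ``tol``."""
        ip = nearest_index(self.pump_axis, pump, tol)
        jp = nearest_index(self.probe_axis, probe, tol)
        return float(self.amplitude[ip, jp])

    def scaled(self, k: float) -> "Spectrum2D":
        return Spectrum2D(self.pump_axis, self.probe_axis, self.amplitude * k,
                          dict(self.meta))


@dataclass
class TissueCube:
    """A spatial grid of 2D spectra sharing one axis pair, plus masks.

    ``amplitude`` is indexed ``[x, y, pump, probe]``.  ``mask`` flags pixels
    inside the scanned lens area; torn (signal-void) pixels remain inside the
    mask and are rejected downstream by QC.  ``truth_fraction`` and
    ``truth_tear`` are generator-only ground truth and must be absent for
    measured data.
    """

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    amplitude: np.ndarray
    mask: np.ndarray
    truth_fraction: np.ndarray | None = None
    truth_tear: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump_axis = _check_axis("pump_axis", self.pump_axis)
        self.probe_axis = _check_axis("probe_axis", self.probe_axis)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 4:
            raise ValueError("amplitude must be 4-D: [x, y, pump, probe]")
        nx, ny, npump, nprobe = self.amplitude.shape
        if nx == 0 or ny == 0:
            raise ValueError("empty cube: zero pixels")
        if (npump, nprobe) != (self.pump_axis.size, self.probe_axis.size):
            raise ValueError("spectral dimensions do not match the axes")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (nx, ny):
            raise ValueError("mask shape must be (nx, ny)")
        if not np.all(np.isfinite(self.amplitude[self.mask])):
            raise ValueError("masked-in pixels must have finite amplitudes")
        if self.truth_fraction is not None:
            self.truth_fraction = np.asarray(self.truth_fraction, dtype=float)
            if self.truth_fraction.shape != (nx, ny):
                raise ValueError("truth_fraction shape must be (nx, ny)")
            if np.nanmin(self.truth_fraction) < 0 or np.nanmax(self.truth_fraction) > 1:
                raise ValueError("truth_fraction must lie in [0, 1]")
        if self.truth_tear is not None:
            self.truth_tear = np.asarray(self.truth_tear, dtype=bool)
            if self.truth_tear.shape != (nx, ny):
                raise ValueError("truth_tear shape must be (nx, ny)")

    @property
    def nx(self) -> int:
        return self.amplitude.shape[0]

    @property
    def ny(self) -> int:
        return self.amplitude.shape[1]

    def spectrum(self, ix: int, iy: int) -> Spectrum2D:
        """The single-pixel spectrum at spatial index (ix, iy)."""
        meta = dict(self.meta)
        meta["pixel"] = (int(ix), int(iy))
        return Spectrum2D(self.pump_axis, self.probe_axis,
                          self.amplitude[ix, iy], meta)

    def mean_spectrum(self, where: np.ndarray | None = None) -> Spectrum2D:
        """Average spectrum over ``where`` (default: the lens mask)."""
        sel = self.mask if where is None else np.asarray(where, dtype=bool)
        if not sel.any():
            raise ValueError("no pixels selected")
        meta = dict(self.meta)
        meta["pixel"] = "bulk"
        return Spectrum2D(self.pump_axis, self.probe_axis,
                          self.amplitude[sel].mean(axis=0), meta)
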