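"""Spatial feature maps, torn-region QC rejection, and distributions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    DISPLAY_RANGES,
    NORMALIZATION_FREQS,
    PROBE_SPACING,
    QC_FLOOR_MULTIPLIER,
    XPEAK_PROBE_MOUSE,
    XPEAK_PUMP,
)
from .core import TissueCube, nearest_index
from .features import pixel_features, robust_noise_sd

FEATURE_NAMES = ("diag_ratio", "xpeak_intensity", "peak_freq", "anharm")


@dataclass
class FeatureMap:
    """One per-pixel scalar field plus its usability mask.

    ``display_range`` is the fixed rendering scale; data values outside it
    are clamped only at render time, never in the stored values.
    """

    values: np.ndarray
    qc_mask: np.ndarray
    feature_name: str
    display_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
        if self.values.shape != self.qc_mask.shape:
            raise ValueError("values and qc_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.qc_mask])):
            raise ValueError("values must be finite wherever qc_mask is true")

    def usable_values(self) -> np.ndarray:
        return self.values[self.qc_mask]


@dataclass
class FrequencyHistogram:
    """Percent-of-locations distribution over frequency bins."""

    bin_edges: np.ndarray
    percent_of_locations: np.ndarray

    @property
    def mode(self) -> float:
        k = int(np.argmax(self.percent_of_locations))
        return 0.5 * float(self.bin_edges[k] + self.bin_edges[k + 1])


def cube_noise_floor(cube: TissueCube, multiplier: float = QC_FLOOR_MULTIPLIER) -> float:
    """QC floor for a cube: multiplier x pooled robust noise of its pixels."""
    block = cube.amplitude[:, :, :8, -8:]
    mad = np.median(np.abs(block - np.median(block)))
    return multiplier * 1.4826 * float(mad)


def reject_torn_regions(
    cube: TissueCube,
    sample_class: str | None = None,
    floor: float | None = None,
) -> np.ndarray:
    """Usability mask: inside the lens and with signal at the norm frequency.

    A pixel is rejected when its raw diagonal amplitude at the class
    normalization frequency does not exceed the QC floor (default 5x the
    pooled robust noise estimate), or when it lies outside the lens mask.
    Contiguity is not required.
    """
    sample_class = sample_class or cube.meta.get("sample_class")
    if sample_class not in NORMALIZATION_FREQS:
        raise ValueError(f"unknown or missing sample class {sample_class!r}")
    f = NORMALIZATION_FREQS[sample_class]
    ip = nearest_index(cube.pump_axis, f)
    jp = nearest_index(cube.probe_axis, f)
    if floor is None:
        floor = cube_noise_floor(cube)
    signal = np.abs(cube.amplitude[:, :, ip, jp])
    return cube.mask & (signal > floor)


def build_feature_map(
    cube: TissueCube,
    feature: str,
    sample_class: str | None = None,
    probe_freq: float = XPEAK_PROBE_MOUSE,
    pump_freq: float = XPEAK_PUMP,
    floor: float | None = None,
) -> FeatureMap:
    """Per-pixel feature field over the usable (masked, non-torn) pixels."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}; valid: {FEATURE_NAMES}")
    sample_class = sample_class or cube.meta.get("sample_class")
    if floor is None:
        floor = cube_noise_floor(cube)
    usable = reject_torn_regions(cube, sample_class, floor=floor)
    values = np.full((cube.nx, cube.ny), np.nan)
    qc = np.zeros((cube.nx, cube.ny), dtype=bool)
    for ix, iy in np.argwhere(usable):
        feats = pixel_features(cube.spectrum(ix, iy), sample_class,
                               probe_freq=probe_freq, pump_freq=pump_freq,
                               qc_floor=floor)
        v = feats[feature]
        if feats["qc_flag"] and np.isfinite(v):
            values[ix, iy] = v
            qc[ix, iy] = True
    if not qc.any():
        raise ValueError("no usable pixels after QC rejection")
    return FeatureMap(values, qc, feature, DISPLAY_RANGES[feature])


def feature_table(
    cube: TissueCube,
    sample_class: str | None = None,
    probe_freq: float = XPEAK_PROBE_MOUSE,
    pump_freq: float = XPEAK_PUMP,
):
    """Tidy per-pixel feature records for all masked-in pixels.

    Returns a pandas DataFrame with pixel_x, pixel_y, the four features and
    qc_flag; rejected pixels carry NaN features and qc_flag False.
    """
    import pandas as pd

    sample_class = sample_class or cube.meta.get("sample_class")
    floor = cube_noise_floor(cube)
    usable = reject_torn_regions(cube, sample_class, floor=floor)
    rows = []
    for ix, iy in np.argwhere(cube.mask):
        if usable[ix, iy]:
            feats = pixel_features(cube.spectrum(ix, iy), sample_class,
                                   probe_freq=probe_freq, pump_freq=pump_freq,
                                   qc_floor=floor)
        else:
            feats = {k: np.nan for k in FEATURE_NAMES}
            feats["qc_flag"] = False
            feats["qc_reason"] = "torn/outside-signal pixel"
        rows.append({"pixel_x": ix, "pixel_y": iy,
                     **{k: feats[k] for k in FEATURE_NAMES},
                     "qc_flag": bool(feats["qc_flag"])})
    return pd.DataFrame(rows)


def frequency_histogram(
    fmap: FeatureMap,
    bin_width: float = PROBE_SPACING,
    grid_anchor: float = 1580.0,
) -> FrequencyHistogram:
    """Percent-of-locations histogram of a peak-frequency map.

    Bin edges are aligned to the probe grid (anchored at ``grid_anchor``
    minus half a bin so grid frequencies fall at bin centers).
    """
    vals = fmap.usable_values()
    if vals.size == 0:
        raise ValueError("no usable pixels to histogram")
    start = grid_anchor - 0.5 * bin_width
    lo = start + bin_width * np.floor((vals.min() - start) / bin_width)
    hi = start + bin_width * np.ceil((vals.max() - start) / bin_width + 1e-9)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(vals, bins=edges)
    percent = 100.0 * counts / counts.sum()
    return FrequencyHistogram(edges, percent)


def render_map_png(fmap: FeatureMap, path, cmap: str = "viridis") -> None:
    """Optional rendered image with the fixed display scale (clamped).

    Images are presentation artifacts only; the matrix text written by the
    pipeline remains the data of record.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = fmap.display_range
    shown = np.where(fmap.qc_mask, np.clip(fmap.values, lo, hi), np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(shown.T, origin="lower", vmin=lo, vmax=hi, cmap=cmap)
    ax.set_title(fmap.feature_name)
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=120)
    plt.close(fig)
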