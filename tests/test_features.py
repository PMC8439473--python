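"""Unit tests for per-spectrum feature extraction."""

import numpy as np
import pytest

from amide2d import Spectrum2D, compose_spectrum, render_component, simulate_cube
from amide2d.core import FeatureQCError, default_axes
from amide2d.features import (
    DiagonalSlice,
    anharmonicity,
    crosspeak_locate,
    crosspeak_measure,
    diagonal_ratio,
    diagonal_slice,
    normalize_slice,
    peak_frequency,
    pixel_features,
)

from conftest import rotated_gauss


def analytic_mixture_diag(freqs, components, weights):
    """Oracle: diagonal values of a weighted component sum, dense-evaluable."""
    total = np.zeros_like(freqs, dtype=float)
    for w, c in zip(weights, components):
        f = freqs
        fund = rotated_gauss(f, f, c.omega0, c.omega0, c.sigma_diag, c.sigma_antidiag)
        over = rotated_gauss(f, f, c.omega0, c.omega0 - c.delta,
                             c.sigma_diag, c.sigma_antidiag)
        total += w * c.mu**4 * (fund - over)
    return total


class TestDiagonalSlice:
    def test_native_ffpe_argmax_near_1641(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        d = diagonal_slice(s)
        assert abs(d.freq[np.argmax(d.intensity)] - 1641.0) <= 2.5

    def test_zero_spectrum_zero_slice(self, pump_axis, probe_axis):
        s = Spectrum2D(pump_axis, probe_axis,
                       np.zeros((pump_axis.size, probe_axis.size)))
        d = diagonal_slice(s)
        assert np.abs(d.intensity).max() == 0.0

    def test_isotropic_gaussian_matches_1d_gaussian(self, pump_axis, probe_axis):
        # DERIVED: closed-form Gaussian along the diagonal parametrization.
        P, B = np.meshgrid(pump_axis, probe_axis, indexing="ij")
        sigma = 6.0
        s = Spectrum2D(pump_axis, probe_axis,
                       rotated_gauss(P, B, 1636.0, 1636.0, sigma, sigma))
        d = diagonal_slice(s)
        expected = np.exp(-((d.freq - 1636.0) ** 2) / (2 * sigma**2))
        np.testing.assert_allclose(d.intensity, expected, atol=1e-12)

    def test_negative_convention_flipped(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        neg = Spectrum2D(pump_axis, probe_axis, -s.amplitude)
        d = diagonal_slice(neg)
        assert d.sign == -1.0
        assert d.intensity[np.argmax(np.abs(d.intensity))] > 0

    def test_no_overlap_rejected(self, probe_axis):
        pump = np.arange(1400.0, 1460.0, 2.5)
        s = Spectrum2D(pump, probe_axis, np.zeros((pump.size, probe_axis.size)))
        with pytest.raises(ValueError, match="overlap"):
            diagonal_slice(s)


class TestNormalizeSlice:
    def test_ffpe_value_at_1641_is_one(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        d = normalize_slice(diagonal_slice(s), "tissue_FFPE")
        idx = np.argmin(np.abs(d.freq - 1641.0))
        assert d.intensity[idx] == pytest.approx(1.0)

    def test_idempotent(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        d1 = normalize_slice(diagonal_slice(s), "tissue_FFPE")
        d2 = normalize_slice(d1, "tissue_FFPE")
        np.testing.assert_allclose(d1.intensity, d2.intensity, atol=1e-12)

    def test_scale_invariance(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        d = normalize_slice(diagonal_slice(s), "tissue_FFPE")
        dk = normalize_slice(diagonal_slice(s.scaled(37.2)), "tissue_FFPE")
        np.testing.assert_allclose(d.intensity, dk.intensity, atol=1e-12)

    def test_floor_violation_flagged(self, pump_axis, probe_axis):
        s = Spectrum2D(pump_axis, probe_axis,
                       np.zeros((pump_axis.size, probe_axis.size)))
        with pytest.raises(FeatureQCError):
            normalize_slice(diagonal_slice(s), "tissue_FFPE", qc_floor=0.01)

    def test_unknown_class_rejected(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, pump_axis, probe_axis)
        with pytest.raises(ValueError, match="tissue_FFPE"):
            normalize_slice(diagonal_slice(s), "tissue_martian")


class TestDiagonalRatio:
    def test_pure_native_matches_analytic(self, pump_axis, ffpe_library):
        # DERIVED: analytic two-lobe diagonal evaluated at the matched grid
        # points, including the overtone contribution.
        nat = ffpe_library[0]
        s = compose_spectrum({"native_beta": 1.0}, ffpe_library, *default_axes())
        d = normalize_slice(diagonal_slice(s), "tissue_FFPE")
        r = diagonal_ratio(d)
        freqs = d.freq
        analytic = analytic_mixture_diag(freqs, [nat], [1.0])
        i36 = np.argmin(np.abs(freqs - 1636.0))
        i41 = np.argmin(np.abs(freqs - 1641.0))
        assert r == pytest.approx(analytic[i36] / analytic[i41], rel=1e-9)

    def test_flat_slice_ratio_one(self):
        freqs = np.arange(1600.0, 1660.0, 2.5)
        d = DiagonalSlice(freqs, np.ones_like(freqs))
        assert diagonal_ratio(d) == pytest.approx(1.0)

    def test_mutant_pixel_exceeds_wt_pixel(self):
        wt = simulate_cube("wt_mouse", 12, 12, noise_sd=0.0, seed=9)
        mut = simulate_cube("r120g_mouse", 12, 12, noise_sd=0.0, seed=9)
        cx, cy = 6, 6
        r_wt = diagonal_ratio(normalize_slice(
            diagonal_slice(wt.spectrum(cx, cy)), "tissue_FFPE"))
        r_mut = diagonal_ratio(normalize_slice(
            diagonal_slice(mut.spectrum(cx, cy)), "tissue_FFPE"))
        assert r_mut > r_wt

    def test_zero_denominator_flagged(self):
        freqs = np.arange(1600.0, 1660.0, 2.5)
        d = DiagonalSlice(freqs, np.zeros_like(freqs))
        with pytest.raises(FeatureQCError):
            diagonal_ratio(d)


class TestPeakFrequency:
    def test_protein_r120g_printed_value(self):
        from amide2d.spectral_model import GENOTYPES, make_component_library

        g = GENOTYPES["protein_R120G"]
        lib = make_component_library(g.environment, subject="protein",
                                     native_omega0=g.native_omega0)
        s = compose_spectrum({"native_beta": 1.0}, lib, *default_axes())
        assert abs(peak_frequency(diagonal_slice(s)) - 1633.0) <= 2.5

    def test_single_impulse_exact(self):
        freqs = 1601.0 + 2.5 * np.arange(24)  # grid holds 1626.0 exactly
        y = np.zeros_like(freqs)
        y[10] = 1.0  # 1626.0
        assert peak_frequency(DiagonalSlice(freqs, y)) == pytest.approx(1626.0)

    def test_two_gaussian_mixture_vs_dense_grid_search(self):
        # DERIVED: brute-force 0.01 cm^-1 grid search on the analytic sum.
        def f(x):
            return (0.7 * np.exp(-((x - 1641.0) ** 2) / (2 * 36.0))
                    + 0.3 * np.exp(-((x - 1636.0) ** 2) / (2 * 36.0)))

        dense = np.arange(1600.0, 1660.0, 0.01)
        oracle = dense[np.argmax(f(dense))]
        grid = np.arange(1580.0, 1740.0, 2.5)
        est = peak_frequency(DiagonalSlice(grid, f(grid)))
        assert abs(est - oracle) <= 0.2

    def test_band_edge_flagged(self):
        freqs = np.arange(1600.0, 1660.0, 2.5)
        y = freqs - freqs[0]  # monotone: max on the band edge
        with pytest.raises(FeatureQCError, match="edge"):
            peak_frequency(DiagonalSlice(freqs, y))


class TestCrossPeak:
    def test_linear_slice_zero_intensity(self, pump_axis, probe_axis):
        P, B = np.meshgrid(pump_axis, probe_axis, indexing="ij")
        s = Spectrum2D(pump_axis, probe_axis, 0.02 * P + 3.0)
        m = crosspeak_measure(s, probe_freq=1701.0, pump_freq=1632.0)
        assert abs(m.intensity) < 1e-12

    def test_gaussian_bump_on_ramp_recovered(self, pump_axis, probe_axis):
        # DERIVED: additive construction; flanks placed where the sigma=5
        # bump's tails are < 1e-9 so the stated 1e-6 tolerance is reachable.
        h, sigma = 0.42, 5.0
        P, B = np.meshgrid(pump_axis, probe_axis, indexing="ij")
        ramp = 0.01 * P - 15.0
        bump = h * np.exp(-((P - 1632.0) ** 2) / (2 * sigma**2))
        s = Spectrum2D(pump_axis, probe_axis, ramp + bump)
        m = crosspeak_measure(s, probe_freq=1701.0, pump_freq=1632.0,
                              flank_windows=((1562.0, 1580.0), (1684.0, 1702.0)))
        ip = np.argmin(np.abs(pump_axis - 1632.0))
        expected = h * np.exp(-((pump_axis[ip] - 1632.0) ** 2) / (2 * sigma**2))
        assert m.intensity == pytest.approx(expected, abs=1e-6)

    def test_mutant_intensity_exceeds_wt(self):
        wt = simulate_cube("wt_mouse", 12, 12, noise_sd=0.0, seed=10)
        mut = simulate_cube("r120g_mouse", 12, 12, noise_sd=0.0, seed=10)
        f_wt = pixel_features(wt.spectrum(6, 6), "tissue_FFPE")
        f_mut = pixel_features(mut.spectrum(6, 6), "tissue_FFPE")
        assert f_mut["xpeak_intensity"] > f_wt["xpeak_intensity"]

    def test_overlapping_flanks_rejected(self, pump_axis, probe_axis):
        s = Spectrum2D(pump_axis, probe_axis,
                       np.zeros((pump_axis.size, probe_axis.size)))
        with pytest.raises(ValueError, match="overlap"):
            crosspeak_measure(s, probe_freq=1701.0, pump_freq=1632.0,
                              flank_windows=((1628.0, 1636.0), (1644.0, 1657.0)))

    def test_locate_mutant_mouse_printed_coords(self):
        cube = simulate_cube("r120g_mouse", 12, 12, noise_sd=0.0, seed=11)
        loc = crosspeak_locate(cube.mean_spectrum())
        assert loc is not None
        assert abs(loc[0] - 1632.0) <= 2.5
        assert abs(loc[1] - 1701.0) <= 2.5

    def test_locate_human_cataract_printed_coords(self):
        cube = simulate_cube("cataract_human", 12, 12, noise_sd=0.0, seed=11)
        loc = crosspeak_locate(cube.mean_spectrum())
        assert loc is not None
        assert abs(loc[0] - 1632.0) <= 2.5
        assert abs(loc[1] - 1695.0) <= 2.5

    def test_locate_helix_only_not_detected(self, pump_axis, probe_axis, ffpe_library):
        s = compose_spectrum({"helix_coil": 1.0}, ffpe_library, pump_axis, probe_axis)
        assert crosspeak_locate(s) is None


class TestAnharmonicity:
    def test_isolated_component_round_trip(self, pump_axis, probe_axis, ffpe_library):
        nat = ffpe_library[0]
        s = render_component(nat, pump_axis, probe_axis)
        m = anharmonicity(s)
        assert abs(m.shift - nat.delta) <= 1.25

    def test_mutant_median_below_wt(self):
        medians = {}
        for preset in ("wt_mouse", "r120g_mouse"):
            cube = simulate_cube(preset, 12, 12, noise_sd=0.0, seed=12)
            shifts = [anharmonicity(cube.spectrum(ix, iy)).shift
                      for ix, iy in np.argwhere(cube.mask)]
            medians[preset] = np.median(shifts)
        assert medians["r120g_mouse"] < medians["wt_mouse"]

    def test_mixture_vs_dense_grid_oracle(self, pump_axis, probe_axis, ffpe_library):
        # DERIVED: dense grid search on the analytic probe slice at the same
        # pump row the operation uses.
        nat, amy = ffpe_library[0], ffpe_library[1]
        s = compose_spectrum({"native_beta": 0.5, "amyloid_beta": 0.5},
                             ffpe_library, pump_axis, probe_axis)
        m = anharmonicity(s)
        pump_row = m.pump_freq

        def probe_profile(y):
            total = np.zeros_like(y)
            for w, c in [(0.5, nat), (0.5, amy)]:
                total += w * c.mu**4 * (
                    rotated_gauss(pump_row, y, c.omega0, c.omega0,
                                  c.sigma_diag, c.sigma_antidiag)
                    - rotated_gauss(pump_row, y, c.omega0, c.omega0 - c.delta,
                                    c.sigma_diag, c.sigma_antidiag))
            return total

        dense = np.arange(1590.0, 1680.0, 0.01)
        prof = probe_profile(dense)
        f_pos = dense[np.argmax(prof)]
        below = dense < f_pos
        f_neg = dense[below][np.argmin(prof[below])]
        assert m.shift == pytest.approx(f_pos - f_neg, abs=0.3)

    def test_no_negative_lobe_flagged(self, pump_axis, probe_axis):
        P, B = np.meshgrid(pump_axis, probe_axis, indexing="ij")
        s = Spectrum2D(pump_axis, probe_axis,
                       rotated_gauss(P, B, 1641.0, 1641.0, 8.0, 4.0))
        with pytest.raises(FeatureQCError):
            anharmonicity(s)


class TestScaleInvariance:
    def test_all_features_invariant_to_positive_scaling(self):
        cube = simulate_cube("r120g_mouse", 12, 12, noise_sd=0.0, seed=13)
        s = cube.spectrum(6, 6)
        f1 = pixel_features(s, "tissue_FFPE")
        f2 = pixel_features(s.scaled(123.4), "tissue_FFPE")
        for key in ("diag_ratio", "xpeak_intensity", "peak_freq", "anharm"):
            assert f1[key] == pytest.approx(f2[key], rel=1e-9)
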