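"""Synthetic-data generator for amide-I 2D infrared spectra and tissue cubes.

Spectra are composed from secondary-structure component bands.  Each band is
a pair of opposite-sign 2D Gaussian lobes (fundamental positive, overtone
negative, separated by the anharmonic shift along the probe axis) whose
amplitude scales with the fourth power of the transition dipole.  Beta-sheet
components additionally carry a cross-peak lobe pair off the diagonal.

Whole lens slices are simulated as elliptical masks over a spatial grid with
a smoothly varying amyloid-like fraction field, optional torn (signal-void)
regions, and additive Gaussian noise.  The generator can also emit raw
pump-delay interferograms (with four-frame phase cycling) for round-trip
testing of the preprocessing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .constants import C_CM_PER_FS, N_PHASE_FRAMES
from .core import Spectrum2D, TissueCube, default_axes


# --------------------------------------------------------------------------
# component and preset tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossPeak:
    """Off-diagonal coupling peak attached to a beta-sheet component.

    ``nu_perp`` is the probe frequency of the positive cross-peak lobe and
    ``amplitude_ratio`` its height as a fraction of the component's diagonal
    amplitude.  ``nu_pump`` optionally decouples the cross-peak pump
    coordinate from the diagonal frequency (the observed maximum sits at a
    smaller pump frequency than the diagonal band).
    """

    nu_perp: float
    amplitude_ratio: float
    nu_pump: float | None = None


@dataclass(frozen=True)
class SpectralComponent:
    """One secondary-structure band of the amide-I region."""

    name: str
    omega0: float
    delta: float
    sigma_diag: float
    sigma_antidiag: float
    mu: float
    crosspeak: CrossPeak | None = None

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta (anharmonic shift) must be > 0")
        if not (self.sigma_diag >= self.sigma_antidiag > 0):
            raise ValueError("require sigma_diag >= sigma_antidiag > 0")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.crosspeak is not None:
            if "beta" not in self.name:
                raise ValueError("cross peaks are restricted to beta-sheet components")
            if not self.crosspeak.nu_perp > self.omega0:
                raise ValueError("crosspeak nu_perp must exceed omega0")

    @property
    def sigma_probe(self) -> float:
        """Effective 1-D Gaussian width of a diagonal lobe along the probe axis."""
        sd, sa = self.sigma_diag, self.sigma_antidiag
        return 2.0 * sd * sa / np.hypot(sd, sa)


@dataclass(frozen=True)
class EnvironmentPreset:
    """Component frequency table for one tissue-preservation environment."""

    name: str
    native_beta: float
    amyloid_beta: float
    helix_coil: float
    sample_class: str


ENVIRONMENTS = {
    "frozen": EnvironmentPreset("frozen", 1632.0, 1621.0, 1650.0, "tissue_frozen"),
    "dried": EnvironmentPreset("dried", 1636.0, 1629.0, 1651.0, "tissue_dried"),
    "ffpe": EnvironmentPreset("ffpe", 1641.0, 1636.0, 1652.0, "tissue_FFPE"),
}

# Cross-peak geometry: the positive lobe sits at a pump frequency a few cm^-1
# below the amyloid diagonal frequency and a probe frequency ~60-65 cm^-1
# above it; human lenses show a smaller probe frequency than mutant mice.
_XPEAK_PUMP_OFFSET = -4.0
_XPEAK_PERP_OFFSET = {"mouse": 65.0, "human": 59.0, "protein": 65.0}


@dataclass(frozen=True)
class GenotypePreset:
    """Generator parameters for one sample type.

    ``amyloid_mean``/``amyloid_sd`` set the spatial amyloid-fraction field;
    ``helix_weight`` adds the alpha-helix/random-coil shoulder seen in human
    lenses; ``native_omega0`` overrides the native-beta frequency for the
    purified-protein presets.
    """

    name: str
    subject: str                      # mouse | human | protein
    amyloid_mean: float
    amyloid_sd: float
    helix_weight: float = 0.0
    environment: str = "ffpe"
    native_omega0: float | None = None
    sample_class: str | None = None   # overrides the environment's class


GENOTYPES = {
    "wt_mouse": GenotypePreset("wt_mouse", "mouse", 0.01, 0.005),
    "r120g_mouse": GenotypePreset("r120g_mouse", "mouse", 0.025, 0.008),
    "juvenile_human": GenotypePreset("juvenile_human", "human", 0.005, 0.003, 0.2),
    "cataract_human": GenotypePreset("cataract_human", "human", 0.04, 0.01, 0.2),
    "protein_aB": GenotypePreset(
        "protein_aB", "protein", 0.0, 0.0, environment="frozen",
        native_omega0=1639.0, sample_class="protein_aB"),
    "protein_R120G": GenotypePreset(
        "protein_R120G", "protein", 0.0, 0.0, environment="frozen",
        native_omega0=1633.0, sample_class="protein_R120G"),
}


def make_component_library(
    preset: str | EnvironmentPreset,
    subject: str = "mouse",
    native_omega0: float | None = None,
) -> list[SpectralComponent]:
    """Build the three-component band library for one environment.

    ``subject`` selects the cross-peak probe frequency ("mouse" -> 1701 for
    the fixed-tissue amyloid band, "human" -> 1695).  ``native_omega0``
    optionally overrides the native beta-sheet frequency (used for the
    purified-protein presets).
    """
    if isinstance(preset, str):
        try:
            preset = ENVIRONMENTS[preset]
        except KeyError:
            valid = ", ".join(sorted(ENVIRONMENTS))
            raise ValueError(f"unknown environment preset {preset!r}; valid presets: {valid}")
    if subject not in _XPEAK_PERP_OFFSET:
        valid = ", ".join(sorted(_XPEAK_PERP_OFFSET))
        raise ValueError(f"unknown subject {subject!r}; valid subjects: {valid}")

    nat0 = preset.native_beta if native_omega0 is None else float(native_omega0)
    amy0 = preset.amyloid_beta
    perp = _XPEAK_PERP_OFFSET[subject]
    native = SpectralComponent(
        name="native_beta", omega0=nat0, delta=14.0,
        sigma_diag=10.0, sigma_antidiag=2.8, mu=1.0,
        crosspeak=CrossPeak(nu_perp=nat0 + 51.0, amplitude_ratio=0.01),
    )
    amyloid = SpectralComponent(
        name="amyloid_beta", omega0=amy0, delta=10.0,
        sigma_diag=8.0, sigma_antidiag=2.5, mu=1.45,
        crosspeak=CrossPeak(nu_perp=amy0 + perp, amplitude_ratio=0.25,
                            nu_pump=amy0 + _XPEAK_PUMP_OFFSET),
    )
    helix = SpectralComponent(
        name="helix_coil", omega0=preset.helix_coil, delta=14.0,
        sigma_diag=14.0, sigma_antidiag=4.8, mu=0.9,
    )
    return [native, amyloid, helix]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _gauss_rotated(P, B, cx, cy, sigma_diag, sigma_antidiag):
    """Correlated 2D Gaussian in rotated (diagonal, anti-diagonal) coordinates.

    The diagonal coordinate is measured as per-axis displacement along the
    pump=probe line, i.e. d = (dx + dy) / 2 and a = (dy - dx) / 2, so that a
    point displaced by t along the diagonal has d = t.
    """
    dx = P - cx
    dy = B - cy
    d = 0.5 * (dx + dy)
    a = 0.5 * (dy - dx)
    return np.exp(-d ** 2 / (2.0 * sigma_diag ** 2) - a ** 2 / (2.0 * sigma_antidiag ** 2))


def _gauss_separable(P, B, cx, cy, sx, sy):
    return np.exp(-(P - cx) ** 2 / (2.0 * sx ** 2) - (B - cy) ** 2 / (2.0 * sy ** 2))


def _check_coverage(c: SpectralComponent, pump_axis, probe_axis) -> None:
    """Reject axes that would truncate more than ~1% of a component's mass.

    Implemented as a 4-sigma coverage rule on every lobe; at four standard
    deviations the omitted tail mass is far below the 1% budget.
    """
    sd, sy, sa = c.sigma_diag, c.sigma_probe, c.sigma_antidiag
    need = [
        ("pump", c.omega0 - 4 * sd, c.omega0 + 4 * sd),
        ("probe", c.omega0 - c.delta - 4 * sy, c.omega0 + 4 * sy),
    ]
    if c.crosspeak is not None:
        cp = c.crosspeak
        cx = c.omega0 if cp.nu_pump is None else cp.nu_pump
        need.append(("pump", cx - 4 * sd, cx + 4 * sd))
        need.append(("probe", cp.nu_perp - c.delta - 4 * sa, cp.nu_perp + 4 * sa))
    axes = {"pump": pump_axis, "probe": probe_axis}
    for which, lo, hi in need:
        ax = axes[which]
        if ax[0] > lo or ax[-1] < hi:
            raise ValueError(
                f"axes too narrow for component {c.name!r}: {which} axis must "
                f"cover [{lo:.1f}, {hi:.1f}] cm^-1 (truncation would exceed "
                f"1% of the peak mass)"
            )


def render_component(
    c: SpectralComponent,
    pump_axis: np.ndarray,
    probe_axis: np.ndarray,
    check_coverage: bool = True,
) -> Spectrum2D:
    """Render one component band onto the given axes.

    Amplitude is ``mu**4 * [G(center (w0, w0)) - G(center (w0, w0 - delta))]``
    with a correlated-Gaussian lineshape, plus (for beta-sheet components) a
    cross-peak lobe pair at (nu_pump, nu_perp) / (nu_pump, nu_perp - delta)
    scaled by ``amplitude_ratio``.
    """
    pump_axis = np.asarray(pump_axis, dtype=float)
    probe_axis = np.asarray(probe_axis, dtype=float)
    if check_coverage:
        _check_coverage(c, pump_axis, probe_axis)
    P, B = np.meshgrid(pump_axis, probe_axis, indexing="ij")
    amp = _gauss_rotated(P, B, c.omega0, c.omega0, c.sigma_diag, c.sigma_antidiag)
    amp -= _gauss_rotated(P, B, c.omega0, c.omega0 - c.delta,
                          c.sigma_diag, c.sigma_antidiag)
    if c.crosspeak is not None:
        cp = c.crosspeak
        cx = c.omega0 if cp.nu_pump is None else cp.nu_pump
        xp = _gauss_separable(P, B, cx, cp.nu_perp, c.sigma_diag, c.sigma_antidiag)
        xp -= _gauss_separable(P, B, cx, cp.nu_perp - c.delta,
                               c.sigma_diag, c.sigma_antidiag)
        amp += cp.amplitude_ratio * xp
    amp *= c.mu ** 4
    return Spectrum2D(pump_axis, probe_axis, amp, {"component": c.name})


def compose_spectrum(
    weights: dict[str, float],
    library: list[SpectralComponent],
    pump_axis: np.ndarray,
    probe_axis: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_class: str | None = None,
) -> Spectrum2D:
    """Weighted sum of rendered components plus i.i.d. Gaussian noise.

    ``weights`` maps component names to non-negative fractions summing to 1;
    components absent from the mapping get weight 0.  Deterministic under a
    fixed ``rng`` seed.
    """
    names = [c.name for c in library]
    unknown = set(weights) - set(names)
    if unknown:
        raise ValueError(f"weights refer to unknown components: {sorted(unknown)}")
    w = np.array([float(weights.get(n, 0.0)) for n in names])
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    amp = np.zeros((len(pump_axis), len(probe_axis)))
    for wi, c in zip(w, library):
        if wi > 0:
            amp += wi * render_component(c, pump_axis, probe_axis).amplitude
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        amp = amp + gen.normal(0.0, noise_sd, size=amp.shape)
    meta = {"weights": dict(weights), "noise_sd": float(noise_sd)}
    if sample_class is not None:
        meta["sample_class"] = sample_class
    return Spectrum2D(np.asarray(pump_axis, float), np.asarray(probe_axis, float),
                      amp, meta)


# --------------------------------------------------------------------------
# tissue-cube simulation
# --------------------------------------------------------------------------

def _smooth_fraction_field(nx, ny, mean, sd, smooth_px, rng, cap):
    """Low-pass-filtered white noise, rescaled to (mean, sd), clipped to [0, cap]."""
    z = rng.standard_normal((nx, ny))
    if smooth_px > 0:
        z = ndimage.gaussian_filter(z, sigma=smooth_px, mode="reflect")
        s = z.std()
        if s > 0:
            z = (z - z.mean()) / s
    return np.clip(mean + sd * z, 0.0, cap)


def _grow_tear(mask, target, rng):
    """Grow one contiguous torn region of ``target`` pixels inside ``mask``."""
    nx, ny = mask.shape
    inside = np.argwhere(mask)
    seed = tuple(inside[rng.integers(len(inside))])
    torn = np.zeros_like(mask)
    frontier = [seed]
    count = 0
    while frontier and count < target:
        k = int(rng.integers(len(frontier)))
        x, y = frontier.pop(k)
        if torn[x, y] or not mask[x, y]:
            continue
        torn[x, y] = True
        count += 1
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            u, v = x + dx, y + dy
            if 0 <= u < nx and 0 <= v < ny and mask[u, v] and not torn[u, v]:
                frontier.append((u, v))
    return torn


def elliptical_mask(nx: int, ny: int, fill: float = 0.9) -> np.ndarray:
    """Lens-shaped (elliptical) boolean mask covering ``fill`` of each axis."""
    x = (np.arange(nx) - (nx - 1) / 2.0) / (fill * nx / 2.0)
    y = (np.arange(ny) - (ny - 1) / 2.0) / (fill * ny / 2.0)
    return (x[:, None] ** 2 + y[None, :] ** 2) <= 1.0


def simulate_cube(
    preset: str | GenotypePreset,
    nx: int = 16,
    ny: int = 16,
    amyloid_field_params: dict | None = None,
    tear_params: dict | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    environment: str | None = None,
    pump_axis: np.ndarray | None = None,
    probe_axis: np.ndarray | None = None,
) -> TissueCube:
    """Simulate one lens-slice cube for a genotype preset.

    The amyloid fraction varies smoothly across the lens; torn regions (if
    requested) zero the signal but stay inside the lens mask so that the QC
    stage must find them.  Ground truth is stored on the cube.
    """
    if isinstance(preset, str):
        try:
            preset = GENOTYPES[preset]
        except KeyError:
            valid = ", ".join(sorted(GENOTYPES))
            raise ValueError(f"unknown genotype preset {preset!r}; valid presets: {valid}")
    if nx < 8 or ny < 8:
        raise ValueError("nx and ny must be >= 8")

    env_name = environment or preset.environment
    env = ENVIRONMENTS.get(env_name)
    if env is None:
        valid = ", ".join(sorted(ENVIRONMENTS))
        raise ValueError(f"unknown environment {env_name!r}; valid presets: {valid}")
    sample_class = preset.sample_class or env.sample_class
    library = make_component_library(env, subject=preset.subject,
                                     native_omega0=preset.native_omega0)

    fp = dict(amyloid_field_params or {})
    mean = float(fp.pop("mean", preset.amyloid_mean))
    sd = float(fp.pop("sd", preset.amyloid_sd))
    smooth_px = float(fp.pop("smooth_px", 2.0))
    if fp:
        raise ValueError(f"unknown amyloid_field_params keys: {sorted(fp)}")
    if not 0.0 <= mean <= 1.0:
        raise ValueError("amyloid field mean must lie in [0, 1]")

    if pump_axis is None or probe_axis is None:
        pump_axis, probe_axis = default_axes()
    rng = np.random.default_rng(seed)

    mask = elliptical_mask(nx, ny)
    cap = 1.0 - preset.helix_weight
    fraction = _smooth_fraction_field(nx, ny, mean, sd, smooth_px, rng, cap)

    torn = np.zeros((nx, ny), dtype=bool)
    tp = dict(tear_params or {})
    tear_fraction = float(tp.pop("fraction", 0.0))
    n_regions = int(tp.pop("n_regions", 1))
    if tp:
        raise ValueError(f"unknown tear_params keys: {sorted(tp)}")
    if tear_fraction > 0:
        target_total = int(round(tear_fraction * mask.sum()))
        for _ in range(n_regions):
            remaining = target_total - torn.sum()
            if remaining <= 0:
                break
            per = int(np.ceil(remaining / max(1, n_regions - _)))
            torn |= _grow_tear(mask & ~torn, min(per, remaining), rng)

    bases = np.stack([render_component(c, pump_axis, probe_axis).amplitude
                      for c in library])           # (3, npump, nprobe)
    w = np.empty((nx, ny, len(library)))
    w[..., 0] = 1.0 - fraction - preset.helix_weight   # native_beta
    w[..., 1] = fraction                               # amyloid_beta
    w[..., 2] = preset.helix_weight                    # helix_coil

    amp = np.tensordot(w, bases, axes=([2], [0]))      # (nx, ny, npump, nprobe)
    amp[torn] = 0.0
    if noise_sd > 0:
        amp += rng.normal(0.0, noise_sd, size=amp.shape)

    meta = {
        "preset": preset.name,
        "environment": env.name,
        "sample_class": sample_class,
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "subject": preset.subject,
    }
    return TissueCube(pump_axis, probe_axis, amp, mask,
                      truth_fraction=fraction, truth_tear=torn, meta=meta)


# --------------------------------------------------------------------------
# raw time-domain emission
# --------------------------------------------------------------------------

@dataclass
class RawPixelRecord:
    """Raw stage data for one spatial location.

    ``frames`` holds the four phase-cycling detector readouts per pump delay
    per probe pixel, indexed ``[delay, frame, probe_pixel]``.
    """

    delays: np.ndarray
    frames: np.ndarray
    probe_axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if not np.all(np.diff(self.delays) > 0):
            raise ValueError("delays must be strictly increasing")
        if self.frames.ndim != 3 or self.frames.shape[1] != N_PHASE_FRAMES:
            raise ValueError("frames must have shape (n_delays, 4, n_probe)")
        if self.frames.shape[0] != self.delays.size:
            raise ValueError("frames and delays disagree on n_delays")


def default_delay_grid(pump_axis: np.ndarray, oversample: int = 2) -> np.ndarray:
    """Pump-delay grid whose DFT bins land exactly on the pump-axis points.

    The frequency-bin spacing is the pump-axis spacing divided by
    ``oversample`` (the total span is then ``oversample`` periods of the
    finest pump spacing), and the grid is fine enough to satisfy Nyquist for
    the highest pump frequency.
    """
    pump_axis = np.asarray(pump_axis, dtype=float)
    spacing = float(np.min(np.diff(pump_axis)))
    if oversample < 2:
        raise ValueError("oversample must be >= 2 so the span covers 2x the "
                         "inverse of the finest pump spacing")
    dnu = spacing / oversample
    m_max = int(round(pump_axis[-1] / dnu))
    n = 2 * (m_max + 32)
    dt = 1.0 / (n * dnu * C_CM_PER_FS)
    return dt * np.arange(n)


def emit_time_domain(
    s: Spectrum2D,
    n_delays: int | None = None,
    delay_step: float | None = None,
    background: float = 1.0,
) -> RawPixelRecord:
    """Emit a pump-delay interferogram stack that Fourier-transforms back to ``s``.

    Each probe pixel carries a cosine series over the pump frequencies plus a
    constant common-mode background; four phase-cycling frames are written
    per delay with the (+, -, -, +) signing so their standard combination
    returns the pure signal.
    """
    if n_delays is None or delay_step is None:
        delays = default_delay_grid(s.pump_axis)
    else:
        delays = float(delay_step) * np.arange(int(n_delays))
        nyquist = 1.0 / (2.0 * float(delay_step) * C_CM_PER_FS)
        if s.pump_axis[-1] >= nyquist:
            raise ValueError(
                f"delay grid too coarse: {s.pump_axis[-1]:.1f} cm^-1 aliases "
                f"(Nyquist {nyquist:.1f} cm^-1)"
            )
        span = delays[-1] - delays[0] + (delays[1] - delays[0])
        min_span = 2.0 / (float(np.min(np.diff(s.pump_axis))) * C_CM_PER_FS)
        if span < min_span * (1 - 1e-9):
            raise ValueError(
                f"delay span {span:.0f} fs too short: need >= {min_span:.0f} fs "
                "(2x the inverse of the finest pump-axis spacing)"
            )
    phase = 2.0 * np.pi * C_CM_PER_FS * np.outer(delays, s.pump_axis)
    signal = np.cos(phase) @ s.amplitude          # (n_delays, n_probe)
    b = float(background)
    frames = np.stack([b + signal, b - signal, b - signal, b + signal], axis=1)
    return RawPixelRecord(delays, frames, s.probe_axis,
                          meta={**s.meta, "background": b})


def scale_mu(c: SpectralComponent, k: float) -> SpectralComponent:
    """Return a copy of ``c`` with the transition dipole scaled by ``k``."""
    return replace(c, mu=c.mu * k)
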