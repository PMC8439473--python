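"""Shared physical constants and spectroscopic conventions.

All frequencies are wavenumbers in cm^-1 and all times are femtoseconds.
The phase-cycling coefficients are the single source of truth shared by the
time-domain generator and the preprocessing stage.
"""

#: Speed of light in cm/fs (converts wavenumber to cycles per femtosecond).
C_CM_PER_FS = 2.99792458e-5

#: Nominal detector (probe-axis) pixel spacing, cm^-1.
PROBE_SPACING = 2.5

#: Two frequencies are treated as equal when within this tolerance, cm^-1.
FREQ_TOLERANCE = 2.5

#: Number of phase-cycling frames recorded per pump delay.
N_PHASE_FRAMES = 4

#: Linear combination applied to the four phase-cycling frames.  The pattern
#: (+, -, -, +)/4 cancels any common-mode background exactly and returns the
#: pump-probe signal with unit gain.
PHASE_CYCLE_COEFFS = (0.25, -0.25, -0.25, 0.25)

#: Diagonal-slice normalization frequency per sample class, cm^-1.
NORMALIZATION_FREQS = {
    "tissue_FFPE": 1641.0,
    "tissue_frozen": 1632.0,
    "tissue_dried": 1636.0,
    "protein_aB": 1639.0,
    "protein_R120G": 1632.0,
}

#: Default diagonal-ratio frequencies (numerator / denominator), cm^-1.
DIAG_RATIO_NUM = 1636.0
DIAG_RATIO_DEN = 1641.0

#: Default cross-peak readout coordinates, cm^-1.
XPEAK_PUMP = 1632.0
XPEAK_PROBE_MOUSE = 1701.0
XPEAK_PROBE_HUMAN = 1695.0

#: QC floor = this multiple of the robust noise estimate of a spectrum.
QC_FLOOR_MULTIPLIER = 5.0

#: Fixed display ranges for rendered feature maps (clamped, not rescaled).
DISPLAY_RANGES = {
    "diag_ratio": (0.8, 1.2),
    "xpeak_intensity": (0.0, 0.1),
    "peak_freq": (1600.0, 1660.0),
    "anharm": (0.0, 30.0),
}

#: Default amide-I band searched for diagonal peak maxima, cm^-1.
PEAK_BAND = (1600.0, 1660.0)
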