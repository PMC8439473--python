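# amide2d

Synthetic two-dimensional infrared (2D-IR) amide-I spectra and hyperspectral
tissue-image analysis for detecting and quantifying amyloid-like β-sheet
secondary structure.

The package covers the full desk-scale pipeline:

- **`amide2d.spectral_model`** — synthetic-data generator. Composes 2D
  amide-I spectra from secondary-structure component bands (native β-sheet,
  amyloid-like β-sheet, α-helix/random coil) with opposite-sign
  fundamental/overtone lobe pairs, |μ|⁴ amplitude scaling, and β-sheet cross
  peaks; simulates whole lens-slice cubes (elliptical masks, smoothly varying
  amyloid fraction, torn signal-void regions, additive noise); emits raw
  pump-delay interferograms with four-frame phase cycling.
- **`amide2d.preprocessing`** — phase-cycling combination, pump-delay Fourier
  transform onto the pump frequency axis, probe-axis calibration against
  known water lines, and the 2.5 cm⁻¹ frequency-equality convention.
- **`amide2d.features`** — diagonal slices, class normalization (FFPE tissue
  → 1641 cm⁻¹, frozen tissue → 1632, αB protein → 1639, R120G protein →
  1632), 1636/1641 diagonal ratio, peak frequency with parabolic sub-bin
  refinement, baseline-subtracted cross-peak intensity and location, and
  anharmonic shift.
- **`amide2d.imaging`** — spatial feature maps with fixed display scales
  (ratio 0.8–1.2, cross peak 0–0.1), torn-region QC rejection, and
  percent-of-locations frequency histograms.
- **`amide2d.quantify`** — per-lens summaries with 95% CIs, percent
  differences, two-tailed (Welch) t-tests at the 95/99/99.5% levels, and
  monotone piecewise-linear calibration curves mapping a spectral feature to
  percent amyloid-like structure.
- **`amide2d.io` / `amide2d.config` / `amide2d.pipeline` / `amide2d.cli`** —
  the cube container format, validated run configuration, the end-to-end
  pipeline with a hash manifest, and the command-line interface.

## CLI

```sh
# simulate a mutant-mouse FFPE lens slice
amide2d simulate --preset r120g_mouse --nx 16 --ny 16 --seed 1 --out lens.cube.npz

# per-pixel features and a ratio map
amide2d features --in lens.cube.npz --out lens.features.tsv
amide2d image --in lens.cube.npz --feature diag_ratio --out-prefix lens

# full demo pipeline (two groups, manifest with content hashes)
amide2d run --seed 1 --out-dir run_out
```

Presets: `wt_mouse`, `r120g_mouse`, `juvenile_human`, `cataract_human`,
`protein_aB`, `protein_R120G`; environments: `frozen`, `dried`, `ffpe`.

## Notes

- All randomness flows from explicit seeds; reruns of the pipeline with the
  same config reproduce every data file (the manifest hashes array content).
- Rendered PNG maps are presentation artifacts; TSV matrices are always the
  data of record.
- Generator ground truth (`truth/` namespace) is stored only for synthetic
  cubes and drives the parameter-recovery tests.
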