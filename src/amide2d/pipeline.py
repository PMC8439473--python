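"""End-to-end pipeline: simulate -> features -> maps -> statistics.

Every derived table is plain TSV/JSON; the manifest records a deterministic
content hash for each output so a rerun with the same config and seed can be
verified bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .config import RunConfig
from .core import default_axes
from .features import diagonal_ratio, diagonal_slice, normalize_slice
from .imaging import FEATURE_NAMES, build_feature_map, feature_table, frequency_histogram
from .io import content_hash, write_cube
from .quantify import (
    compare_groups,
    estimate_percent_amyloid,
    fit_calibration,
    percent_difference,
    summarize_lens,
)
from .spectral_model import ENVIRONMENTS, GENOTYPES, compose_spectrum, make_component_library, simulate_cube

log = logging.getLogger("amide2d")


def calibration_standards(
    percents,
    environment: str = "ffpe",
    subject: str = "mouse",
    feature: str = "diag_ratio",
):
    """Noiseless same-generator standards: (percent, feature value) pairs."""
    env = ENVIRONMENTS[environment]
    library = make_component_library(env, subject=subject)
    pump, probe = default_axes()
    out = []
    for pct in percents:
        w = pct / 100.0
        s = compose_spectrum({"native_beta": 1.0 - w, "amyloid_beta": w},
                             library, pump, probe)
        d = normalize_slice(diagonal_slice(s), env.sample_class)
        if feature != "diag_ratio":
            raise ValueError("only the diagonal ratio is calibrated by default")
        out.append((float(pct), diagonal_ratio(d)))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full demo pipeline and return the manifest dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)
    outputs: list[Path] = []
    lens_tables: dict[str, dict[str, object]] = {}
    summaries = []

    lens_seeds = {}
    spawn = rng_root.spawn(sum(g.lenses for g in config.groups.values()))
    k = 0
    for gname, gspec in config.groups.items():
        for i in range(gspec.lenses):
            lens_seeds[(gname, i)] = int(spawn[k].generate_state(1)[0] % (2**31))
            k += 1

    for gname, gspec in config.groups.items():
        if gspec.preset not in GENOTYPES:
            raise ValueError(f"group {gname!r}: unknown preset {gspec.preset!r}")
        lens_tables[gname] = {}
        for i in range(gspec.lenses):
            lens_id = f"{gname}_lens{i + 1}"
            try:
                cube = simulate_cube(
                    gspec.preset, nx=gspec.nx, ny=gspec.ny,
                    tear_params={"fraction": gspec.tear_fraction},
                    noise_sd=gspec.noise_sd,
                    seed=lens_seeds[(gname, i)],
                    environment=config.environment,
                )
            except Exception as e:
                raise RuntimeError(f"stage simulate failed for lens {lens_id}: {e}") from e
            outputs.append(write_cube(cube, out_dir / f"{lens_id}.cube.npz"))

            try:
                table = feature_table(cube, probe_freq=config.probe_freq,
                                      pump_freq=config.pump_freq)
            except Exception as e:
                raise RuntimeError(f"stage features failed for lens {lens_id}: {e}") from e
            for _, row in table[~table["qc_flag"]].iterrows():
                log.info("QC reject %s pixel (%d, %d)", lens_id,
                         row["pixel_x"], row["pixel_y"])
            tsv = out_dir / f"{lens_id}.features.tsv"
            table.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
            outputs.append(tsv)
            lens_tables[gname][lens_id] = table

            for feat in ("diag_ratio", "xpeak_intensity", "peak_freq"):
                try:
                    fmap = build_feature_map(cube, feat,
                                             probe_freq=config.probe_freq,
                                             pump_freq=config.pump_freq)
                except Exception as e:
                    raise RuntimeError(f"stage image failed for lens {lens_id}: {e}") from e
                mpath = out_dir / f"{lens_id}.{feat}.map.tsv"
                np.savetxt(mpath, fmap.values, delimiter="\t", fmt="%.6g",
                           header=f"{feat} map for {lens_id} (NaN = rejected)")
                outputs.append(mpath)
                if feat == "peak_freq":
                    hist = frequency_histogram(fmap)
                    hpath = out_dir / f"{lens_id}.peak_freq.hist.tsv"
                    np.savetxt(
                        hpath,
                        np.column_stack([hist.bin_edges[:-1], hist.bin_edges[1:],
                                         hist.percent_of_locations]),
                        delimiter="\t", fmt="%.6g",
                        header="bin_lo\tbin_hi\tpercent_of_locations")
                    outputs.append(hpath)

            summaries.append(summarize_lens([table], lens_id, gname))

    stats_doc = {"lenses": [], "comparisons": [], "percent_amyloid": {}}
    for s in summaries:
        stats_doc["lenses"].append({
            "lens_id": s.lens_id, "group": s.group, "n_pixels": s.n_pixels,
            "means": s.means, "ci95": s.ci95, "flags": s.flags,
        })

    group_names = list(config.groups)
    for ia in range(len(group_names)):
        for ib in range(ia + 1, len(group_names)):
            ga, gb = group_names[ia], group_names[ib]
            for feat in ("diag_ratio", "xpeak_intensity"):
                pooled_a = np.concatenate(
                    [t[t["qc_flag"]][feat].to_numpy() for t in lens_tables[ga].values()])
                pooled_b = np.concatenate(
                    [t[t["qc_flag"]][feat].to_numpy() for t in lens_tables[gb].values()])
                cmp_px = compare_groups(pooled_a, pooled_b, equal_var=config.equal_var,
                                        feature=feat, group_a=ga, group_b=gb)
                lens_means_a = [s.means[feat] for s in summaries if s.group == ga]
                lens_means_b = [s.means[feat] for s in summaries if s.group == gb]
                rec = asdict(cmp_px)
                rec["unit"] = "pixels"
                rec["percent_diff"] = percent_difference(cmp_px.mean_a, cmp_px.mean_b)
                stats_doc["comparisons"].append(rec)
                if len(lens_means_a) >= 2 and len(lens_means_b) >= 2:
                    cmp_lens = compare_groups(lens_means_a, lens_means_b,
                                              equal_var=config.equal_var,
                                              feature=feat, group_a=ga, group_b=gb)
                    rec = asdict(cmp_lens)
                    rec["unit"] = "lens_means"
                    rec["percent_diff"] = percent_difference(cmp_lens.mean_a,
                                                             cmp_lens.mean_b)
                    stats_doc["comparisons"].append(rec)

    if config.calibration_percents:
        standards = calibration_standards(config.calibration_percents,
                                          environment=config.environment,
                                          feature=config.calibration_feature)
        curve = fit_calibration(standards, config.calibration_feature)
        stats_doc["calibration_standards"] = standards
        for s in summaries:
            est = estimate_percent_amyloid(s, curve)
            stats_doc["percent_amyloid"][s.lens_id] = asdict(est)

    stats_path = out_dir / "stats.json"
    stats_path.write_text(json.dumps(stats_doc, indent=2, sort_keys=True))
    outputs.append(stats_path)

    manifest = {
        "seed": int(config.seed),
        "config": config.to_dict(),
        "files": {p.name: content_hash(p) for p in sorted(outputs)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
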