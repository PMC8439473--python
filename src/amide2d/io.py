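"""Data-of-record container format for cubes and raw stage data.

Cubes are stored as NumPy ``.npz`` archives with namespaced keys::

    axes/pump_axis, axes/probe_axis   frequency axes, cm^-1 (float64)
    pixels/amplitude                  [x, y, pump, probe] stack
    mask/mask                         lens mask
    truth/fraction, truth/tear        generator ground truth (synthetic only)
    raw/delays, raw/frames            optional time-domain data
    meta/json                         JSON metadata incl. format_version

Derived tables are always written as plain TSV elsewhere so that results
remain diffable; the archive is only the spectral data of record.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .core import TissueCube

FORMAT_VERSION = 1


class CubeFormatError(RuntimeError):
    """The file is not a readable cube container of a supported version."""


def write_cube(cube: TissueCube, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(cube.meta)
    meta["format_version"] = FORMAT_VERSION
    arrays = {
        "axes/pump_axis": cube.pump_axis,
        "axes/probe_axis": cube.probe_axis,
        "pixels/amplitude": cube.amplitude,
        "mask/mask": cube.mask,
        "meta/json": np.array(json.dumps(meta, sort_keys=True)),
    }
    if cube.truth_fraction is not None:
        arrays["truth/fraction"] = cube.truth_fraction
    if cube.truth_tear is not None:
        arrays["truth/tear"] = cube.truth_tear
    np.savez(path, **arrays)
    return path


def read_cube(path) -> TissueCube:
    """Read a cube container; bit-identical round trip with write_cube."""
    path = Path(path)
    if not path.exists():
        raise CubeFormatError(f"no such file: {path}")
    try:
        with np.load(path, allow_pickle=False) as z:
            keys = set(z.files)
            required = {"axes/pump_axis", "axes/probe_axis",
                        "pixels/amplitude", "mask/mask", "meta/json"}
            missing = required - keys
            if missing:
                raise CubeFormatError(
                    f"{path}: missing container groups {sorted(missing)}")
            meta = json.loads(str(z["meta/json"]))
            version = meta.pop("format_version", None)
            if version != FORMAT_VERSION:
                raise CubeFormatError(
                    f"{path}: unsupported format_version {version!r} "
                    f"(supported: {FORMAT_VERSION})")
            try:
                return TissueCube(
                    pump_axis=z["axes/pump_axis"],
                    probe_axis=z["axes/probe_axis"],
                    amplitude=z["pixels/amplitude"],
                    mask=z["mask/mask"],
                    truth_fraction=z["truth/fraction"] if "truth/fraction" in keys else None,
                    truth_tear=z["truth/tear"] if "truth/tear" in keys else None,
                    meta=meta,
                )
            except ValueError as e:
                raise CubeFormatError(f"{path}: inconsistent arrays: {e}") from e
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError) as e:
        raise CubeFormatError(f"{path}: not a readable cube container ({e})") from e


def write_raw(record, path) -> Path:
    """Store a raw time-domain record (delays, 4-frame stacks, probe axis)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(record.meta)
    meta["format_version"] = FORMAT_VERSION
    np.savez(
        path,
        **{
            "raw/delays": record.delays,
            "raw/frames": record.frames,
            "axes/probe_axis": record.probe_axis,
            "meta/json": np.array(json.dumps(meta, sort_keys=True, default=str)),
        },
    )
    return path


def read_raw(path):
    from .spectral_model import RawPixelRecord

    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta/json"]))
            version = meta.pop("format_version", None)
            if version != FORMAT_VERSION:
                raise CubeFormatError(f"{path}: unsupported format_version {version!r}")
            return RawPixelRecord(z["raw/delays"], z["raw/frames"],
                                  z["axes/probe_axis"], meta)
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError) as e:
        raise CubeFormatError(f"{path}: not a readable raw container ({e})") from e


def content_hash(path) -> str:
    """Deterministic content hash of a data file.

    For ``.npz`` archives the hash covers the sorted member names and array
    bytes (the zip wrapper embeds timestamps and is not reproducible); for
    everything else it is the sha256 of the file bytes.
    """
    import hashlib

    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for name in sorted(z.files):
                arr = np.ascontiguousarray(z[name])
                h.update(name.encode())
                h.update(str(arr.dtype).encode())
                h.update(str(arr.shape).encode())
                h.update(arr.tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()
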