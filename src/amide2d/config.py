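"""Run configuration: a validated key-value document for the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .constants import XPEAK_PROBE_MOUSE, XPEAK_PUMP

_GROUP_KEYS = {"preset", "lenses", "nx", "ny", "noise_sd", "tear_fraction"}


@dataclass
class GroupSpec:
    preset: str
    lenses: int = 2
    nx: int = 16
    ny: int = 16
    noise_sd: float = 0.01
    tear_fraction: float = 0.0


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run.

    Unknown keys are rejected so silent typos cannot change an analysis.
    """

    seed: int = 0
    out_dir: str = "amide2d_run"
    environment: str = "ffpe"
    groups: dict = field(default_factory=dict)        # name -> GroupSpec
    probe_freq: float = XPEAK_PROBE_MOUSE
    pump_freq: float = XPEAK_PUMP
    calibration_percents: list | None = None
    calibration_feature: str = "diag_ratio"
    equal_var: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        groups = {}
        for name, g in dict(data.pop("groups", {})).items():
            extra = set(g) - _GROUP_KEYS
            if extra:
                raise ValueError(f"unknown keys in group {name!r}: {sorted(extra)}")
            groups[str(name)] = GroupSpec(**g)
        cfg = cls(**data)
        cfg.groups = groups
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = {k: asdict(v) for k, v in self.groups.items()}
        return d


def demo_config(out_dir: str = "amide2d_run", seed: int = 0) -> RunConfig:
    """Small two-group mouse demo used by the smoke tests and CLI default."""
    return RunConfig.from_dict({
        "seed": seed,
        "out_dir": out_dir,
        "groups": {
            "wt": {"preset": "wt_mouse", "lenses": 2, "nx": 16, "ny": 16},
            "r120g": {"preset": "r120g_mouse", "lenses": 2, "nx": 16, "ny": 16},
        },
        "calibration_percents": [0, 1, 2, 3, 4, 5, 6],
    })
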