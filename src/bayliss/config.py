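"""Run configuration, unit handling and serialization.

Config files are YAML with angles in degrees and pressures in mmHg;
internally angles are radians where needed and pressures kPa
(1 mmHg = 0.133322 kPa).  Every run can emit a frozen copy of the
resolved configuration plus JSON metadata (package version, config
hash, wall clock) so that two runs with equal configs are
reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .params import MaterialParams, params_from_dict, params_to_dict
from .protocols import (
    MMHG_TO_KPA,
    PressureProtocol,
    ScenarioSpec,
    build_staircase,
    build_wave_protocol,
)
from .ring import RingConfiguration

mmhg_to_kpa = lambda p: p * MMHG_TO_KPA  # noqa: E731
kpa_to_mmhg = lambda p: p / MMHG_TO_KPA  # noqa: E731


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    params: MaterialParams = field(default_factory=MaterialParams)
    ring: RingConfiguration = field(default_factory=RingConfiguration)
    protocol_name: str = "staircase"  # 'staircase' | 'waves'
    protocol_options: dict = field(default_factory=dict)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.fully_active)
    seed: int = 0

    def build_protocol(self) -> PressureProtocol:
        if self.protocol_name == "staircase":
            opts = dict(self.protocol_options)
            if "levels" in opts:
                opts["levels"] = tuple(opts["levels"])
            return build_staircase(**opts)
        if self.protocol_name == "waves":
            opts = dict(self.protocol_options)
            for k in ("low", "high"):
                if k in opts:
                    opts[k] = tuple(opts[k])
            return build_wave_protocol(**opts)
        raise ConfigError(f"unknown protocol {self.protocol_name!r}", ["protocol_name"])

    def to_dict(self) -> dict:
        return {
            "params": params_to_dict(self.params),
            "ring": asdict(self.ring),
            "protocol": {"name": self.protocol_name, "options": dict(self.protocol_options)},
            "scenario": self.scenario.provenance(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        bad: list[str] = []
        known = {"params", "ring", "protocol", "scenario", "seed"}
        for key in set(d) - known:
            bad.append(key)
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}", sorted(bad))
        try:
            params = params_from_dict(d.get("params", {}))
        except TypeError as err:
            raise ConfigError(f"bad parameter block: {err}", ["params"]) from err
        try:
            ring = RingConfiguration(**d.get("ring", {}))
        except TypeError as err:
            raise ConfigError(f"bad ring block: {err}", ["ring"]) from err
        proto = d.get("protocol", {})
        scen_d = {k: v for k, v in d.get("scenario", {}).items() if v is not None}
        scen_d.setdefault("mode", "fully_active")
        if scen_d.get("ca_scale") is None:
            scen_d["ca_scale"] = 1.0
        try:
            scenario = ScenarioSpec(**scen_d)
        except TypeError as err:
            raise ConfigError(f"bad scenario block: {err}", ["scenario"]) from err
        return cls(
            params=params,
            ring=ring,
            protocol_name=proto.get("name", "staircase"),
            protocol_options=proto.get("options", {}),
            scenario=scenario,
            seed=int(d.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def write_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_metadata(cfg: RunConfig, path, extra: dict | None = None) -> dict:
    meta = {
        "package": "bayliss",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=float)
    return meta
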