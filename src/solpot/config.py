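"""Run-wide configuration with the default derivation constants.

Every tunable of the derivation pipeline lives here so a run can be resolved
to a single flat mapping, written next to its outputs and reloaded to
reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: kcal/mol at 298.15 K; energies scale linearly with this constant.
DEFAULT_KBT = 0.593

LAYER_ORDERS = ("smooth_then_threshold", "threshold_then_smooth")
MV_BIN_MODES = ("all_bins", "shared_support")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a derivation / significance / scoring run.

    Defaults are the derivation constants used throughout: 3-10 Å distance
    range in 0.2 Å bins plus an overflow bin, smoothing constant alpha = 4/3,
    occurrence thresholds of 10 (pair potentials) and 20 (group potentials),
    a solubility split at 64 % and a 100-shuffle randomization null.
    """

    d_min: float = 3.0
    d_max: float = 10.0
    bin_width: float = 0.2
    separate_overflow: bool = True
    alpha: float = 4.0 / 3.0
    min_occurrences: float = 10.0
    group_min_occurrences: float = 20.0
    kbt: float = DEFAULT_KBT
    split_threshold: float = 64.0
    n_shuffles: int = 100
    seed: int = 0
    layer_order: str = "smooth_then_threshold"
    mv_bin_mode: str = "all_bins"
    mv_separation_class: str = ">8"

    def __post_init__(self) -> None:
        if self.alpha <= 1.0:
            raise ValueError("smoothing constant alpha must be larger than one")
        if self.min_occurrences <= 0 or self.group_min_occurrences <= 0:
            raise ValueError("occurrence thresholds must be positive")
        if self.layer_order not in LAYER_ORDERS:
            raise ValueError(f"layer_order must be one of {LAYER_ORDERS}")
        if self.mv_bin_mode not in MV_BIN_MODES:
            raise ValueError(f"mv_bin_mode must be one of {MV_BIN_MODES}")
        if not (0.0 <= self.split_threshold <= 101.0):
            raise ValueError("split_threshold must be a percentage")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


DEFAULT_CONFIG = RunConfig()
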