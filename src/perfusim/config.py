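"""Run configuration: YAML round-trip, unit parsing, hashing.

Configs are flat YAML mappings.  Times are in days by default; the pump
update interval, prediction horizon, control horizon and store interval
also accept strings with an explicit unit suffix ("6 h", "0.5 d") because
pump cadences are conventionally quoted in hours.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .process_model import ConfigurationError, ProcessParameters

__all__ = ["RunConfig", "parse_time_days"]

_TIME_FIELDS = ("pui", "pred_horizon", "ctrl_horizon", "store_interval")
_CAMPAIGNS = ("simulate", "ensemble", "grid", "compare")


def parse_time_days(value) -> float:
    """A time given as a number (days) or a suffixed string ("6 h", "2 d")."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower()
    for suffix, factor in (("h", 1.0 / 24.0), ("d", 1.0)):
        if text.endswith(suffix):
            return float(text[: -len(suffix)].strip()) * factor
    raise ConfigurationError(
        f"cannot parse time {value!r}: use a number of days or an 'h'/'d' suffix"
    )


@dataclass(frozen=True)
class RunConfig:
    """Full campaign description: process parameters plus output options."""

    params: ProcessParameters = field(default_factory=ProcessParameters)
    campaign: str = "ensemble"
    outdir: str = "perfusim_out"
    burn_in: float = 1.0
    band_level: float = 0.95
    band_method: str = "normal"
    histogram_bins: str | int = "fd"
    compare_h_set: float | None = None  # strategy-B set point of `compare`

    def __post_init__(self) -> None:
        if self.campaign not in _CAMPAIGNS:
            raise ConfigurationError(
                f"unknown campaign {self.campaign!r}; choose from {_CAMPAIGNS}"
            )
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")
        if not 0 < self.band_level < 1:
            raise ConfigurationError("band_level must lie in (0, 1)")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self.params)
        data.update(
            campaign=self.campaign,
            outdir=self.outdir,
            burn_in=self.burn_in,
            band_level=self.band_level,
            band_method=self.band_method,
            histogram_bins=self.histogram_bins,
            compare_h_set=self.compare_h_set,
        )
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        own = {
            key: data.pop(key)
            for key in (
                "campaign", "outdir", "burn_in", "band_level",
                "band_method", "histogram_bins", "compare_h_set",
            )
            if key in data
        }
        for key in _TIME_FIELDS:
            if key in data and data[key] is not None:
                data[key] = parse_time_days(data[key])
        param_fields = {f.name for f in dataclasses.fields(ProcessParameters)}
        unknown = set(data) - param_fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(params=ProcessParameters(**data), **own)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
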