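"""Declarative campaign configuration (YAML) with strict validation.

A campaign config declares the surrogate model, the schedule cadence,
the pH ladder (optionally extended on the ionized side), the umbrella
window ladder with its force-constant rule, replicate count and seeds,
and the analysis parameters.  Unknown keys are rejected with the key
path so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .engine import Schedule
from .exchange import Window, build_window_ladder, extend_ph_ladder, piecewise_k_rule
from .model import ToyModel, model_from_dict

METHODS = ("cphmd", "phre", "us", "reus")


class ConfigError(ValueError):
    """Campaign configuration violation, reported with its key path."""


def _check_keys(block: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Binning, gating, bootstrap and WHAM parameters."""

    scan_lo: float = -12.0  # A, pKa scan range
    scan_hi: float = 22.0
    scan_bin_width: float = 1.0  # A
    scan_stride: float = 0.25  # A
    min_points: int = 50
    min_ph: int = 2
    min_replicas: int = 2
    mono_slack: float = 0.02
    n_boot: int = 1000
    pop_lo: float = -15.0  # A, ionized-population range
    pop_hi: float = 25.0
    pop_bin_width: float = 0.2  # A
    wham_bin_width: float = 0.05  # A
    wham_tol_kT: float = 1e-7
    wham_max_iter: int = 100_000

    @classmethod
    def from_dict(cls, block: Mapping, path: str = "analysis") -> "AnalysisConfig":
        _check_keys(block, set(cls.__dataclass_fields__), path)
        return cls(**block)


@dataclass(frozen=True)
class CampaignConfig:
    model: ToyModel
    method: str
    schedule: Schedule
    replicates: int
    seeds: tuple[int, ...]
    ph_ladder: tuple[float, ...]
    windows: Optional[tuple[Window, ...]] = None
    us_ext: bool = False
    diffusion: float = 0.05
    z_init: Optional[float] = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if len(self.seeds) != self.replicates:
            raise ConfigError(
                f"need exactly one seed per replicate: {self.replicates} replicates, "
                f"{len(self.seeds)} seeds"
            )
        if not self.ph_ladder:
            raise ConfigError("ph_ladder must contain at least one pH value")
        if self.method in ("us", "reus") and not self.windows:
            raise ConfigError(f"method '{self.method}' requires a 'windows' block")
        if self.method == "phre" and len(self.ph_ladder) < 2:
            raise ConfigError("method 'phre' requires a pH ladder with >= 2 values")
        if not (self.diffusion > 0):
            raise ConfigError("diffusion must be > 0")

    @property
    def effective_ph_ladder(self) -> tuple[float, ...]:
        """The pH ladder actually simulated (US-ext applied for 'us')."""
        if self.us_ext and self.method == "us":
            return tuple(extend_ph_ladder(self.ph_ladder, self.model.residue_class))
        return self.ph_ladder


_TOP_KEYS = {
    "model",
    "method",
    "schedule",
    "replicates",
    "seeds",
    "ph_ladder",
    "windows",
    "us_ext",
    "diffusion",
    "z_init",
    "analysis",
}


def _parse_windows(block: Mapping) -> tuple[Window, ...]:
    _check_keys(block, {"start", "stop", "spacing", "k_rule"}, "windows")
    for key in ("start", "stop", "spacing", "k_rule"):
        if key not in block:
            raise ConfigError(f"windows block missing required key {key!r}")
    segments = []
    for i, seg in enumerate(block["k_rule"]):
        _check_keys(seg, {"lo", "hi", "k"}, f"windows.k_rule[{i}]")
        segments.append((float(seg["lo"]), float(seg["hi"]), float(seg["k"])))
    try:
        ladder = build_window_ladder(
            float(block["start"]), float(block["stop"]), float(block["spacing"]),
            piecewise_k_rule(segments),
        )
    except ValueError as exc:
        raise ConfigError(f"windows: {exc}") from exc
    return tuple(ladder)


def config_from_dict(raw: Mapping) -> CampaignConfig:
    _check_keys(raw, _TOP_KEYS, "<top level>")
    for key in ("model", "method", "schedule", "replicates", "seeds", "ph_ladder"):
        if key not in raw:
            raise ConfigError(f"config missing required block {key!r}")
    try:
        model = model_from_dict(raw["model"])
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc
    sched_block = dict(raw["schedule"])
    _check_keys(sched_block, set(Schedule.__dataclass_fields__), "schedule")
    if sched_block.get("exchange_period", "unset") is None:
        sched_block["exchange_period"] = None
    try:
        schedule = Schedule(**sched_block)
    except ValueError as exc:
        raise ConfigError(f"schedule: {exc}") from exc
    windows = _parse_windows(raw["windows"]) if raw.get("windows") else None
    analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
    return CampaignConfig(
        model=model,
        method=str(raw["method"]),
        schedule=schedule,
        replicates=int(raw["replicates"]),
        seeds=tuple(int(s) for s in raw["seeds"]),
        ph_ladder=tuple(float(p) for p in raw["ph_ladder"]),
        windows=windows,
        us_ext=bool(raw.get("us_ext", False)),
        diffusion=float(raw.get("diffusion", 0.05)),
        z_init=None if raw.get("z_init") is None else float(raw["z_init"]),
        analysis=analysis,
    )


def load_config(path) -> CampaignConfig:
    """Load and fully validate a campaign config from a YAML file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(raw)


def config_hash(config: CampaignConfig) -> str:
    """Stable content hash of a campaign config, for the run manifest."""
    import hashlib

    canon = repr(config).encode()
    return hashlib.sha256(canon).hexdigest()[:16]
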