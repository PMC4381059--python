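"""Run configuration: defaults, validation, YAML/JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range thresholds."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Flat configuration for a full screen run (keys mirror CLI flags)."""

    # inputs
    genome: str | None = None
    targets: dict[str, str] = field(default_factory=dict)  # name -> protospacer
    sites: str | None = None  # BED of candidate sites for bait design
    peak_files: dict[str, str] = field(default_factory=dict)
    feature_files: dict[str, str] = field(default_factory=dict)
    treated_r1: str | None = None
    treated_r2: str | None = None
    treated_coords: str | None = None  # TSV of mapping coords, or SAM
    control_r1: str | None = None
    control_r2: str | None = None
    control_coords: str | None = None
    out_dir: str = "captor_out"
    # thresholds (screen defaults)
    pam: str = "NGG"
    max_mm: int = 4
    seed_len: int = 12
    seed_max_mm: int = 4
    min_len: int = 35
    qual_threshold: int = 20
    min_reads: int = 25
    homopolymer_len: int = 5
    background_pct: float = 5.0
    alpha: float = 0.01
    min_anchor: int = 20
    min_span: int = 100
    direction: str = "greater"
    correction: str | None = None
    n_random_controls: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_RANGES = {
    "max_mm": (0, 20),
    "seed_len": (5, 20),
    "seed_max_mm": (0, 12),
    "min_len": (1, 10_000),
    "qual_threshold": (0, 60),
    "min_reads": (0, 10**9),
    "homopolymer_len": (2, 1000),
    "background_pct": (0.0, 100.0),
    "min_anchor": (1, 10_000),
    "min_span": (1, 10_000),
    "n_random_controls": (0, 10**9),
}


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Fill defaults and validate ranges; collect all problems before raising."""
    if isinstance(raw, RunConfig):
        raw = raw.to_dict()
    known = set(RunConfig.__dataclass_fields__)
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = RunConfig(**cfg_kwargs)
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if not lo <= v <= hi:
            errors.append(f"{key}={v} outside [{lo}, {hi}]")
    if not 0.0 < cfg.alpha <= 1.0:
        errors.append(f"alpha={cfg.alpha} outside (0, 1]")
    if cfg.direction not in ("greater", "less"):
        errors.append(f"direction must be 'greater' or 'less', got {cfg.direction!r}")
    if cfg.correction not in (None, "bonferroni", "bh"):
        errors.append(f"unknown correction {cfg.correction!r}")
    for name, proto in cfg.targets.items():
        if len(proto) != 20 or set(proto.upper()) - set("ACGT"):
            errors.append(f"target {name!r}: protospacer must be 20 nt A/C/G/T")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return validate_config(raw or {})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
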