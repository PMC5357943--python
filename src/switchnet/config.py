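"""Run configuration for the end-to-end pipeline (YAML in, resolved JSON out)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cartography import RegionBounds

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration; serialized next to every run."""

    expression: str
    outdir: str
    sample_sheet: str | None = None
    clinical: str | None = None
    # filtering / differential selection
    min_value: float | None = None
    min_fraction: float = 0.8
    de_log2fc: float = 1.0
    de_pseudocount: float = 0.05
    # network
    cutoff: float = 0.8
    network_condition: str = "tumor"
    # clustering
    k: int | None = None
    k_min: int = 2
    k_max: int = 10
    restarts: int = 10
    elbow_tol: float = 0.05
    # cartography
    hub_min_degree: int = 5
    party_threshold: float = 0.5
    region_bounds: dict = field(
        default_factory=lambda: asdict(RegionBounds())
    )
    require_hub_for_switch: bool = False
    # robustness
    run_robustness: bool = True
    fractions: list = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20, 0.25])
    n_random_reps: int = 20
    # survival
    max_followup_days: float | None = None
    # reproducibility
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"expression", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"config missing required keys: {sorted(missing)}")
        return cls(**raw)

    def bounds(self) -> RegionBounds:
        return RegionBounds(**self.region_bounds)

    def validate_paths(self) -> None:
        for key in ("expression", "sample_sheet", "clinical"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key} file not found: {val}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path
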