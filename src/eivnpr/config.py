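"""Run configuration: flat YAML key-value files with strict key checking.

CLI flags override file values; unknown keys are rejected so typos fail
loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .array_data import DEFAULT_FLAG_MAP, Flag
from .exceptions import DataError
from .simulate import TwoComponentParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    keep_weak: bool = False
    fc_cutoff: float = 2.0
    sig_level: float = 0.05
    alpha_sig: float = 0.05
    basal_multiplier: float = 2.0
    variance_method: str = "simple"
    n_bag: int = 50
    grid_size: int = 256
    kernel_nodes: int = 512
    h0_grid: list | None = None
    alpha_grid: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    k_neighbors: int = 50
    normalize: str = "auto"
    normalizer_ids: list | None = None
    flag_map: dict = field(
        default_factory=lambda: {k: v.value for k, v in DEFAULT_FLAG_MAP.items()}
    )
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def flag_map_enum(self) -> dict:
        return {k: Flag(v) for k, v in self.flag_map.items()}

    def simulate_params(self, **overrides) -> TwoComponentParams:
        allowed = {f.name for f in fields(TwoComponentParams)}
        merged = {**self.simulate, **overrides}
        unknown = set(merged) - allowed
        if unknown:
            raise DataError(f"unknown simulate keys: {sorted(unknown)}")
        for key in ("mu_control", "de_effect", "normalizer_ids", "array_offsets"):
            if key in merged and isinstance(merged[key], list):
                merged[key] = tuple(merged[key])
        return TwoComponentParams(**merged)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config, apply overrides, reject unknown keys."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise DataError(f"{path}: config must be a mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
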