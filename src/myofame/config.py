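"""Run configuration: a small validated, YAML-round-trippable settings bundle."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .fitting import FitConfig
from .rates import DEFAULT_ACETATE_EXTRACTION, DEFAULT_LUMPED_CONSTANT


@dataclass
class RunConfig:
    """Everything a full study run needs, serialized alongside its outputs."""

    output_dir: str = "study_out"
    inputs_dir: str | None = None  # default: <output_dir>/inputs
    simulate: bool = True  # generate inputs if the directory is absent
    seed: int = 42
    n_per_group: int = 4
    noise_sigma: float = 0.05
    fit_window: tuple[float, float] = (0.0, 15.0)
    restarts: int = 5
    patlak_t_star: float = 7.5  # minutes
    fdg_blood_volume_fraction: float = 0.3  # assumed vascular fraction for Patlak
    lumped_constant: float = DEFAULT_LUMPED_CONSTANT
    acetate_extraction: float = DEFAULT_ACETATE_EXTRACTION
    alpha: float = 0.05
    tracers: tuple[str, ...] = ("palmitate", "acetate", "fdg")

    def __post_init__(self):
        self.fit_window = tuple(float(v) for v in self.fit_window)
        self.tracers = tuple(self.tracers)
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lumped_constant <= 0 or not 0 < self.acetate_extraction <= 1:
            raise ValueError("invalid tracer correction constants")
        unknown = set(self.tracers) - {"palmitate", "acetate", "fdg"}
        if unknown:
            raise ValueError(f"unknown tracers: {sorted(unknown)}")

    def fit_config(self, seed_offset: int = 0) -> FitConfig:
        return FitConfig(
            fit_window=self.fit_window,
            restarts=self.restarts,
            seed=self.seed + seed_offset,
        )

    def resolved_inputs_dir(self) -> Path:
        return Path(self.inputs_dir) if self.inputs_dir else Path(self.output_dir) / "inputs"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["fit_window"] = list(self.fit_window)
        data["tracers"] = list(self.tracers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
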