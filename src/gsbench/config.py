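"""Run configuration: a flat, fully serializable description of a benchmark
run, written back next to every output so a run can be reproduced exactly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .evaluation import VARIANTS, EvalSettings
from .gblup import GBLUPSettings
from .simulate import SimulationConfig, dataset_profile


@dataclass
class RunConfig:
    """Inputs and knobs of one benchmark run.

    Either ``markers_path``/``phenotypes_path`` point at existing files, or
    ``profile``/``simulation`` describe a synthetic dataset to generate.
    """

    output_dir: str = "results/run"
    markers_path: str | None = None
    phenotypes_path: str | None = None
    profile: str | None = None
    simulation: dict | None = None
    variants: list[str] = field(default_factory=lambda: [v.name for v in VARIANTS])
    method: str = "reml"
    gblup: dict = field(default_factory=dict)
    n_knots: int | None = None
    extrapolation_policy: str = "constant_offset"
    alpha: float = 0.01
    p_adjust: str | None = None
    nrmse_normalization: str = "mean"
    n_reps: int = 10
    test_fraction: float = 0.2
    cv_scheme: str = "monte_carlo"
    master_seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.markers_path is not None and self.phenotypes_path is not None
        has_sim = self.profile is not None or self.simulation is not None
        if not (has_files or has_sim):
            raise ConfigurationError(
                "config must supply marker/phenotype paths, a profile, or a simulation block"
            )

    def eval_settings(self) -> EvalSettings:
        return EvalSettings(
            method=self.method,
            gblup=GBLUPSettings(**self.gblup),
            n_knots=self.n_knots,
            extrapolation_policy=self.extrapolation_policy,
            alpha=self.alpha,
            p_adjust=self.p_adjust,
            nrmse_normalization=self.nrmse_normalization,
            seed=self.master_seed,
        )

    def simulation_config(self) -> SimulationConfig:
        if self.profile is not None:
            overrides = dict(self.simulation or {})
            return dataset_profile(self.profile, seed=self.master_seed, **overrides)
        if self.simulation is None:
            raise ConfigurationError("no simulation block in config")
        sim = dict(self.simulation)
        sim.setdefault("seed", self.master_seed)
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return SimulationConfig(**sim)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
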