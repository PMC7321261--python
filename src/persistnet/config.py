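"""Pipeline configuration: YAML-backed, validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as _PydanticError

from .cohort import CohortSpec
from .exceptions import ConfigError


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortConfig(_Block):
    n_regions: int = 68
    n_modules: int = 4
    group_sizes: dict[str, int] = Field(default_factory=lambda: {"AD": 40, "MCI": 77, "NC": 33})
    within_mean: float = 100.0
    between_mean: float = 20.0
    disconnection: dict[str, float] = Field(
        default_factory=lambda: {"AD": 0.6, "MCI": 0.3, "NC": 0.0}
    )
    between_attenuation: float = 0.5
    noise_model: str = "poisson"
    lognormal_sigma: float = 0.4
    seed: int = 0

    def to_spec(self) -> CohortSpec:
        return CohortSpec(**self.model_dump())


class ConnectivityConfig(_Block):
    method: str = "pearson_1minus"
    alpha: float = 0.05
    exclude_pair: bool = False
    shrinkage: float = 0.1
    on_degenerate: str = "raise"
    on_unsupported: str = "raise"


class PersistenceConfig(_Block):
    ipf_formula: str = "discrete"
    sampling: str = "breakpoints"
    n_grid: int = 101


class GraphMetricsConfig(_Block):
    seed: int = 0
    affinity: bool = False
    ec_summary: str = "mean"
    mod_solver: str = "auto"


class StatsConfig(_Block):
    n_permutations: int = 10_000
    seed: int = 0
    alpha_pairwise: float = 0.05
    alpha_omnibus: float = 0.01


class IOConfig(_Block):
    input_dir: str | None = None  # directory with manifest.csv + matrices; None = simulate
    write_matrices: bool = True
    write_curves: bool = True


class PipelineConfig(_Block):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    connectivity: ConnectivityConfig = Field(default_factory=ConnectivityConfig)
    persistence: PersistenceConfig = Field(default_factory=PersistenceConfig)
    graphmetrics: GraphMetricsConfig = Field(default_factory=GraphMetricsConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    io: IOConfig = Field(default_factory=IOConfig)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected
    with the offending key named."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except _PydanticError as exc:
        raise ConfigError(str(exc)) from exc
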