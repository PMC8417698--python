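"""YAML pipeline configuration with a strict, versioned schema."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .exceptions import ConfigurationError
from .synthetic import SyntheticConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    n_genes: int = 500
    network_model: str = "preferential_attachment"
    mean_degree: float = 4.0
    module_size: int = 20
    evidence_effect: float = 3.0
    noise_sd: float = 1.0
    n_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    n_enriched_sets: int = 5
    n_diseases: int = 6
    shared_signal_fraction: float = 0.5
    tractable_rate: float = 0.3

    def to_config(self, seed: int) -> SyntheticConfig:
        return SyntheticConfig(seed=seed, **self.model_dump())


class RWRSection(_Strict):
    restart: float = 0.75
    tol: float = 1e-10
    max_iter: int = 10_000
    layer_weights: dict[str, float] | None = None


class EnrichmentSection(_Strict):
    pathway_top_fraction: float = 0.02
    neighbor_top_fraction: float = 0.01
    tsea_n_perm: int = 200
    tsea_weight_exponent: float = 1.0


class CrosstalkSection(_Strict):
    theta_quantile: float = 0.95
    n_perm: int = 100
    degree_bin_width: int = 1
    exact_max_nodes: int = 15
    pathway_fdr: float = 0.05


class RobustnessSection(_Strict):
    convention: str = "exclude_removed"
    k_min: int = 1
    k_max: int = 3

    @field_validator("convention")
    @classmethod
    def _check_convention(cls, v: str) -> str:
        if v not in ("exclude_removed", "include_removed"):
            raise ValueError(f"unknown convention {v!r}")
        return v


class CrossmapSection(_Strict):
    radius: int = 3
    k_clusters: int = 4
    epochs: int = 60
    alpha0: float = 0.5


class PipelineConfig(_Strict):
    version: int = 1
    seed: int = 0
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)
    rwr: RWRSection = Field(default_factory=RWRSection)
    enrichment: EnrichmentSection = Field(default_factory=EnrichmentSection)
    crosstalk: CrosstalkSection = Field(default_factory=CrosstalkSection)
    robustness: RobustnessSection = Field(default_factory=RobustnessSection)
    crossmap: CrossmapSection = Field(default_factory=CrossmapSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8"
        )
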