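"""Pipeline configuration: nested dataclasses with strict YAML loading.

Unknown keys are rejected rather than ignored — a misspelled threshold
silently falling back to a default is the worst failure mode for a
parameterized pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import FilterParams, LfcFilterMode


@dataclass(frozen=True)
class NetworkConfig:
    r2_min: float = 0.8
    beta_grid: list[int] = field(default_factory=lambda: list(range(1, 21)))
    beta_override: int | None = 3
    n_bins: int = 20
    cutoff_grid: list[float] = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 20)])
    cutoff_override: float | None = 0.2
    cutoff_scale: str = "adjacency"  # "adjacency" thresholds a_ij; "similarity" thresholds s_ij

    def __post_init__(self) -> None:
        if self.cutoff_scale not in ("adjacency", "similarity"):
            raise ValueError("cutoff_scale must be 'adjacency' or 'similarity'")


@dataclass(frozen=True)
class HlcConfig:
    min_module_size: int = 3

    def __post_init__(self) -> None:
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass(frozen=True)
class LassoConfig:
    k_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    rule: str = "1se"  # CV penalty choice: "min" or "1se"

    def __post_init__(self) -> None:
        if self.rule not in ("min", "1se"):
            raise ValueError("lasso.rule must be 'min' or '1se'")


@dataclass(frozen=True)
class EnrichmentConfig:
    deg_threshold: float = 2.0


@dataclass(frozen=True)
class PreprocessConfig:
    pseudocount: float = 1.0
    phenotype_pseudocount: float = 0.0
    quantile_ratio_max: float = 1.5
    low_expr_value: float = 10.0
    low_expr_frac: float = 0.8
    lfc_iqr_threshold: float = 0.25
    lfc_filter_mode: str = "remove_low_variance"

    def filter_params(self) -> FilterParams:
        return FilterParams(
            quantile_ratio_max=self.quantile_ratio_max,
            low_expr_value=self.low_expr_value,
            low_expr_frac=self.low_expr_frac,
            lfc_iqr_threshold=self.lfc_iqr_threshold,
            lfc_filter_mode=LfcFilterMode(self.lfc_filter_mode),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    hlc: HlcConfig = field(default_factory=HlcConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)


_SECTIONS: dict[str, type] = {
    "preprocess": PreprocessConfig,
    "network": NetworkConfig,
    "hlc": HlcConfig,
    "lasso": LassoConfig,
    "enrichment": EnrichmentConfig,
}


def _build(cls: type, data: dict[str, Any], context: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section '{context}'")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ValueError(f"config section '{name}' must be a mapping")
            kwargs[name] = _build(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise ValueError(f"unknown top-level config key(s) {sorted(data)}")
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_dict(raw)


def config_to_dict(config: PipelineConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def default_config_yaml() -> str:
    """A template with every key and its default, ready to edit."""
    return yaml.safe_dump(config_to_dict(PipelineConfig()), sort_keys=False)
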