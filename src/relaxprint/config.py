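"""Validated run configuration (pydantic models; unknown keys rejected).

A run config fully determines a pipeline execution: acquisition protocol,
synthetic panel, region geometry, reference mode, ellipsoid level, the
calibration/validation split sizes and the top-level seed.  Schedule values
may be declared in us/ms/s and are converted to seconds on load.
"""

from __future__ import annotations

import json

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import forward_model as fm
from .errors import ConfigError

__all__ = [
    "ProtocolConfig",
    "ComponentConfig",
    "SpeciesConfig",
    "MixtureSeriesConfig",
    "PanelConfigModel",
    "SplitConfig",
    "RunConfig",
    "load_run_config",
]

_UNIT = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    tau1_schedule: list[float] = [100, 150, 200, 250, 300, 400, 500]
    tau1_unit: str = "us"
    n_schedule: list[int] = list(fm.DEFAULT_N_SCHEDULE)
    tau2: float = 100.0
    tau2_unit: str = "ms"
    noise_sigma: float = 1e-3

    @field_validator("tau1_unit", "tau2_unit")
    @classmethod
    def _unit_known(cls, v):
        if v not in _UNIT:
            raise ValueError(f"unknown time unit {v!r}; use one of {sorted(_UNIT)}")
        return v

    def to_protocol(self, seed: int = 0) -> fm.AcquisitionProtocol:
        return fm.AcquisitionProtocol(
            tau1_schedule=tuple(t * _UNIT[self.tau1_unit] for t in self.tau1_schedule),
            n_schedule=tuple(self.n_schedule),
            tau2=self.tau2 * _UNIT[self.tau2_unit],
            noise_sigma=self.noise_sigma,
            seed=seed,
        )


class ComponentConfig(_Strict):
    amplitude: float
    t1: float
    t2: float


class SpeciesConfig(_Strict):
    components: list[ComponentConfig]
    t_unit: str = "ms"

    @field_validator("t_unit")
    @classmethod
    def _unit_known(cls, v):
        if v not in _UNIT:
            raise ValueError(f"unknown time unit {v!r}")
        return v


class MixtureSeriesConfig(_Strict):
    base: str
    adulterant: str
    fractions: list[float]
    tag: str = "calibration"


class PanelConfigModel(_Strict):
    species_library: dict[str, SpeciesConfig] | None = None
    brands_per_species: dict[str, int] = dict(fm.DEFAULT_BRAND_COUNTS)
    brand_jitter_cv: float = Field(0.03, ge=0)
    mixture_series: list[MixtureSeriesConfig] = [
        MixtureSeriesConfig(
            base="FO", adulterant="SO", fractions=list(fm.CALIBRATION_RATIOS),
            tag="calibration",
        ),
        MixtureSeriesConfig(
            base="FO", adulterant="SO", fractions=list(fm.VALIDATION_RATIOS),
            tag="validation",
        ),
    ]

    def to_panel_config(self, seed: int = 0) -> fm.PanelConfig:
        if self.species_library is None:
            library = dict(fm.DEFAULT_SPECIES_LIBRARY)
        else:
            library = {}
            for name, sp in self.species_library.items():
                scale = _UNIT[sp.t_unit]
                comps = tuple(
                    fm.RelaxationComponent(c.amplitude, c.t1 * scale, c.t2 * scale)
                    for c in sp.components
                )
                library[name] = fm.OilSample(name, comps, "species")
        series = tuple(
            fm.MixtureSeries(s.base, s.adulterant, tuple(s.fractions), s.tag)
            for s in self.mixture_series
        )
        return fm.PanelConfig(
            species_library=library,
            brands_per_species=dict(self.brands_per_species),
            brand_jitter_cv=self.brand_jitter_cv,
            mixture_series=series,
            seed=seed,
        )


class SplitConfig(_Strict):
    """Which pure brands join the quantification calibration set."""

    base_species: str = "FO"
    adulterant_species: str = "SO"
    n_calibration_base: int = 4
    n_calibration_adulterant: int = 3
    n_validation_base: int = 1
    n_validation_adulterant: int = 1


class RunConfig(_Strict):
    """Top-level pipeline configuration; schema_version guards forward compat."""

    schema_version: int = 1
    seed: int = 0
    protocol: ProtocolConfig = ProtocolConfig()
    panel: PanelConfigModel = PanelConfigModel()
    regions: dict | None = None  # region JSON mapping; None = default tiling
    reference_mode: str = "mean"
    ellipsoid_level: float = Field(0.95, gt=0, lt=1)
    split: SplitConfig = SplitConfig()

    @field_validator("reference_mode")
    @classmethod
    def _mode_known(cls, v):
        if v not in ("mean", "smooth"):
            raise ValueError("reference_mode must be 'mean' or 'smooth'")
        return v


def load_run_config(source) -> RunConfig:
    """Load and validate a run config from a JSON file path, text, or dict.

    Unknown keys anywhere in the document are rejected before any stage runs.
    """
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, dict):
        data = source
    else:
        text = source
        try:
            data = json.loads(text)
        except (json.JSONDecodeError, TypeError):
            with open(source, "r", encoding="utf-8") as fh:
                data = json.load(fh)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid run config: {exc}") from exc
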