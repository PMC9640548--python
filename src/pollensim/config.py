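"""Declarative YAML run configuration.

Schema-validated (unknown keys rejected); every physical constant the model
uses is surfaced here, with the published values as defaults where they
exist (36 km grid spacing, 60 m first layer, 28/18 um grain diameters,
13/30 grains m^-3 clinical thresholds, 10/50/100 verification levels,
Mar 1-Apr 30 / Aug 1-Sep 30 season windows).
"""

from __future__ import annotations

from datetime import datetime, timezone
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .emission import MetAdjustParams, MetAdjustSet, TAXA, TaxonParams
from .grid import GridDomain
from .phenology import PhenologyParams
from .synthetic import SynthConfig
from .transport import BoundaryCondition, TransportConfig

_STRICT = ConfigDict(extra="forbid")


class GridSection(BaseModel):
    model_config = _STRICT
    nx: int = 20
    ny: int = 15
    nz: int = 4
    dx: float = 36_000.0
    dy: float = 36_000.0
    layer_tops: List[float] = [60.0, 150.0, 400.0, 1000.0]
    t0: datetime = datetime(2004, 3, 1, tzinfo=timezone.utc)
    n_hours: int = 720

    def build(self) -> GridDomain:
        return GridDomain(nx=self.nx, ny=self.ny, nz=self.nz, dx=self.dx,
                          dy=self.dy, layer_tops=tuple(self.layer_tops),
                          t0=self.t0, n_hours=self.n_hours)


class PhenologySection(BaseModel):
    model_config = _STRICT
    t_base: Optional[float] = None
    gdd_onset: Optional[float] = None
    season_spread: Optional[float] = None
    peak_offset: Optional[float] = None
    diurnal_peak_hour: Optional[float] = None
    diurnal_width: Optional[float] = None
    precip_suppression: Optional[float] = None

    def apply_to(self, base: PhenologyParams) -> PhenologyParams:
        overrides = {k: v for k, v in self.model_dump().items() if v is not None}
        if not overrides:
            return base
        from dataclasses import replace
        return replace(base, **overrides)


class TaxonSection(BaseModel):
    model_config = _STRICT
    name: str = "oak"
    q_p: Optional[float] = None
    c_r: Optional[float] = None
    d_p: Optional[float] = None
    rho_p: Optional[float] = None
    clinical_threshold: Optional[float] = None
    verification_levels: Optional[List[float]] = None
    season_window: Optional[List[List[int]]] = None  # [[m, d], [m, d]]

    @field_validator("name")
    @classmethod
    def _known_taxon(cls, v):
        if v not in TAXA and v != "custom":
            raise ValueError(f"taxon must be one of {sorted(TAXA)} or 'custom'")
        return v

    def build(self, phenology: Optional[PhenologySection] = None) -> TaxonParams:
        base = TAXA.get(self.name, TAXA["oak"])()
        overrides = {}
        for k in ("q_p", "c_r", "d_p", "rho_p", "clinical_threshold"):
            v = getattr(self, k)
            if v is not None:
                overrides[k] = v
        if self.verification_levels is not None:
            overrides["verification_levels"] = tuple(self.verification_levels)
        if self.season_window is not None:
            overrides["season_window"] = tuple(tuple(x) for x in self.season_window)
        if self.name == "custom":
            overrides.setdefault("name", "custom")
        from dataclasses import replace
        taxon = replace(base, **overrides) if overrides else base
        if phenology is not None:
            taxon = replace(taxon, phenology=phenology.apply_to(taxon.phenology))
        return taxon


class MetAdjustSection(BaseModel):
    model_config = _STRICT
    ke: dict = {}
    kr: dict = {}
    z0: Optional[float] = None

    def build(self) -> MetAdjustParams:
        default = MetAdjustParams()
        allowed = set(MetAdjustSet.__dataclass_fields__)
        for name, d in (("ke", self.ke), ("kr", self.kr)):
            unknown = set(d) - allowed
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
        from dataclasses import replace
        ke = replace(default.ke, **self.ke) if self.ke else default.ke
        kr = replace(default.kr, **self.kr) if self.kr else default.kr
        z0 = self.z0 if self.z0 is not None else default.z0
        return MetAdjustParams(ke=ke, kr=kr, z0=z0)


class TransportSection(BaseModel):
    model_config = _STRICT
    scavenging_a: float = 8.4e-5
    scavenging_b: float = 0.79
    settling_in: Literal["vdiff", "zadv"] = "vdiff"
    bc_mode: Literal["zero", "constant"] = "zero"
    bc_value: float = 0.0

    def build(self) -> TransportConfig:
        return TransportConfig(scavenging_a=self.scavenging_a,
                               scavenging_b=self.scavenging_b,
                               settling_in=self.settling_in)

    def boundary(self) -> BoundaryCondition:
        return BoundaryCondition(mode=self.bc_mode, value=self.bc_value)


class SynthSection(BaseModel):
    model_config = _STRICT
    mean_temp_c: float = 12.0
    diurnal_amplitude_c: float = 6.0
    seasonal_ramp_c: float = 8.0
    spatial_gradient_c: float = 4.0
    temp_noise_sd_c: float = 1.5
    temp_noise_rho: float = 0.9
    wind_mean: Tuple[float, float] = (3.0, 1.0)
    wind_sd: float = 1.5
    wind_rho: float = 0.85
    precip_event_rate: float = 0.05
    precip_mean_intensity: float = 2.0
    rh_base: float = 70.0
    rh_temp_slope: float = 1.5
    kh: float = 500.0
    kv: float = 10.0
    n_patches: int = 6
    coverage_max: float = 0.8
    lai_range: Tuple[float, float] = (1.0, 4.0)
    min_zero_fraction: float = 0.2
    n_stations: int = 12
    sampling_days_per_week: int = 3
    obs_noise_sd: float = 0.5
    delta_t_c: float = 2.0
    precip_scale: float = 1.1
    wind_scale: float = 1.0
    n_regions: int = 9

    def build(self) -> SynthConfig:
        d = self.model_dump()
        d.pop("n_regions")
        d["wind_mean"] = tuple(d["wind_mean"])
        d["lai_range"] = tuple(d["lai_range"])
        return SynthConfig(**d)


class RunConfig(BaseModel):
    """Top-level configuration: one YAML document per run."""

    model_config = _STRICT
    schema_version: int = 1
    seed: int = 0
    log_level: str = "INFO"
    grid: GridSection = GridSection()
    taxon: TaxonSection = TaxonSection()
    phenology: PhenologySection = PhenologySection()
    met_adjust: MetAdjustSection = MetAdjustSection()
    transport: TransportSection = TransportSection()
    synthetic: SynthSection = SynthSection()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    return cfg.model_dump(mode="json")
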