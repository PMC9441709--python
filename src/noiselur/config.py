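"""Run configuration: schema-validated YAML with strict unknown-key rejection.

One global seed fans out deterministically to per-stage child seeds (via
``numpy.random.SeedSequence.spawn`` order: city, sites, simulation, CV,
diagnostics) so any stage can be re-run in isolation and reproduce its part
of a full run.  The resolved configuration is serialized into every output
directory for provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

STAGE_ORDER = ("city", "sites", "simulate", "cv", "diagnostics")


class CitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    extent_m: tuple[float, float] = (4000.0, 4000.0)
    landcover_res_m: float = 20.0
    ndvi_res_m: float = 30.0
    n_eas: int = 40
    water_fraction: float = Field(0.03, ge=0.0, lt=0.5)

    @field_validator("extent_m")
    @classmethod
    def _positive_extent(cls, v):
        if min(v) <= 0:
            raise ValueError("extent must be positive")
        return v


class SitesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_rotating: int = 136
    n_fixed: int = 10
    rotating_days: int = 7
    fixed_days: int = 30


class SelectionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r2_gain_threshold: float = Field(0.01, gt=0.0, lt=1.0)
    collinearity_r: float = Field(0.8, gt=0.0, lt=1.0)
    sign_constraint: bool = True
    vif_report: bool = True


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    city: CitySection = CitySection()
    sites: SitesSection = SitesSection()
    buffers_m: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0)
    selection: SelectionSection = SelectionSection()
    cv_scheme: str = "loocv"
    grid_cell_m: float = Field(50.0, gt=0.0)
    ir_offset_dba: float = 3.0
    thresholds: dict[str, float] = {"l_den": 53.0, "l_night": 45.0}
    output_dir: str = "noiselur_run"

    @field_validator("cv_scheme")
    @classmethod
    def _scheme(cls, v):
        if v not in ("loocv", "cv10_sites"):
            raise ValueError("cv_scheme must be 'loocv' or 'cv10_sites'")
        return v

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed for a named pipeline stage."""
        idx = STAGE_ORDER.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGE_ORDER))[idx]
        return int(child.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write(self, outdir) -> None:
        from . import __version__

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        doc = self.model_dump()
        doc["package_version"] = __version__
        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
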