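"""Config-file schemas (YAML/JSON) and result serialization.

A lesion definition document has four sections: ``geometry`` (profile
family, reference radius, severity, length), ``plaque`` (minimum
attenuation, remodeling index, generative flags), ``cap`` (modulus, Poisson
ratio, thickness) and ``flow`` (hyperemic flow and pressure conditions).
Cohort and evaluation configs mirror :class:`cvikit.cohort.CohortConfig`
and :func:`cvikit.stats.evaluate_cohort`. Validation is via pydantic;
schema violations surface the offending key path.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cohort import CULPRIT_MARGINALS, NONCULPRIT_MARGINALS, ClassMarginals, CohortConfig
from .geometry import CapProperties, build_lesion
from .hemodynamics import FlowConditions

__all__ = [
    "LesionConfig",
    "CohortConfigDoc",
    "EvalConfigDoc",
    "load_lesion_config",
    "load_cohort_config",
    "load_eval_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    family: str = "cosine"
    a_ref_mm: float = Field(1.5, gt=0)
    severity: float = Field(0.5, ge=0, lt=1)
    length_mm: float = Field(16.0, gt=0)
    dz_mm: float = Field(0.1, gt=0)
    inlet_mm: float = Field(10.0, gt=0)
    outlet_mm: float = Field(10.0, gt=0)
    wall_thickness_mm: float = Field(1.0, gt=0)


class ApcSection(_Strict):
    sc: bool = False
    nrs: bool = False


class PlaqueSection(_Strict):
    hu_min: float = 60.0
    hu_background: float = 120.0
    remodeling_index: float = Field(1.0, gt=0)
    nu: float = Field(0.45, ge=0, lt=0.5)
    apc: ApcSection = ApcSection()


class CapSection(_Strict):
    Ec_kPa: float = Field(200.0, gt=0)
    nu: float = Field(0.25, ge=0, lt=0.5)
    h_um: float = Field(20.0, gt=0)


class FlowSection(_Strict):
    Q_ml_s: float = Field(2.693, ge=0)
    mu_Pa_s: float = Field(0.0035, gt=0)
    rho: float = Field(1060.0, gt=0)
    Pa_mmHg: float = Field(90.0, gt=0)
    Kt: float = Field(1.52, ge=0)


class LesionConfig(_Strict):
    geometry: GeometrySection = GeometrySection()
    plaque: PlaqueSection = PlaqueSection()
    cap: CapSection = CapSection()
    flow: FlowSection = FlowSection()
    unit_mode: str = "paper"
    outer_bc: str = "free"

    def build(self):
        g, p, c = self.geometry, self.plaque, self.cap
        geom, plaque = build_lesion(
            a_ref=g.a_ref_mm,
            severity=g.severity,
            length=g.length_mm,
            family=g.family,
            dz=g.dz_mm,
            inlet=g.inlet_mm,
            outlet=g.outlet_mm,
            wall_thickness=g.wall_thickness_mm,
            hu_min=p.hu_min,
            hu_background=p.hu_background,
            remodeling_index=p.remodeling_index,
            sc=p.apc.sc,
            nrs=p.apc.nrs,
            nu_p=p.nu,
        )
        cap = CapProperties(Ec=c.Ec_kPa, nu_c=c.nu, h=c.h_um)
        f = self.flow
        cond = FlowConditions(Q=f.Q_ml_s, mu=f.mu_Pa_s, rho=f.rho, Pa=f.Pa_mmHg, Kt=f.Kt)
        return geom, plaque, cap, cond


class MarginalsSection(_Strict):
    ds_mean: float
    ds_sd: float
    length_mean: float
    length_sd: float
    hu_mean: float
    hu_sd: float
    ri_mean: float
    ri_sd: float
    sc_prev: float = Field(ge=0, le=1)
    nrs_prev: float = Field(ge=0, le=1)


class CohortConfigDoc(_Strict):
    n_lesions: int = Field(ge=2)
    seed: int | None = None
    culprit_fraction: float = Field(63.0 / 209.0, ge=0, le=1)
    effect_size: float = 1.0
    label_mode: str = "logistic"
    nonculprit: MarginalsSection | None = None
    culprit: MarginalsSection | None = None
    dz_mm: float = Field(0.25, gt=0)
    unit_mode: str = "paper"
    event_time_dist: str = "uniform"

    def to_config(self, seed: int | None = None) -> CohortConfig:
        use_seed = seed if seed is not None else self.seed
        if use_seed is None:
            raise ValueError("a seed is required (config key 'seed' or --seed)")
        kwargs = dict(
            n_lesions=self.n_lesions,
            seed=use_seed,
            culprit_fraction=self.culprit_fraction,
            effect_size=self.effect_size,
            label_mode=self.label_mode,
            dz=self.dz_mm,
            unit_mode=self.unit_mode,
            event_time_dist=self.event_time_dist,
        )
        if self.nonculprit is not None:
            kwargs["nonculprit"] = ClassMarginals(**self.nonculprit.model_dump())
        if self.culprit is not None:
            kwargs["culprit"] = ClassMarginals(**self.culprit.model_dump())
        return CohortConfig(**kwargs)


class EvalConfigDoc(_Strict):
    features: list[str] | None = None
    value_fn_mode: str = "apparent"
    n_boot: int = Field(1000, ge=1)
    seed: int | None = None
    cutoff_feature: str = "cvi"


def _load_doc(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def load_lesion_config(path) -> LesionConfig:
    return LesionConfig.model_validate(_load_doc(path))


def load_cohort_config(path) -> CohortConfigDoc:
    return CohortConfigDoc.model_validate(_load_doc(path))


def load_eval_config(path) -> EvalConfigDoc:
    return EvalConfigDoc.model_validate(_load_doc(path))


def config_hash(path) -> str:
    """Short SHA-256 of the raw config bytes, for provenance headers."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
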