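"""Configuration models for cohort simulation and pipeline orchestration.

All configuration is expressed as pydantic models so that JSON configs are
validated up front and every invalid field is reported at once.  The defaults
encode the study conditions the downstream analysis assumes: a 15/7/10
control / low-fatigue / high-fatigue cohort, a pontine-to-cerebellar gray
matter gradient running from ~12 %GM to ~90 %GM, and a 1.25-fold elevation of
total creatine in a subset of white-matter-rich pons voxels of the patient
groups.
"""

from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .voxels import ALL_VOXELS, GROUPS

Metabolite = Literal["NAA", "tCr"]
GroupLabel = Literal["control", "low_fatigue", "high_fatigue"]

#: Per-voxel mean and SD of %GM (gray matter as a percentage of GM+WM).
#: Defaults reproduce the control gradient of the pontine CSI grid:
#: WM-rich rostral rows ~12-14 %GM, mid rows ~31-37, caudal rows ~60-67,
#: cerebellum ~90-94.
DEFAULT_TISSUE_PROFILE: dict[str, tuple[float, float]] = {
    "R6": (12.3, 5.7), "R5": (14.3, 6.6), "L5": (13.1, 6.8), "L6": (12.4, 4.9),
    "R4": (31.3, 7.8), "R3": (34.9, 7.0), "L3": (34.3, 9.1), "L4": (36.5, 10.3),
    "R2": (62.6, 8.9), "R1": (63.6, 9.1), "L1": (60.3, 8.7), "L2": (67.2, 11.2),
    "C1": (90.0, 8.3), "C2": (94.3, 4.0), "C3": (93.9, 5.2), "C4": (90.7, 7.8),
}

#: Pure-tissue metabolite amplitudes (arbitrary units).  Chosen so noiseless
#: NAA/tCr runs from 2.74 at 100% WM to 1.10 at 100% GM, bracketing the
#: observed voxel ratios (~2.5 in WM-rich pons rows, ~1.2 in cerebellum), and
#: so that tCr is higher in GM than WM (higher glial density).
DEFAULT_GM_CONC: dict[str, float] = {"NAA": 1.10, "tCr": 1.00}
DEFAULT_WM_CONC: dict[str, float] = {"NAA": 2.00, "tCr": 0.73}


class GroupEffect(BaseModel):
    """A multiplicative group-specific effect on one metabolite.

    ``mode="voxel"`` multiplies the voxel's noiseless amplitude wholesale in
    the matched voxels; ``mode="wm_pool"`` multiplies only the WM-compartment
    contribution (fWM * C_WM) in every matched voxel, emulating a pure-tissue
    concentration change.  ``voxel="*"`` matches all 16 voxels.
    """

    model_config = ConfigDict(frozen=True)

    group: GroupLabel
    voxel: str = "*"
    metabolite: Metabolite
    factor: float = Field(gt=0)
    mode: Literal["voxel", "wm_pool"] = "voxel"

    @field_validator("voxel")
    @classmethod
    def _known_voxel(cls, v: str) -> str:
        if v != "*" and v not in ALL_VOXELS:
            raise ValueError(f"unknown voxel label {v!r}")
        return v


#: Study-condition default: tCr elevated 1.25-fold in the voxels where the
#: group contrasts are expected (high fatigue: L4 and R6; low fatigue: L6).
DEFAULT_EFFECTS: tuple[GroupEffect, ...] = (
    GroupEffect(group="high_fatigue", voxel="L4", metabolite="tCr", factor=1.25),
    GroupEffect(group="high_fatigue", voxel="R6", metabolite="tCr", factor=1.25),
    GroupEffect(group="low_fatigue", voxel="L6", metabolite="tCr", factor=1.25),
)


class TruncatedNormal(BaseModel):
    """Mean/SD with hard truncation bounds, for clinical score simulation."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(ge=0)
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "TruncatedNormal":
        if self.low > self.high:
            raise ValueError("low must not exceed high")
        if not (self.low <= self.mean <= self.high):
            raise ValueError("mean must lie within [low, high]")
        return self


class ClinicalParams(BaseModel):
    """Per-group clinical covariate distributions.

    FSS defaults keep each group on its own side of the >36 fatigue cutoff;
    EDSS is drawn on the 0.5-step ordinal grid; lesion load is log-uniform
    within the group's observed range.  Controls carry no EDSS/lesion values.
    """

    model_config = ConfigDict(frozen=True)

    age: TruncatedNormal
    fss: TruncatedNormal
    edss_choices: tuple[float, ...] = ()
    lesion_range_cm3: Optional[tuple[float, float]] = None

    @field_validator("edss_choices")
    @classmethod
    def _edss_grid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        for x in v:
            if not (0 <= x <= 10) or round(x * 2) != x * 2:
                raise ValueError(f"EDSS value {x} not on the 0.5-step [0,10] grid")
        return v

    @field_validator("lesion_range_cm3")
    @classmethod
    def _lesion_range(cls, v):
        if v is not None and not (0 < v[0] <= v[1]):
            raise ValueError("lesion range must satisfy 0 < low <= high")
        return v


DEFAULT_CLINICAL: dict[str, ClinicalParams] = {
    "control": ClinicalParams(
        age=TruncatedNormal(mean=38, sd=7, low=26, high=49),
        fss=TruncatedNormal(mean=18, sd=4, low=13, high=26),
    ),
    "low_fatigue": ClinicalParams(
        age=TruncatedNormal(mean=38, sd=5, low=29, high=43),
        fss=TruncatedNormal(mean=22, sd=9, low=11, high=34),
        edss_choices=(1.0, 1.5),
        lesion_range_cm3=(0.15, 16.25),
    ),
    "high_fatigue": ClinicalParams(
        age=TruncatedNormal(mean=42, sd=8, low=29, high=56),
        fss=TruncatedNormal(mean=52, sd=6, low=42, high=59),
        edss_choices=(1.0, 1.5, 2.0, 2.5),
        lesion_range_cm3=(0.44, 37.17),
    ),
}


class CrlbModel(BaseModel):
    """Parameters mapping amplitude and noise to the reported relative CRLB.

    The reported bound is ``100 * noise_sd * k / amplitude`` percent.  With
    probability ``inflate_prob`` a voxel's CRLB is instead drawn uniformly
    from ``inflate_range`` (above the QC threshold), emulating the occasional
    unusable fit so the quality filter operates at a realistic rejection rate.
    """

    model_config = ConfigDict(frozen=True)

    k: float = Field(default=1.0, gt=0)
    inflate_prob: float = Field(default=0.035, ge=0, le=1)
    inflate_range: tuple[float, float] = (25.0, 50.0)
    cap_pct: float = Field(default=999.0, gt=0)

    @field_validator("inflate_range")
    @classmethod
    def _ordered(cls, v):
        if not (0 < v[0] <= v[1]):
            raise ValueError("inflate_range must satisfy 0 < low <= high")
        return v


class CohortConfig(BaseModel):
    """Full description of a synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n_control: int = Field(default=15, ge=1)
    n_low_fatigue: int = Field(default=7, ge=1)
    n_high_fatigue: int = Field(default=10, ge=1)
    tissue_profile: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PROFILE)
    )
    gm_conc: dict[Metabolite, float] = Field(default_factory=lambda: dict(DEFAULT_GM_CONC))
    wm_conc: dict[Metabolite, float] = Field(default_factory=lambda: dict(DEFAULT_WM_CONC))
    effect_map: tuple[GroupEffect, ...] = DEFAULT_EFFECTS
    csf_fraction_range: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"pons": (0.02, 0.15), "cerebellum": (0.05, 0.25)}
    )
    noise_sd: float = Field(default=0.08, ge=0)
    crlb_model: CrlbModel = CrlbModel()
    clinical_params: dict[GroupLabel, ClinicalParams] = Field(
        default_factory=lambda: dict(DEFAULT_CLINICAL)
    )
    seed: int = 0

    @field_validator("tissue_profile")
    @classmethod
    def _profile_complete(cls, v):
        bad = []
        missing = [vox for vox in ALL_VOXELS if vox not in v]
        if missing:
            bad.append(f"missing voxels: {', '.join(missing)}")
        unknown = [vox for vox in v if vox not in ALL_VOXELS]
        if unknown:
            bad.append(f"unknown voxels: {', '.join(unknown)}")
        for vox, (m, s) in v.items():
            if not (0 <= m <= 100):
                bad.append(f"{vox}: %GM mean {m} outside [0, 100]")
            if s < 0:
                bad.append(f"{vox}: %GM SD {s} < 0")
        if bad:
            raise ValueError("; ".join(bad))
        return v

    @field_validator("gm_conc", "wm_conc")
    @classmethod
    def _conc_positive(cls, v):
        bad = [f"{m}: {c} <= 0" for m, c in v.items() if c <= 0]
        if set(v) != {"NAA", "tCr"}:
            bad.append("concentrations must be given for exactly NAA and tCr")
        if bad:
            raise ValueError("; ".join(bad))
        return v

    @field_validator("csf_fraction_range")
    @classmethod
    def _csf_ranges(cls, v):
        bad = []
        for region in ("pons", "cerebellum"):
            if region not in v:
                bad.append(f"missing region {region!r}")
                continue
            lo, hi = v[region]
            if not (0 <= lo <= hi < 1):
                bad.append(f"{region}: CSF range ({lo}, {hi}) not within [0, 1)")
        if bad:
            raise ValueError("; ".join(bad))
        return v

    @model_validator(mode="after")
    def _groups_present(self) -> "CohortConfig":
        missing = [g for g in GROUPS if g not in self.clinical_params]
        if missing:
            raise ValueError(f"clinical_params missing groups: {', '.join(missing)}")
        return self

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "low_fatigue": self.n_low_fatigue,
            "high_fatigue": self.n_high_fatigue,
        }

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_low_fatigue + self.n_high_fatigue

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        return cls.model_validate(json.loads(text))


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration: stage toggles and shared parameters."""

    model_config = ConfigDict(frozen=True)

    cohort: CohortConfig = CohortConfig()
    run_simulate: bool = True
    run_metrics: bool = True
    run_ratios: bool = True
    run_projection: bool = True
    run_compare: bool = True
    cohort_csv: Optional[str] = None  # entry point when run_simulate is False
    crlb_max_pct: float = Field(default=20.0, gt=0)
    n_bootstrap: int = Field(default=2000, ge=0)
    fdr_level: float = Field(default=0.05, gt=0, lt=1)
    covariates: tuple[str, ...] = ("pct_gm",)
    seed: int = 0

    @field_validator("covariates")
    @classmethod
    def _known_covariates(cls, v):
        allowed = {"pct_gm", "age"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unsupported covariates: {sorted(bad)}; allowed: {sorted(allowed)}")
        return v


def config_schema() -> dict:
    """JSON schema for the cohort configuration (shipped for external tooling)."""
    return CohortConfig.model_json_schema()
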