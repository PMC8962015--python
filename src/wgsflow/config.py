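"""Scenario configuration: the complete parameter set defining one simulated world.

A scenario bundles the hospital landscape, test panels, molecular-marker
prevalences, WGS facility parameters, behavioral gates, referral policy, MTB
schedules, the arrival process and the run controls.  Defaults reproduce the
base case: 43 general / 21 teaching / 8 academic hospitals, one national
WGS facility, 7 molecular tumor boards, 5313 expected patients per year,
2000-day replications.

Scenarios load from YAML or JSON.  Unknown keys are rejected so that a typo in
a config file fails loudly instead of silently running the default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

MARKERS = ("EGFR", "KRAS", "ALK", "ROS1", "BRAF", "PDL1_high", "WGS_only")

#: 1 working day = 7/5 calendar days (turnarounds quoted in working days are
#: stored here already converted to calendar days).
WORKING_DAY = 7.0 / 5.0


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AssaySpec(_Model):
    """A single diagnostic assay: technology, covered markers, turnaround, cost."""

    name: str
    technology: Literal["IHC", "Sanger", "TGP", "WGS"]
    markers: list[str]
    turnaround_days: float = Field(gt=0, description="calendar days")
    cost: float = Field(ge=0, description="euro")

    @model_validator(mode="after")
    def _known_markers(self) -> "AssaySpec":
        unknown = set(self.markers) - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers {sorted(unknown)}; known: {MARKERS}")
        return self


def _default_general_panel() -> list[AssaySpec]:
    return [
        AssaySpec(name="ALK IHC", technology="IHC", markers=["ALK"],
                  turnaround_days=7.0, cost=70.0),
        AssaySpec(name="EGFR/KRAS Sanger", technology="Sanger",
                  markers=["EGFR", "KRAS"], turnaround_days=10.0, cost=150.0),
    ]


def _default_broad_panel() -> list[AssaySpec]:
    return [
        AssaySpec(name="PD-L1 IHC", technology="IHC", markers=["PDL1_high"],
                  turnaround_days=7.0, cost=70.0),
        AssaySpec(name="ALK IHC", technology="IHC", markers=["ALK"],
                  turnaround_days=7.0, cost=70.0),
        AssaySpec(name="TGP", technology="TGP",
                  markers=["EGFR", "ROS1", "BRAF", "KRAS"],
                  turnaround_days=12.0, cost=400.0),
    ]


class PanelsConfig(_Model):
    """Standard-of-care panels per hospital stratum.

    General hospitals run a narrow panel (ALK by IHC, EGFR/KRAS by Sanger);
    teaching and academic hospitals run PD-L1 and ALK by IHC plus a targeted
    gene panel covering EGFR, ROS1, BRAF and KRAS, all in parallel.
    """

    general: list[AssaySpec] = Field(default_factory=_default_general_panel)
    teaching: list[AssaySpec] = Field(default_factory=_default_broad_panel)
    academic: list[AssaySpec] = Field(default_factory=_default_broad_panel)

    @model_validator(mode="after")
    def _non_empty(self) -> "PanelsConfig":
        for stratum in ("general", "teaching", "academic"):
            if not getattr(self, stratum):
                raise ValueError(f"panel for stratum '{stratum}' is empty")
        return self


class HospitalsConfig(_Model):
    n_general: int = Field(default=43, ge=1)
    n_teaching: int = Field(default=21, ge=1)
    n_academic: int = Field(default=8, ge=1)
    #: Dirichlet concentration multiplier per stratum; larger values give that
    #: stratum systematically heavier catchments (academic centres see more
    #: patients than an average general hospital).
    catchment_concentration: dict[str, float] = Field(
        default_factory=lambda: {"general": 1.0, "teaching": 2.0, "academic": 3.0})
    #: Redraw hospital positions/catchments each replication (the hospital
    #: networks then vary across runs while the referral rules stay fixed).
    fixed_geography: bool = False
    #: Strata that have implemented WGS; base case is academic-only.
    wgs_strata: list[Literal["general", "teaching", "academic"]] = Field(
        default_factory=lambda: ["academic"])

    @model_validator(mode="after")
    def _check(self) -> "HospitalsConfig":
        missing = {"general", "teaching", "academic"} - set(self.catchment_concentration)
        if missing:
            raise ValueError(f"catchment_concentration missing strata {sorted(missing)}")
        if any(v <= 0 for v in self.catchment_concentration.values()):
            raise ValueError("catchment_concentration values must be > 0")
        return self


class WgsConfig(_Model):
    cost: float = Field(default=2925.0, ge=0, description="euro per sequenced patient")
    #: 10 working days = 14 calendar days.
    sequencing_days: float = Field(default=10.0 * WORKING_DAY, gt=0)
    #: Annual biopsy throughput of the facility; None = unlimited.
    annual_capacity: Optional[float] = Field(default=None, gt=0)
    #: Fresh-frozen biopsy acquisition + shipping to the facility.
    biopsy_logistics_days: float = Field(default=3.0, gt=0)
    #: Minimum tumor-cell percentage for successful sequencing.
    tumor_cell_threshold_pct: float = Field(default=20.0, ge=0, le=100)
    #: Beta distribution of the tumor-cell percentage (on [0, 100]); the
    #: defaults put 28.0% of biopsies below the 20% threshold.
    tumor_cell_beta_a: float = Field(default=1.2121, gt=0)
    tumor_cell_beta_b: float = Field(default=2.0, gt=0)


class BehaviorConfig(_Model):
    """Static behavioral gates on the WGS route."""

    adoption_prob: float = Field(default=0.90, ge=0, le=1,
                                 description="P(pathologist has adopted WGS)")
    wgs_preference_prob: float = Field(default=0.90, ge=0, le=1,
                                       description="P(patient prefers WGS over SoC)")


class ReferralConfig(_Model):
    #: Percentage of SoC-negative patients actually referred onward.
    percentage: float = Field(default=100.0, ge=0, le=100)
    delay_min_days: float = Field(default=4.0, ge=0)
    delay_max_days: float = Field(default=8.0, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ReferralConfig":
        if self.delay_max_days < self.delay_min_days:
            raise ValueError("delay_max_days < delay_min_days")
        return self


class MtbConfig(_Model):
    count: int = Field(default=7, ge=1)
    interval_days: float = Field(default=7.0, gt=0)
    #: A report must be on the agenda at least this long before a meeting.
    agenda_cutoff_days: float = Field(default=2.0, ge=0)
    #: Probability a case is deferred to the following meeting.
    deferral_prob: float = Field(default=0.5, ge=0, le=1)
    #: Cases per meeting; None = unlimited.
    per_meeting_capacity: Optional[int] = Field(default=None, ge=1)


class PopulationConfig(_Model):
    annual_patients: float = Field(default=5313.0, gt=0)
    #: Independent per-marker prevalences; co-occurrence allowed.
    prevalences: dict[str, float] = Field(default_factory=lambda: {
        "KRAS": 0.30, "EGFR": 0.12, "ALK": 0.04, "ROS1": 0.02,
        "BRAF": 0.03, "PDL1_high": 0.28, "WGS_only": 0.08})
    #: Mean of the exponential time-to-death from diagnosis (median ~150 d).
    mean_survival_days: float = Field(default=216.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "PopulationConfig":
        unknown = set(self.prevalences) - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers in prevalences: {sorted(unknown)}")
        bad = {k: v for k, v in self.prevalences.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"prevalences outside [0, 1]: {bad}")
        return self


class RunConfig(_Model):
    horizon_days: float = Field(default=2000.0, ge=0)
    warmup_days: float = Field(default=0.0, ge=0)
    replications: int = Field(default=500, ge=1)
    master_seed: int = Field(default=20220327, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.horizon_days > 0 and self.warmup_days >= self.horizon_days:
            raise ValueError("warmup_days must be < horizon_days")
        return self


class ScenarioConfig(_Model):
    """The complete parameter set for one simulated world."""

    hospitals: HospitalsConfig = Field(default_factory=HospitalsConfig)
    panels: PanelsConfig = Field(default_factory=PanelsConfig)
    wgs: WgsConfig = Field(default_factory=WgsConfig)
    behavior: BehaviorConfig = Field(default_factory=BehaviorConfig)
    referral: ReferralConfig = Field(default_factory=ReferralConfig)
    mtb: MtbConfig = Field(default_factory=MtbConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    run: RunConfig = Field(default_factory=RunConfig)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ScenarioConfig":
        if self.mtb.count > self.hospitals.n_academic:
            raise ValueError(
                f"mtb.count ({self.mtb.count}) exceeds n_academic "
                f"({self.hospitals.n_academic}); each MTB is hosted by an "
                "academic hospital")
        if self.wgs_enabled and "academic" not in self.hospitals.wgs_strata \
                and not self.hospitals.wgs_strata:
            raise ValueError("wgs_strata is empty: no last-resort WGS destination")
        return self

    @property
    def wgs_enabled(self) -> bool:
        return bool(self.hospitals.wgs_strata)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def default(cls) -> "ScenarioConfig":
        return cls()

    @classmethod
    def from_dict(cls, data: dict | None) -> "ScenarioConfig":
        return cls.model_validate(data or {})

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def with_override(self, path: str, value) -> "ScenarioConfig":
        """Return a copy with the dotted parameter ``path`` set to ``value``.

        >>> ScenarioConfig.default().with_override("wgs.cost", 3425).wgs.cost
        3425.0
        """
        data = self.model_dump()
        node = data
        *parents, leaf = path.split(".")
        for key in parents:
            if not isinstance(node, dict) or key not in node:
                raise KeyError(f"unknown parameter path: {path!r}")
            node = node[key]
        if not isinstance(node, dict) or leaf not in node:
            raise KeyError(f"unknown parameter path: {path!r}")
        node[leaf] = value
        return ScenarioConfig.model_validate(data)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario file (YAML or JSON; empty file = defaults)."""
    return ScenarioConfig.from_file(path)
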