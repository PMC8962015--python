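"""Patient generation: arrivals, molecular profiles, behavior, biopsies, death.

Newly diagnosed stage IV NSCLC patients arrive as a homogeneous Poisson
process at the national annual rate.  Each patient carries an independent
molecular profile (one Bernoulli draw per actionable marker), a WGS
preference flag, an exponential competing-risk death time, and draws biopsies
whose tumor-cell percentage follows a Beta law that determines suitability
for sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .config import MARKERS, ScenarioConfig


@dataclass(frozen=True)
class MolecularProfile:
    """Actionable markers present in the tumor; detection takes any covered
    positive.  ``WGS_only`` stands for targets no SoC assay covers."""

    markers: frozenset[str]

    def __contains__(self, marker: str) -> bool:
        return marker in self.markers

    @property
    def soc_negative_possible(self) -> bool:
        return len(self.markers) == 0


@dataclass(frozen=True)
class Biopsy:
    tumor_cell_pct: float
    suitable: bool


@dataclass
class Patient:
    """An individual agent traversing the diagnostic pathway."""

    id: int
    arrival: float
    home_index: int
    profile: MolecularProfile
    prefers_wgs: bool
    death_time: float
    cost: float = 0.0
    status: str = "in_progress"  # in_progress | concluded | died
    reason: Optional[str] = None  # recommendation | died | no_biomarker_exhausted
    conclusion_time: Optional[float] = None
    referral_count: int = 0
    wgs_requested: bool = False
    wgs_biopsy: Optional[Biopsy] = None
    wgs_received: bool = False
    wgs_queue_wait: Optional[float] = None
    hospitals_visited: list[str] = field(default_factory=list)
    log: list[tuple[float, str, str]] = field(default_factory=list)

    def record(self, time: float, label: str, where: str = "") -> None:
        self.log.append((time, label, where))


def generate_arrivals(annual_rate: float, horizon_days: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Arrival times of a homogeneous Poisson process on [0, horizon).

    The daily rate is ``annual_rate / 365``; with the default 5313/year and a
    2000-day horizon the expected count is ~29,112 patients.
    """
    if annual_rate <= 0:
        raise ValueError("annual_rate must be > 0")
    if horizon_days < 0:
        raise ValueError("horizon_days must be >= 0")
    if horizon_days == 0:
        return np.empty(0)
    n = rng.poisson(annual_rate / 365.0 * horizon_days)
    return np.sort(rng.uniform(0.0, horizon_days, size=n))


def sample_profiles(n: int, prevalences: dict[str, float],
                    rng: np.random.Generator) -> list[MolecularProfile]:
    """Independent Bernoulli draw per marker for each of ``n`` patients."""
    for marker, p in prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence of {marker} outside [0, 1]: {p}")
    names = [m for m in MARKERS if m in prevalences]
    probs = np.array([prevalences[m] for m in names])
    hits = rng.random((n, len(names))) < probs
    return [MolecularProfile(frozenset(m for m, h in zip(names, row) if h))
            for row in hits]


def sample_profile(prevalences: dict[str, float],
                   rng: np.random.Generator) -> MolecularProfile:
    return sample_profiles(1, prevalences, rng)[0]


def sample_biopsy(scenario: ScenarioConfig,
                  rng: np.random.Generator) -> Biopsy:
    """Draw one biopsy: tumor-cell percentage ~ Beta on [0, 100]; suitable iff
    the percentage reaches the threshold (default: at least 20%)."""
    cfg = scenario.wgs
    pct = 100.0 * rng.beta(cfg.tumor_cell_beta_a, cfg.tumor_cell_beta_b)
    return Biopsy(tumor_cell_pct=pct,
                  suitable=pct >= cfg.tumor_cell_threshold_pct)


def unsuitable_fraction(scenario: ScenarioConfig) -> float:
    """Closed-form P(biopsy unsuitable) under the configured Beta law."""
    cfg = scenario.wgs
    return float(stats.beta.cdf(cfg.tumor_cell_threshold_pct / 100.0,
                                cfg.tumor_cell_beta_a, cfg.tumor_cell_beta_b))


def sample_patients(arrivals: np.ndarray, home_indices: np.ndarray,
                    scenario: ScenarioConfig, rng_profiles: np.random.Generator,
                    rng_behavior: np.random.Generator,
                    rng_mortality: np.random.Generator) -> list[Patient]:
    """Build patient agents in arrival order.

    Profiles, preference flags and death times are drawn here, before any
    policy-dependent event fires, so they are identical across scenarios that
    share the same master seed (common random numbers).
    """
    n = len(arrivals)
    profiles = sample_profiles(n, scenario.population.prevalences, rng_profiles)
    prefers = rng_behavior.random(n) < scenario.behavior.wgs_preference_prob
    survival = rng_mortality.exponential(
        scenario.population.mean_survival_days, size=n)
    return [
        Patient(id=i, arrival=float(arrivals[i]), home_index=int(home_indices[i]),
                profile=profiles[i], prefers_wgs=bool(prefers[i]),
                death_time=float(arrivals[i] + survival[i]))
        for i in range(n)
    ]
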