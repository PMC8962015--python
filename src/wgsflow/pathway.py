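"""Diagnostic workflow primitives: SoC panels, the WGS facility queue, MTBs.

The pathway logic is: a patient's hospital runs its standard-of-care panel
(assays in parallel, so panel turnaround is the slowest assay).  A covered
positive marker concludes the pathway with a treatment recommendation.
SoC-negative patients cascade general -> teaching -> academic (each referral
realized with the scenario's referral percentage and adding a transfer
delay); at an academic hospital WGS is the last resort, gated by pathologist
adoption and patient preference.  A fresh biopsy ships to the single national
facility, occupies one sequencing slot for the full processing duration, and
— if the tumor-cell content was sufficient — yields a report that a molecular
tumor board discusses at its next eligible meeting, producing the treatment
recommendation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .config import AssaySpec, ScenarioConfig
from .engine import EventQueue
from .landscape import Hospital
from .population import MolecularProfile, Patient


@dataclass(frozen=True)
class TestPanel:
    """The parallel assay battery a hospital stratum runs in-house."""

    stratum: str
    assays: tuple[AssaySpec, ...]

    def __post_init__(self) -> None:
        if not self.assays:
            raise ValueError(f"empty panel for stratum {self.stratum!r}")

    @property
    def turnaround_days(self) -> float:
        # Assays run in parallel: the panel is done when the slowest assay is.
        return max(a.turnaround_days for a in self.assays)

    @property
    def cost(self) -> float:
        return sum(a.cost for a in self.assays)

    @property
    def covered_markers(self) -> frozenset[str]:
        return frozenset(m for a in self.assays for m in a.markers)


def build_panels(scenario: ScenarioConfig) -> dict[str, TestPanel]:
    return {s: TestPanel(s, tuple(getattr(scenario.panels, s)))
            for s in ("general", "teaching", "academic")}


@dataclass(frozen=True)
class PanelResult:
    found: bool
    duration_days: float
    cost: float


def run_soc_panel(panel: TestPanel, profile: MolecularProfile) -> PanelResult:
    """Run a panel against a molecular profile (detection sensitivity 1.0).

    ``found`` is true iff any assay covers a marker present in the tumor;
    duration is the max assay turnaround, cost the sum of assay costs.
    """
    found = bool(panel.covered_markers & profile.markers)
    return PanelResult(found=found, duration_days=panel.turnaround_days,
                       cost=panel.cost)


def decide_next_step(hospital: Hospital, panel_found: bool,
                     referral_percentage: float,
                     rng_behavior: np.random.Generator) -> str:
    """Route a patient after a completed panel: conclude, refer, or wgs.

    A found biomarker always concludes.  SoC-negative general/teaching
    patients are referred up the cascade with probability equal to the
    referral percentage, else conclude without a biomarker.  SoC-negative
    academic patients go to WGS if the hospital has implemented it (the
    behavioral gates are applied separately); otherwise they conclude — WGS
    is strictly the last-resort test and WGS recipients are never referred.
    """
    if panel_found:
        return "conclude"
    if hospital.stratum in ("general", "teaching"):
        if rng_behavior.random() < referral_percentage / 100.0:
            return "refer"
        return "conclude"
    return "wgs" if hospital.wgs_implemented else "conclude"


def gate_wgs(hospital: Hospital, patient: Patient,
             rng_behavior: np.random.Generator) -> bool:
    """Joint behavioral gate: pathologist adoption AND patient preference."""
    adopted = rng_behavior.random() < hospital.adoption_prob
    return adopted and patient.prefers_wgs


def wgs_slots(annual_capacity: Optional[float], sequencing_days: float) -> Optional[int]:
    """Concurrent sequencing slots implied by an annual biopsy capacity.

    ``slots = floor(capacity * duration / 365)``, at least 1; None when the
    capacity is unlimited.
    """
    if annual_capacity is None:
        return None
    return max(1, math.floor(annual_capacity * sequencing_days / 365.0))


class WGSFacility:
    """The single national sequencing facility: a FIFO multi-slot queue.

    Each arriving biopsy occupies exactly one slot for the full processing
    duration (sample QC, library preparation and sequencing); suitability of
    the tumor-cell content is established within that pipeline, so unsuitable
    samples consume throughput like any other.  With unlimited capacity every
    biopsy starts processing on arrival and queue waits are exactly zero.
    """

    def __init__(self, scenario: ScenarioConfig, queue: EventQueue):
        self.sequencing_days = scenario.wgs.sequencing_days
        self.slots = wgs_slots(scenario.wgs.annual_capacity, self.sequencing_days)
        self._queue = queue
        self._busy = 0
        self._waiting: deque[tuple[float, Callable[[float, float], None]]] = deque()
        self.arrivals = 0
        self.waits: list[float] = []

    @property
    def queue_length(self) -> int:
        return len(self._waiting)

    def submit(self, biopsy_arrival: float,
               on_complete: Callable[[float, float], None]) -> None:
        """Register a biopsy arriving now; ``on_complete(finish, wait)`` fires
        when its slot finishes, after any FIFO queueing for a free slot."""
        self.arrivals += 1
        if self.slots is None or self._busy < self.slots:
            self._start(biopsy_arrival, biopsy_arrival, on_complete)
        else:
            self._waiting.append((biopsy_arrival, on_complete))

    def _start(self, start: float, arrival: float,
               on_complete: Callable[[float, float], None]) -> None:
        self._busy += 1
        wait = start - arrival
        self.waits.append(wait)
        finish = start + self.sequencing_days

        def _finish() -> None:
            self._busy -= 1
            if self._waiting and (self.slots is None or self._busy < self.slots):
                queued_arrival, queued_cb = self._waiting.popleft()
                self._start(finish, queued_arrival, queued_cb)
            on_complete(finish, wait)

        self._queue.schedule(finish, _finish)


class MTB:
    """A molecular tumor board meeting at a fixed interval.

    A WGS report is discussed at the first meeting at least ``cutoff`` days
    after the report (the agenda closes before the meeting); with the
    deferral probability the case slips one further meeting (standing in for
    incomplete dossiers and crowded agendas), and a finite per-meeting
    capacity bumps overflow cases to the next meeting.  The treatment
    recommendation is issued at the discussion meeting.
    """

    def __init__(self, index: int, interval_days: float, cutoff_days: float,
                 deferral_prob: float, per_meeting_capacity: Optional[int],
                 phase: float):
        if not 0 <= phase < interval_days:
            raise ValueError("phase must lie in [0, interval)")
        self.index = index
        self.interval = interval_days
        self.cutoff = cutoff_days
        self.deferral_prob = deferral_prob
        self.capacity = per_meeting_capacity
        self.phase = phase
        self._load: dict[int, int] = {}

    def _meeting_index_at_or_after(self, time: float) -> int:
        k = math.ceil((time - self.phase) / self.interval - 1e-12)
        return max(k, 0)

    def meeting_time(self, k: int) -> float:
        return self.phase + k * self.interval

    def schedule_case(self, report_time: float,
                      rng_behavior: np.random.Generator) -> float:
        """Return the discussion (= recommendation) time for a report."""
        k = self._meeting_index_at_or_after(report_time + self.cutoff)
        if rng_behavior.random() < self.deferral_prob:
            k += 1
        if self.capacity is not None:
            while self._load.get(k, 0) >= self.capacity:
                k += 1
        self._load[k] = self._load.get(k, 0) + 1
        return self.meeting_time(k)

    def expected_wait(self) -> float:
        """Closed-form mean report-to-recommendation wait for reports arriving
        uniformly over the meeting cycle (unlimited meeting capacity):
        ``interval/2 + cutoff + deferral_prob * interval``."""
        return self.interval / 2.0 + self.cutoff + self.deferral_prob * self.interval


def build_mtbs(scenario: ScenarioConfig, hospitals: list[Hospital],
               rng_geography: np.random.Generator) -> list[MTB]:
    """One MTB per configured board, with a random meeting phase."""
    cfg = scenario.mtb
    phases = rng_geography.uniform(0.0, cfg.interval_days, size=cfg.count)
    return [MTB(index=k, interval_days=cfg.interval_days,
                cutoff_days=cfg.agenda_cutoff_days,
                deferral_prob=cfg.deferral_prob,
                per_meeting_capacity=cfg.per_meeting_capacity,
                phase=float(phases[k]))
            for k in range(cfg.count)]
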