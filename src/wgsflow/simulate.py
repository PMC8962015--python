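"""Single-replication execution: wiring agents, events and outcome records.

``run_replication`` builds a fresh world — hospital landscape, referral
network, WGS facility, molecular tumor boards, patient arrivals — and plays
the diagnostic pathway forward on the discrete-event kernel until the
horizon.  All state is local to the call: nothing leaks across replications,
and the result is a pure function of (scenario, master seed, replication
index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .config import ScenarioConfig
from .engine import (PRIORITY_DEATH, EventQueue, ReplicationSpec, RngRegistry)
from .landscape import (Hospital, assign_home_hospitals, build_referral_network,
                        generate_hospitals)
from .outcomes import OutcomeRecord
from .pathway import (MTB, WGSFacility, build_mtbs, build_panels,
                      decide_next_step, gate_wgs, run_soc_panel)
from .population import Patient, generate_arrivals, sample_biopsy, sample_patients


@dataclass
class RunResult:
    """Everything one replication produced."""

    replication: int
    horizon_days: float
    hospitals: list[Hospital]
    network: nx.DiGraph
    records: list[OutcomeRecord]
    n_generated: int
    n_concluded: int
    n_died: int
    n_in_progress: int
    n_biopsies_arrived: int
    n_biopsies_suitable: int
    queue_waits: list[float]
    terminal_queue_length: int
    #: (patient id, timestamp, event label, hospital id) rows, kept on request.
    pathway_log: Optional[list[tuple[int, float, str, str]]] = None

    def check_conservation(self) -> None:
        """Patients generated = recommendation/exhausted + died + in-progress."""
        if self.n_generated != self.n_concluded + self.n_died + self.n_in_progress:
            raise AssertionError(
                f"patient conservation violated: {self.n_generated} generated, "
                f"{self.n_concluded} concluded + {self.n_died} died + "
                f"{self.n_in_progress} in progress")


class _Replication:
    """Mutable state and event handlers of one replication."""

    def __init__(self, scenario: ScenarioConfig, spec: ReplicationSpec,
                 master_seed: Optional[int]):
        self.scenario = scenario
        self.spec = spec
        seed = scenario.run.master_seed if master_seed is None else master_seed
        self.rngs = RngRegistry(seed, spec.replication,
                                fixed_geography=scenario.hospitals.fixed_geography)
        self.queue = EventQueue()
        self.hospitals = generate_hospitals(scenario, self.rngs.geography)
        self.by_id = {h.id: h for h in self.hospitals}
        self.network = build_referral_network(self.hospitals)
        self.panels = build_panels(scenario)
        self.facility = WGSFacility(scenario, self.queue)
        self.mtbs = build_mtbs(scenario, self.hospitals, self.rngs.geography)
        self.n_biopsies_suitable = 0
        self.death_events: dict[int, object] = {}

    # -- patient generation --------------------------------------------------

    def generate_patients(self) -> list[Patient]:
        arrivals = generate_arrivals(self.scenario.population.annual_patients,
                                     self.spec.horizon_days, self.rngs.arrivals)
        homes = assign_home_hospitals(len(arrivals), self.hospitals,
                                      self.rngs.geography)
        return sample_patients(arrivals, homes, self.scenario,
                               self.rngs.profiles, self.rngs.behavior,
                               self.rngs.mortality)

    # -- event handlers ------------------------------------------------------

    def start(self, patients: list[Patient]) -> None:
        horizon = self.spec.horizon_days
        for p in patients:
            home = self.hospitals[p.home_index]
            self.queue.schedule(
                p.arrival, self._enter_cb(p, home, via_referral=False))
            if p.death_time <= horizon:
                self.death_events[p.id] = self.queue.schedule(
                    p.death_time, self._death_cb(p), priority=PRIORITY_DEATH)

    def _enter_cb(self, patient: Patient, hospital: Hospital, via_referral: bool):
        def _enter() -> None:
            self.enter_hospital(patient, hospital, via_referral)
        return _enter

    def _death_cb(self, patient: Patient):
        def _die() -> None:
            if patient.status == "in_progress":
                self.conclude(patient, self.queue.now, "died")
        return _die

    def enter_hospital(self, patient: Patient, hospital: Hospital,
                       via_referral: bool) -> None:
        if patient.status != "in_progress":
            return
        now = self.queue.now
        node = self.network.nodes[hospital.id]
        if via_referral:
            patient.referral_count += 1
            node["received_referrals"] += 1
            self.network.edges[patient.hospitals_visited[-1], hospital.id][
                "referrals"] += 1
        else:
            node["home_arrivals"] += 1
        patient.hospitals_visited.append(hospital.id)
        panel = self.panels[hospital.stratum]
        patient.cost += panel.cost  # assays committed when testing starts
        patient.record(now, "panel_started", hospital.id)
        result = run_soc_panel(panel, patient.profile)

        def _done() -> None:
            self.on_panel_done(patient, hospital, result.found)
        self.queue.schedule(now + result.duration_days, _done)

    def on_panel_done(self, patient: Patient, hospital: Hospital,
                      found: bool) -> None:
        if patient.status != "in_progress":
            return
        now = self.queue.now
        patient.record(now, "panel_done" + ("_found" if found else "_negative"),
                       hospital.id)
        step = decide_next_step(hospital, found,
                                self.scenario.referral.percentage,
                                self.rngs.behavior)
        if step == "conclude":
            self.conclude(patient, now,
                          "recommendation" if found else "no_biomarker_exhausted")
        elif step == "refer":
            target = self.by_id[hospital.referral_target]
            delay = self.rngs.delays.uniform(
                self.scenario.referral.delay_min_days,
                self.scenario.referral.delay_max_days)
            patient.record(now, "referred", target.id)
            self.queue.schedule(
                now + delay, self._enter_cb(patient, target, via_referral=True))
        else:  # wgs route
            self.start_wgs(patient, hospital)

    def start_wgs(self, patient: Patient, hospital: Hospital) -> None:
        now = self.queue.now
        if not gate_wgs(hospital, patient, self.rngs.behavior):
            patient.record(now, "wgs_gate_failed", hospital.id)
            self.conclude(patient, now, "no_biomarker_exhausted")
            return
        biopsy = sample_biopsy(self.scenario, self.rngs.biopsy)
        patient.wgs_requested = True
        patient.wgs_biopsy = biopsy
        if biopsy.suitable:
            self.n_biopsies_suitable += 1
            patient.cost += self.scenario.wgs.cost
        patient.record(now, "biopsy_shipped", hospital.id)
        ship = now + self.scenario.wgs.biopsy_logistics_days

        def _arrive() -> None:
            # The sample ships regardless of the patient's vital status: the
            # facility processes what it receives.
            self.facility.submit(
                self.queue.now,
                lambda finish, wait: self.on_sequencing_done(
                    patient, hospital, finish, wait))
        self.queue.schedule(ship, _arrive)

    def on_sequencing_done(self, patient: Patient, hospital: Hospital,
                           finish: float, wait: float) -> None:
        patient.wgs_queue_wait = wait
        if patient.status != "in_progress":
            return
        if not patient.wgs_biopsy.suitable:
            patient.record(finish, "wgs_unsuitable", hospital.id)
            self.conclude(patient, finish, "no_biomarker_exhausted")
            return
        patient.wgs_received = True
        patient.record(finish, "wgs_report", hospital.id)
        mtb = self.mtbs[hospital.mtb_index]
        recommendation_time = mtb.schedule_case(finish, self.rngs.behavior)

        def _recommend() -> None:
            if patient.status == "in_progress":
                patient.record(self.queue.now, "mtb_recommendation", hospital.id)
                self.conclude(patient, self.queue.now, "recommendation")
        self.queue.schedule(recommendation_time, _recommend)

    def conclude(self, patient: Patient, time: float, reason: str) -> None:
        if patient.status != "in_progress":
            raise RuntimeError(f"patient {patient.id} concluded twice")
        patient.status = "died" if reason == "died" else "concluded"
        patient.reason = reason
        patient.conclusion_time = time
        patient.record(time, f"concluded_{reason}")
        handle = self.death_events.pop(patient.id, None)
        if handle is not None:
            handle.cancel()


def _to_record(p: Patient) -> OutcomeRecord:
    duration = (p.conclusion_time - p.arrival
                if p.conclusion_time is not None else None)
    return OutcomeRecord(
        patient_id=p.id, arrival=p.arrival, conclusion_time=p.conclusion_time,
        duration_days=duration, total_cost=p.cost,
        wgs_requested=p.wgs_requested,
        wgs_biopsy_suitable=(p.wgs_biopsy.suitable if p.wgs_biopsy else None),
        wgs_received=p.wgs_received, wgs_queue_wait=p.wgs_queue_wait,
        referral_count=p.referral_count, reason=p.reason, status=p.status,
        hospitals_visited=tuple(p.hospitals_visited))


def run_replication(scenario: ScenarioConfig,
                    spec: ReplicationSpec | None = None,
                    replication: int = 0,
                    master_seed: Optional[int] = None,
                    keep_logs: bool = False) -> RunResult:
    """Execute one replication and return its records and tallies.

    ``spec`` defaults to the scenario's run block with the given replication
    index.  ``master_seed`` overrides the scenario's seed when given;
    ``keep_logs`` retains the per-patient pathway event log.
    """
    if spec is None:
        spec = ReplicationSpec(replication=replication,
                               horizon_days=scenario.run.horizon_days,
                               warmup_days=scenario.run.warmup_days)
    sim = _Replication(scenario, spec, master_seed)
    patients = sim.generate_patients()
    sim.start(patients)
    sim.queue.run_until(spec.horizon_days)

    window = [p for p in patients if p.arrival >= spec.warmup_days]
    records = [_to_record(p) for p in window]
    n_died = sum(p.status == "died" for p in window)
    n_concluded = sum(p.status == "concluded" for p in window)
    n_in_progress = sum(p.status == "in_progress" for p in window)
    result = RunResult(
        replication=spec.replication, horizon_days=spec.horizon_days,
        hospitals=sim.hospitals, network=sim.network, records=records,
        n_generated=len(window), n_concluded=n_concluded, n_died=n_died,
        n_in_progress=n_in_progress,
        n_biopsies_arrived=sim.facility.arrivals,
        n_biopsies_suitable=sim.n_biopsies_suitable,
        queue_waits=sim.facility.waits,
        terminal_queue_length=sim.facility.queue_length,
        pathway_log=([(p.id, t, label, where) for p in window
                      for t, label, where in p.log] if keep_logs else None))
    result.check_conservation()
    return result
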