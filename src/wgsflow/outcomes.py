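"""Per-patient endpoint records and per-replication / cross-replication summaries.

The primary outcome is the diagnostic pathway duration: days from diagnosis
(model entry) to treatment recommendation or death, whichever comes first.
Secondary outcomes are the total diagnostic cost per patient, the percentage
of patients who died before receiving a treatment recommendation, and WGS
facility queue statistics.  Cross-replication aggregation reports the
distribution of per-replication means — the data behind violin summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OutcomeRecord:
    """Endpoint data for one patient."""

    patient_id: int
    arrival: float
    conclusion_time: Optional[float]
    duration_days: Optional[float]
    total_cost: float
    wgs_requested: bool
    wgs_biopsy_suitable: Optional[bool]
    wgs_received: bool
    wgs_queue_wait: Optional[float]
    referral_count: int
    reason: Optional[str]  # recommendation | died | no_biomarker_exhausted
    status: str  # concluded | died | in_progress
    hospitals_visited: tuple[str, ...]

    @property
    def concluded(self) -> bool:
        return self.status != "in_progress"


def records_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """One row per patient; stable, documented column names."""
    rows = [{
        "patient_id": r.patient_id, "arrival": r.arrival,
        "conclusion_time": r.conclusion_time, "duration_days": r.duration_days,
        "total_cost": r.total_cost, "wgs_requested": r.wgs_requested,
        "wgs_biopsy_suitable": r.wgs_biopsy_suitable,
        "wgs_received": r.wgs_received, "wgs_queue_wait": r.wgs_queue_wait,
        "referral_count": r.referral_count, "reason": r.reason,
        "status": r.status, "hospitals_visited": ">".join(r.hospitals_visited),
    } for r in records]
    return pd.DataFrame(rows)


def died_before_recommendation_rate(records: Sequence[OutcomeRecord]) -> float:
    """Percentage of concluded pathways ending in death before a treatment
    recommendation; NaN when no pathway concluded."""
    concluded = [r for r in records if r.concluded]
    if not concluded:
        return float("nan")
    died = sum(r.reason == "died" for r in concluded)
    return 100.0 * died / len(concluded)


def _stats(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"mean": float("nan"), "median": float("nan"),
                "q1": float("nan"), "q3": float("nan")}
    return {"mean": float(np.mean(values)), "median": float(np.median(values)),
            "q1": float(np.percentile(values, 25)),
            "q3": float(np.percentile(values, 75))}


@dataclass(frozen=True)
class RunSummary:
    """Aggregates of one replication, over concluded (non-truncated) records."""

    replication: int
    n_generated: int
    n_concluded: int
    n_in_progress: int
    duration_mean: float
    duration_median: float
    duration_q1: float
    duration_q3: float
    wgs_duration_mean: float
    wgs_duration_median: float
    wgs_duration_q1: float
    wgs_duration_q3: float
    n_wgs_received: int
    mean_cost: float
    pct_died_before_recommendation: float
    wgs_queue_wait_mean: float
    wgs_queue_wait_max: float
    annual_wgs_biopsy_demand: float
    annual_suitable_biopsy_rate: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_run(result) -> RunSummary:
    """Reduce a :class:`~wgsflow.simulate.RunResult` to one summary row.

    Duration and cost statistics cover concluded records only; the WGS-subset
    duration covers patients whose sequencing completed.  Biopsy demand is
    annualized facility arrivals (arrivals x 365 / horizon).
    """
    records = result.records
    concluded = [r for r in records if r.concluded]
    durations = np.array([r.duration_days for r in concluded], dtype=float)
    wgs_durations = np.array(
        [r.duration_days for r in concluded if r.wgs_received], dtype=float)
    costs = np.array([r.total_cost for r in concluded], dtype=float)
    waits = np.asarray(result.queue_waits, dtype=float)
    horizon = result.horizon_days
    annualize = 365.0 / horizon if horizon > 0 else float("nan")

    d = _stats(durations)
    w = _stats(wgs_durations)
    return RunSummary(
        replication=result.replication,
        n_generated=result.n_generated,
        n_concluded=len(concluded),
        n_in_progress=result.n_generated - len(concluded),
        duration_mean=d["mean"], duration_median=d["median"],
        duration_q1=d["q1"], duration_q3=d["q3"],
        wgs_duration_mean=w["mean"], wgs_duration_median=w["median"],
        wgs_duration_q1=w["q1"], wgs_duration_q3=w["q3"],
        n_wgs_received=int(sum(r.wgs_received for r in concluded)),
        mean_cost=float(np.mean(costs)) if costs.size else float("nan"),
        pct_died_before_recommendation=died_before_recommendation_rate(records),
        wgs_queue_wait_mean=float(np.mean(waits)) if waits.size else 0.0,
        wgs_queue_wait_max=float(np.max(waits)) if waits.size else 0.0,
        annual_wgs_biopsy_demand=result.n_biopsies_arrived * annualize,
        annual_suitable_biopsy_rate=result.n_biopsies_suitable * annualize,
    )


def summaries_frame(summaries: Iterable[RunSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


#: Per-replication metrics aggregated across replications by default.
DEFAULT_AGG_METRICS = ("duration_mean", "wgs_duration_mean", "mean_cost",
                       "pct_died_before_recommendation",
                       "annual_wgs_biopsy_demand")

_PCTL = (2.5, 25.0, 50.0, 75.0, 97.5)


def aggregate_replications(summaries: Sequence[RunSummary],
                           metrics: Sequence[str] = DEFAULT_AGG_METRICS,
                           ) -> pd.DataFrame:
    """Distribution of per-replication means across replications.

    One row per metric: mean of the per-replication values, their SD, and the
    2.5/25/50/75/97.5 percentiles (the violin data).
    """
    if not summaries:
        raise ValueError("need at least one replication summary")
    rows = []
    for metric in metrics:
        values = np.array([getattr(s, metric) for s in summaries], dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            row = {"metric": metric, "mean": float("nan"), "sd": float("nan"),
                   **{f"p{p:g}": float("nan") for p in _PCTL}}
        else:
            row = {"metric": metric, "mean": float(values.mean()),
                   "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                   **{f"p{p:g}": float(np.percentile(values, p)) for p in _PCTL}}
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")
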