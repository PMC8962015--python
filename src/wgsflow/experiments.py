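"""Replication orchestration, preset sensitivity sweeps, result tables.

The preset sweeps mirror the model's sensitivity analyses: the WGS cost level
(500-euro increments around the 2925-euro price), the percentage of
SoC-negative patients referred onward, and the sequencing capacity crossed
with the MTB meeting frequency.  Sweeps share the master seed across
parameter values (common random numbers): arrivals and molecular profiles are
identical between values, so differences in outcomes reflect the policy, not
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import ScenarioConfig
from .engine import ReplicationSpec
from .outcomes import RunSummary, aggregate_replications, summarize_run
from .simulate import RunResult, run_replication


@dataclass(frozen=True)
class SweepSpec:
    """One swept parameter: dotted path and the values to visit."""

    parameter: str
    values: tuple
    replications: int = 20

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("sweep needs at least one value")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        # Fail early on typos: the path must resolve in the schema.
        ScenarioConfig.default().with_override(self.parameter, self.values[0])


#: The current WGS price and hypothetical levels in 500-euro increments.
COST_LEVELS = (925.0, 1425.0, 1925.0, 2425.0, 2925.0, 3425.0, 3925.0)
REFERRAL_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)
#: Annual sequencing capacities; None = unlimited.
CAPACITY_LEVELS = (1300.0, 1450.0, 1600.0, None)
MTB_INTERVALS = (7.0, 14.0)

_PRESETS = {
    "cost_sweep": ("wgs.cost", COST_LEVELS),
    "referral_sweep": ("referral.percentage", REFERRAL_LEVELS),
    "capacity_sweep": ("wgs.annual_capacity", CAPACITY_LEVELS),
    "mtb_frequency": ("mtb.interval_days", MTB_INTERVALS),
}


def preset(name: str, replications: int = 20) -> SweepSpec:
    """A named sensitivity sweep: cost_sweep, referral_sweep, capacity_sweep
    or mtb_frequency."""
    try:
        parameter, values = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None
    return SweepSpec(parameter=parameter, values=values,
                     replications=replications)


def run_replications(scenario: ScenarioConfig, n_replications: int,
                     master_seed: Optional[int] = None,
                     horizon_days: Optional[float] = None,
                     keep_logs_first: bool = False,
                     ) -> list[RunResult]:
    """Run replications 0..n-1 of one scenario.

    ``keep_logs_first`` retains the pathway event log of replication 0 only
    (the per-patient log of a 2000-day run is sizeable).
    """
    results = []
    for rep in range(n_replications):
        spec = ReplicationSpec(
            replication=rep,
            horizon_days=(scenario.run.horizon_days if horizon_days is None
                          else horizon_days),
            warmup_days=scenario.run.warmup_days)
        results.append(run_replication(scenario, spec=spec,
                                       master_seed=master_seed,
                                       keep_logs=keep_logs_first and rep == 0))
    return results


def summarize_replications(results: Sequence[RunResult]) -> list[RunSummary]:
    return [summarize_run(r) for r in results]


def run_sweep(scenario: ScenarioConfig, sweep: SweepSpec,
              master_seed: Optional[int] = None,
              horizon_days: Optional[float] = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute a sweep; returns (per-replication table, per-value aggregates).

    Every swept value runs replication indices 0..n-1 under the same master
    seed, so arrival times and molecular profiles coincide across values.
    """
    rep_rows: list[dict] = []
    agg_rows: list[dict] = []
    for value in sweep.values:
        sub = scenario.with_override(sweep.parameter, value)
        results = run_replications(sub, sweep.replications,
                                   master_seed=master_seed,
                                   horizon_days=horizon_days)
        summaries = summarize_replications(results)
        for s in summaries:
            row = {"parameter": sweep.parameter, "value": value}
            row.update(s.to_dict())
            rep_rows.append(row)
        agg = aggregate_replications(summaries)
        for metric, row in agg.iterrows():
            agg_rows.append({"parameter": sweep.parameter, "value": value,
                             "metric": metric, **row.to_dict()})
    return pd.DataFrame(rep_rows), pd.DataFrame(agg_rows)
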