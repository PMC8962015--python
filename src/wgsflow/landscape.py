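"""Synthetic national hospital landscape and nearest-by-type referral network.

Hospitals are placed uniformly at random in the unit square (the space does
not represent real geography) and stratified as general, teaching or academic.
Catchment weights — the probability with which a newly diagnosed patient
enters each hospital — are Dirichlet-distributed with stratum-specific
concentration so academic centres carry systematically larger volumes.

Referral structure is a fixed rule: every general hospital refers to its
nearest teaching hospital and every teaching hospital to its nearest academic
hospital, giving a forest of referral trees rooted at academic centres.  The
trees vary with the random geography of each replication; the rule does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import ScenarioConfig

STRATA = ("general", "teaching", "academic")
_PREFIX = {"general": "GH", "teaching": "TH", "academic": "AH"}
_NEXT_STRATUM = {"general": "teaching", "teaching": "academic"}

#: Width of the patient-volume bins used when exporting networks.
VOLUME_BIN_WIDTH = 1500


@dataclass
class Hospital:
    """A provider agent: stratum, position, catchment mass and referral target."""

    id: str
    index: int
    stratum: str
    x: float
    y: float
    catchment: float
    wgs_implemented: bool
    adoption_prob: float
    referral_target: Optional[str] = None
    mtb_index: Optional[int] = None

    def distance_to(self, other: "Hospital") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def generate_hospitals(scenario: ScenarioConfig,
                       rng: np.random.Generator) -> list[Hospital]:
    """Place and parameterize the hospital agents for one replication.

    Positions are uniform on the unit square; catchment weights are a single
    Dirichlet draw whose concentration is the stratum multiplier from the
    scenario, normalized to sum to one over all hospitals.
    """
    cfg = scenario.hospitals
    counts = {"general": cfg.n_general, "teaching": cfg.n_teaching,
              "academic": cfg.n_academic}
    if scenario.wgs_enabled and not any(
            counts[s] > 0 for s in cfg.wgs_strata):
        raise ValueError("no hospitals in any WGS-implementing stratum")

    hospitals: list[Hospital] = []
    strata_seq = [s for s in STRATA for _ in range(counts[s])]
    n = len(strata_seq)
    positions = rng.random((n, 2))
    alpha = np.array([cfg.catchment_concentration[s] for s in strata_seq])
    weights = rng.dirichlet(alpha)

    per_stratum_counter = {s: 0 for s in STRATA}
    for i, stratum in enumerate(strata_seq):
        k = per_stratum_counter[stratum]
        per_stratum_counter[stratum] += 1
        hospitals.append(Hospital(
            id=f"{_PREFIX[stratum]}[{k}]",
            index=i,
            stratum=stratum,
            x=float(positions[i, 0]),
            y=float(positions[i, 1]),
            catchment=float(weights[i]),
            wgs_implemented=stratum in cfg.wgs_strata,
            adoption_prob=scenario.behavior.adoption_prob,
        ))

    _assign_mtbs(hospitals, scenario.mtb.count)
    return hospitals


def _assign_mtbs(hospitals: list[Hospital], n_mtb: int) -> None:
    """Host MTB k at academic hospital k; surplus academics use the MTB of
    their nearest hosting academic neighbour (lowest index on ties)."""
    academics = [h for h in hospitals if h.stratum == "academic"]
    hosts = academics[:n_mtb]
    for k, h in enumerate(hosts):
        h.mtb_index = k
    for h in academics[n_mtb:]:
        nearest = min(hosts, key=lambda g: (h.distance_to(g), g.index))
        h.mtb_index = nearest.mtb_index


def build_referral_network(hospitals: Sequence[Hospital]) -> nx.DiGraph:
    """Wire each hospital to the Euclidean-nearest hospital of the next stratum.

    Returns a directed graph whose nodes carry hospital attributes and whose
    edges carry a zeroed referral tally; also sets ``referral_target`` on the
    hospital objects.  Ties in distance go to the lowest hospital index.
    """
    by_stratum = {s: [h for h in hospitals if h.stratum == s] for s in STRATA}
    graph = nx.DiGraph()
    for h in hospitals:
        graph.add_node(h.id, stratum=h.stratum, x=h.x, y=h.y,
                       catchment=h.catchment, home_arrivals=0,
                       received_referrals=0)
    for stratum, target_stratum in _NEXT_STRATUM.items():
        candidates = by_stratum[target_stratum]
        if not candidates:
            raise ValueError(
                f"no {target_stratum} hospitals: {stratum} hospitals have no "
                "referral destination")
        for h in by_stratum[stratum]:
            target = min(candidates, key=lambda g: (h.distance_to(g), g.index))
            h.referral_target = target.id
            graph.add_edge(h.id, target.id, referrals=0)
    return graph


def assign_home_hospitals(n: int, hospitals: Sequence[Hospital],
                          rng: np.random.Generator) -> np.ndarray:
    """Draw home hospitals for ``n`` patients, categorical on catchment weight.

    Geographic "nearest hospital" entry is represented by catchment mass:
    patients carry no coordinates, so entering the nearest hospital is
    distributionally equivalent to a weighted draw.
    Returns indices into ``hospitals``.
    """
    weights = np.array([h.catchment for h in hospitals], dtype=float)
    weights = weights / weights.sum()
    return rng.choice(len(hospitals), size=n, p=weights)


def volume_bin(volume: int) -> str:
    """Label the 1500-wide patient-volume bin a hospital falls in.

    >>> volume_bin(1400)
    '<=1500'
    >>> volume_bin(1501)
    '1501-3000'
    """
    if volume <= VOLUME_BIN_WIDTH:
        return f"<={VOLUME_BIN_WIDTH}"
    upper = VOLUME_BIN_WIDTH * math.ceil(volume / VOLUME_BIN_WIDTH)
    return f"{upper - VOLUME_BIN_WIDTH + 1}-{upper}"


def tally_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-hospital volume table: home arrivals, received referrals, total."""
    rows = []
    for node, data in graph.nodes(data=True):
        total = data["home_arrivals"] + data["received_referrals"]
        rows.append({"hospital": node, "stratum": data["stratum"],
                     "home_arrivals": data["home_arrivals"],
                     "received_referrals": data["received_referrals"],
                     "total_volume": total, "volume_bin": volume_bin(total)})
    return pd.DataFrame(rows).sort_values("hospital", ignore_index=True)


def export_network(graph: nx.DiGraph, path: str | Path,
                   dot: bool = True, csv: bool = True) -> None:
    """Write the referral network with volume tallies to GraphML (plus a DOT
    rendering and a CSV tally table next to it).

    Node attributes: stratum, total patient volume and its 1500-wide bin;
    edge attribute: referral count.
    """
    path = Path(path)
    export = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        total = data["home_arrivals"] + data["received_referrals"]
        export.add_node(node, stratum=data["stratum"],
                        patient_volume=int(total),
                        volume_bin=volume_bin(total))
    for u, v, data in graph.edges(data=True):
        export.add_edge(u, v, referrals=int(data["referrals"]))
    nx.write_graphml(export, path)
    if dot:
        _write_dot(export, path.with_suffix(".dot"))
    if csv:
        tally_table(graph).to_csv(path.with_suffix(".csv"), index=False)


_DOT_COLORS = {"general": "lightblue", "teaching": "orange", "academic": "red"}


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    lines = ["digraph referrals {", "  rankdir=LR;", "  node [style=filled];"]
    for node, data in graph.nodes(data=True):
        color = _DOT_COLORS.get(data["stratum"], "gray")
        lines.append(
            f'  "{node}" [fillcolor={color}, '
            f'label="{node}\\n{data["patient_volume"]}"];')
    for u, v, data in graph.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [label="{data["referrals"]}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
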