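"""Dispersal-event detection and accumulated latitudinal-dispersion curves.

Ancestral-range reconstructions assign each node either a single area or,
when no overwhelming signal exists, a set of near-tied areas whose proxy
latitudes are averaged. A branch whose endpoint latitudes differ is a
dispersal event; its full displacement (degrees of latitude) is credited to
the 1-Myr bin containing its start age. Only events starting inside the
Triassic window are retained, which keeps Triassic-rooted branches ending
in Jurassic tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areas import AreaScheme
from .statespace import RangeStateSpace
from .trees import TimeCalibratedTree

__all__ = [
    "NodeAreaAssignment",
    "DispersalEvent",
    "DispersalCurve",
    "assign_node_areas",
    "detect_events",
    "accumulate_curves",
    "events_to_frame",
    "TRIASSIC_WINDOW",
    "ANISIAN_RHAETIAN_BINS",
]

TRIASSIC_WINDOW = (251.9, 201.4)  # Ma, Induan base to end-Triassic


@dataclass(frozen=True)
class NodeAreaAssignment:
    """Per-node area (or tied area set) and its proxy latitude."""

    areas: dict          # node id -> tuple of area labels (len 1 = decisive)
    latitudes: dict      # node id -> degrees

    def is_decisive(self, node: int) -> bool:
        return len(self.areas[node]) == 1


@dataclass(frozen=True)
class DispersalEvent:
    parent: int
    child: int
    start_age_ma: float
    parent_latitude: float
    child_latitude: float
    from_areas: tuple
    to_areas: tuple
    clade: str = "all"

    @property
    def displacement_deg(self) -> float:
        return abs(self.child_latitude - self.parent_latitude)


def _state_latitude(areas, scheme: AreaScheme) -> float:
    lats = [scheme.latitude(a) for a in areas]
    return float(np.mean(lats))


def assign_node_areas(
    marginals: np.ndarray,
    space: RangeStateSpace,
    threshold: float = 0.5,
    tie_band: float = 0.1,
) -> NodeAreaAssignment:
    """Turn per-node marginal range probabilities into area assignments.

    A node with a best state that is a single area at probability >=
    ``threshold`` (the "overwhelming signal") gets that area. Otherwise the
    node gets the union of areas over all states within ``tie_band`` of the
    best state's probability, with the arithmetic mean of those areas'
    proxy latitudes.
    """
    scheme = space.scheme
    areas: dict[int, tuple] = {}
    lats: dict[int, float] = {}
    for node, row in enumerate(marginals):
        probs = np.array(row, dtype=float)
        probs[0] = 0.0  # the null range is never an assignment
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"node {node} has no probability mass on non-null states")
        if abs(row.sum() - 1.0) > 1e-6:
            raise ValueError(f"node {node} marginals do not sum to 1")
        best = int(np.argmax(probs))
        best_labels = space.labels(best)
        if len(best_labels) == 1 and probs[best] >= threshold:
            areas[node] = best_labels
            lats[node] = scheme.latitude(best_labels[0])
            continue
        tied = np.flatnonzero(probs >= probs[best] - tie_band)
        labels = sorted({a for s in tied for a in space.labels(int(s))})
        areas[node] = tuple(labels)
        lats[node] = _state_latitude(labels, scheme)
    return NodeAreaAssignment(areas=areas, latitudes=lats)


def detect_events(
    tree: TimeCalibratedTree,
    assignment: NodeAreaAssignment,
    triassic_window: tuple[float, float] = TRIASSIC_WINDOW,
    clade: str = "all",
    start_at: str = "parent",
) -> list[DispersalEvent]:
    """One event per branch whose endpoint latitudes differ.

    ``start_at`` places the event at the parent node's age (default; the
    inclusion rule concerns when events *started*, and within-branch timing
    is unknowable) or at the branch midpoint.
    """
    if start_at not in ("parent", "midpoint"):
        raise ValueError("start_at must be 'parent' or 'midpoint'")
    hi, lo = max(triassic_window), min(triassic_window)
    events = []
    for child in range(tree.n_nodes):
        parent = int(tree.parent[child])
        if parent < 0:
            continue
        lat_p, lat_c = assignment.latitudes[parent], assignment.latitudes[child]
        if abs(lat_c - lat_p) <= 1e-12:
            continue
        if start_at == "parent":
            start = float(tree.ages[parent])
        else:
            start = float((tree.ages[parent] + tree.ages[child]) / 2.0)
        if not (lo <= start <= hi):
            continue
        events.append(
            DispersalEvent(
                parent=parent,
                child=child,
                start_age_ma=start,
                parent_latitude=lat_p,
                child_latitude=lat_c,
                from_areas=assignment.areas[parent],
                to_areas=assignment.areas[child],
                clade=clade,
            )
        )
    events.sort(key=lambda ev: (-ev.start_age_ma, ev.parent, ev.child))
    return events


@dataclass
class DispersalCurve:
    """Accumulated (and event-corrected) latitudinal dispersion per bin."""

    bins: list[tuple[float, float]]
    accumulated_deg: np.ndarray
    corrected_deg: np.ndarray
    event_counts: np.ndarray
    clade: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_Ma": [b[0] for b in self.bins],
                "bin_end_Ma": [b[1] for b in self.bins],
                "clade": self.clade,
                "accumulated_deg": self.accumulated_deg,
                "corrected_deg": self.corrected_deg,
                "cumulative_events": self.event_counts,
            }
        )


ANISIAN_RHAETIAN_BINS = [
    (float(a), float(a - 1.0)) for a in np.arange(247.0, 201.0, -1.0)
]


def accumulate_curves(
    events: list[DispersalEvent],
    bins: list[tuple[float, float]] | None = None,
    by_clade: bool = True,
    correction: str = "cumulative",
) -> dict[str, DispersalCurve]:
    """Build per-clade accumulated latitudinal-dispersion curves.

    An event's full displacement is credited to the bin containing its
    start age; bins are half-open [start, end) in descending Ma, so an
    event at a bin's older edge belongs to that bin. The corrected series
    divides the
    running total by the running event count (``correction="cumulative"``,
    the default) or reports the per-bin mean displacement
    (``correction="per_bin"``); it is 0 where no events have occurred.
    """
    if bins is None:
        bins = ANISIAN_RHAETIAN_BINS
    if correction not in ("cumulative", "per_bin"):
        raise ValueError("correction must be 'cumulative' or 'per_bin'")
    clades = sorted({ev.clade for ev in events}) if by_clade else ["all"]
    if not clades:
        clades = ["all"]
    out: dict[str, DispersalCurve] = {}
    for clade in clades:
        evs = [ev for ev in events if by_clade is False or ev.clade == clade]
        disp = np.zeros(len(bins))
        count = np.zeros(len(bins))
        for ev in evs:
            for i, (hi, lo) in enumerate(bins):
                # oldest bin also includes its upper edge
                in_bin = (lo < ev.start_age_ma <= hi) or (i == 0 and ev.start_age_ma == hi)
                if in_bin:
                    disp[i] += ev.displacement_deg
                    count[i] += 1
                    break
        cum_disp = np.cumsum(disp)
        cum_count = np.cumsum(count)
        if correction == "cumulative":
            with np.errstate(invalid="ignore", divide="ignore"):
                corrected = np.where(cum_count > 0, cum_disp / np.maximum(cum_count, 1), 0.0)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                corrected = np.where(count > 0, disp / np.maximum(count, 1), 0.0)
        out[clade] = DispersalCurve(
            bins=list(bins),
            accumulated_deg=cum_disp,
            corrected_deg=corrected,
            event_counts=cum_count,
            clade=clade,
        )
    return out


def events_to_frame(events: list[DispersalEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parent": [e.parent for e in events],
            "child": [e.child for e in events],
            "start_Ma": [e.start_age_ma for e in events],
            "from_areas": ["+".join(e.from_areas) for e in events],
            "to_areas": ["+".join(e.to_areas) for e in events],
            "displacement_deg": [e.displacement_deg for e in events],
            "clade": [e.clade for e in events],
        }
    )
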