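"""Perfusion-derived flow boundary conditions on the truncated tree.

The arterial flow feeding a segment is its healthy volume times the healthy
perfusion plus, for every tumor hosted by the segment, the tumor volume
times that tumor's perfusion:

    q_s = V0_s * k1_s + sum_i Vc_i * k2_i          [ml/min]

Healthy volume is split equally among the outlets irrigating a segment;
tumor volume is split by explicit non-negative proximity weights.  Per-outlet
flows follow the same rule applied to the assigned volumes, and the inlet
flow is the sum of all outlet flows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vasculature import (
    ArterialTree,
    LiverSegmentRecord,
    PerfusionMap,
    TumorRecord,
    node_positions,
)

__all__ = [
    "OutletTerritory",
    "OutletBC",
    "segment_flow_rate",
    "split_healthy_volume",
    "split_tumor_volume",
    "outlet_flow_rates",
    "inlet_flow_rate",
    "build_territories",
    "proximity_weights",
]


@dataclass(frozen=True)
class OutletTerritory:
    """Tissue volumes irrigated by one outlet."""

    outlet_id: str
    segment: str
    healthy_volume_assigned: float  # ml
    tumor_volume_assigned: dict[str, float]  # tumor_id -> ml

    def __post_init__(self) -> None:
        if self.healthy_volume_assigned < 0:
            raise ValueError(f"{self.outlet_id}: negative healthy volume")
        if any(v < 0 for v in self.tumor_volume_assigned.values()):
            raise ValueError(f"{self.outlet_id}: negative tumor share")


@dataclass(frozen=True)
class OutletBC:
    """Prescribed flow leaving one outlet."""

    outlet_id: str
    flow_rate: float  # ml/min
    flow_fraction: float

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError(f"{self.outlet_id}: negative flow rate")


def segment_flow_rate(
    healthy_volume: float,
    tumor_contributions: list[tuple[float, float]],
    k1: float,
) -> float:
    """Arterial flow (ml/min) feeding one segment.

    ``tumor_contributions`` is a list of (tumor volume ml, tumor perfusion
    ml/min/ml) pairs for every tumor hosted by the segment.
    """
    if healthy_volume < 0 or k1 < 0:
        raise ValueError("healthy_volume and k1 must be non-negative")
    q = healthy_volume * k1
    for vc, k2 in tumor_contributions:
        if vc < 0 or k2 < 0:
            raise ValueError("tumor volume and k2 must be non-negative")
        q += vc * k2
    return q


def split_healthy_volume(
    segment_healthy_volume: float, outlet_ids: list[str]
) -> dict[str, float]:
    """Equal split of a segment's healthy volume among its outlets."""
    if not outlet_ids:
        raise ValueError("at least one outlet is required")
    if segment_healthy_volume < 0:
        raise ValueError("healthy volume must be non-negative")
    share = segment_healthy_volume / len(outlet_ids)
    return {o: share for o in outlet_ids}


def split_tumor_volume(
    tumor_segment_volume: float,
    outlet_ids: list[str],
    proximity_weights: dict[str, float],
) -> dict[str, float]:
    """Proximity-weighted split of a tumor's in-segment volume among outlets."""
    if not outlet_ids:
        raise ValueError("at least one outlet is required")
    w = np.array([proximity_weights[o] for o in outlet_ids], dtype=float)
    if np.any(w < 0):
        raise ValueError("proximity weights must be non-negative")
    total = float(w.sum())
    if total == 0:
        raise ValueError("proximity weights must not all be zero")
    return {o: tumor_segment_volume * float(wi) / total
            for o, wi in zip(outlet_ids, w)}


def outlet_flow_rates(
    territories: list[OutletTerritory],
    perfusion: PerfusionMap,
    tumors: list[TumorRecord],
) -> list[OutletBC]:
    """Per-outlet flows from assigned volumes; fractions of the total."""
    k2_by_tumor = {t.tumor_id: t.k2 for t in tumors}
    flows: list[tuple[str, float]] = []
    for terr in sorted(territories, key=lambda t: t.outlet_id):
        try:
            k1 = perfusion.k1(terr.segment)
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
        q = terr.healthy_volume_assigned * k1
        for tumor_id, vc in terr.tumor_volume_assigned.items():
            q += vc * k2_by_tumor[tumor_id]
        flows.append((terr.outlet_id, q))
    total = sum(q for _, q in flows)
    if total <= 0:
        raise ValueError("total outlet flow is zero; cannot define fractions")
    return [OutletBC(outlet_id=o, flow_rate=q, flow_fraction=q / total)
            for o, q in flows]


def inlet_flow_rate(bcs: list[OutletBC]) -> float:
    """Inlet flow = sum of all outlet flows (ml/min)."""
    if not bcs:
        raise ValueError("at least one outlet BC is required")
    return sum(bc.flow_rate for bc in bcs)


# ---------------------------------------------------------------------------
# territory construction for synthetic phantoms
# ---------------------------------------------------------------------------

def proximity_weights(
    tree: ArterialTree,
    tumor_centroid: np.ndarray,
    outlet_ids: list[str],
) -> dict[str, float]:
    """Inverse-distance weights from a tumor centroid to outlet tips."""
    pos = node_positions(tree)
    weights = {}
    for o in outlet_ids:
        tip = pos[o][1]
        d = float(np.linalg.norm(tip - np.asarray(tumor_centroid, dtype=float)))
        weights[o] = 1.0 / max(d, 1e-12)
    return weights


def build_territories(
    outlet_to_segment: dict[str, str],
    segments: list[LiverSegmentRecord],
    tumors: list[TumorRecord],
    tumor_weights: dict[str, dict[str, float]] | None = None,
) -> list[OutletTerritory]:
    """Assemble per-outlet territories from the outlet->segment mapping.

    ``tumor_weights`` optionally maps tumor_id to per-outlet proximity
    weights; tumors without an entry are split equally among the outlets of
    each hosting segment.
    """
    seg_by_label = {r.segment: r for r in segments}
    outlets_of: dict[str, list[str]] = {}
    for out, seg in sorted(outlet_to_segment.items()):
        if seg not in seg_by_label:
            raise ValueError(f"outlet {out} mapped to unknown segment {seg!r}")
        outlets_of.setdefault(seg, []).append(out)

    healthy_assigned: dict[str, float] = {}
    for seg, outs in outlets_of.items():
        healthy_assigned.update(
            split_healthy_volume(seg_by_label[seg].healthy_volume, outs))

    tumor_assigned: dict[str, dict[str, float]] = {o: {} for o in outlet_to_segment}
    for tumor in tumors:
        for seg, vol in tumor.host_segments.items():
            if vol == 0:
                continue
            outs = outlets_of.get(seg)
            if not outs:
                raise ValueError(
                    f"tumor {tumor.tumor_id} lies in segment {seg} "
                    "which has no outlet"
                )
            if tumor_weights and tumor.tumor_id in tumor_weights:
                w = {o: tumor_weights[tumor.tumor_id].get(o, 0.0) for o in outs}
                if sum(w.values()) == 0:
                    w = {o: 1.0 for o in outs}
            else:
                w = {o: 1.0 for o in outs}
            for o, share in split_tumor_volume(vol, outs, w).items():
                if share > 0:
                    tumor_assigned[o][tumor.tumor_id] = (
                        tumor_assigned[o].get(tumor.tumor_id, 0.0) + share)

    return [
        OutletTerritory(
            outlet_id=o,
            segment=outlet_to_segment[o],
            healthy_volume_assigned=healthy_assigned.get(o, 0.0),
            tumor_volume_assigned=tumor_assigned[o],
        )
        for o in sorted(outlet_to_segment)
    ]
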