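"""Synthetic hepatic arterial trees and liver perfusion phantoms.

This module generates the *inputs* a personalized treatment simulation would
normally take from imaging: a truncated arterial tree (binary branching,
Murray's law radii), per-segment healthy/tumor volumes with arterial
perfusions, catheter placements, and a noisy "observed" activity distribution
standing in for post-treatment quantitative imaging.

All geometry is SI (meters) internally; volumes are ml and perfusions
ml/min/ml at the interface level.  Every generator is a pure function of its
parameters and an integer seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VesselNode",
    "ArterialTree",
    "LiverSegmentRecord",
    "TumorRecord",
    "PerfusionMap",
    "CatheterPlacement",
    "ObservedDistribution",
    "generate_tree",
    "generate_liver_phantom",
    "map_outlets_to_segments",
    "synthesize_observed_distribution",
    "validate_tree",
    "node_positions",
    "branch_frame",
    "tree_to_json",
    "tree_from_json",
]

SEGMENT_LABELS = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")

#: phantom sampling envelopes (ml, ml and ml/min/ml)
HEALTHY_VOLUME_RANGE = (0.0, 400.0)
TUMOR_VOLUME_RANGE = (0.0, 70.0)
K1_RANGE = (0.02, 0.12)
K2_RANGE = (0.35, 1.30)

TREE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselNode:
    """A straight vessel element of the truncated arterial tree."""

    id: str
    parent_id: str | None
    length: float  # m
    radius: float  # m
    direction: np.ndarray  # unit 3-vector
    daughter_ids: tuple[str, ...] = ()
    is_outlet: bool = False

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"node {self.id}: radius must be > 0")
        if self.length <= 0:
            raise ValueError(f"node {self.id}: length must be > 0")
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"node {self.id}: direction must be unit norm")
        if self.is_outlet and self.daughter_ids:
            raise ValueError(f"node {self.id}: an outlet cannot have daughters")


@dataclass
class ArterialTree:
    """Truncated arterial tree: one inlet (root), outlets at the leaves."""

    nodes: dict[str, VesselNode]
    root_id: str
    outlet_ids: list[str]
    murray_exponent: float = 3.0

    def node(self, node_id: str) -> VesselNode:
        return self.nodes[node_id]

    @property
    def n_outlets(self) -> int:
        return len(self.outlet_ids)

    def min_radius(self) -> float:
        return min(n.radius for n in self.nodes.values())


@dataclass(frozen=True)
class LiverSegmentRecord:
    """Healthy and tumor tissue volume contained in one liver segment."""

    segment: str
    healthy_volume: float  # ml
    tumor_volume: float = 0.0  # ml

    def __post_init__(self) -> None:
        if self.healthy_volume < 0 or self.tumor_volume < 0:
            raise ValueError(f"{self.segment}: volumes must be non-negative")

    @property
    def total_volume(self) -> float:
        return self.healthy_volume + self.tumor_volume


@dataclass(frozen=True)
class TumorRecord:
    """A tumor, possibly spanning several segments.

    A lesion spanning x segments is handled as x per-segment contributions,
    so ``host_segments`` maps each hosting segment to the volume share (ml)
    lying inside it; shares sum to ``total_volume``.
    """

    tumor_id: str
    total_volume: float  # ml
    host_segments: dict[str, float]  # segment -> ml
    k2: float  # ml/min/ml

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise ValueError(f"{self.tumor_id}: total_volume must be > 0")
        if self.k2 <= 0:
            raise ValueError(f"{self.tumor_id}: k2 must be > 0")
        if any(v < 0 for v in self.host_segments.values()):
            raise ValueError(f"{self.tumor_id}: negative segment share")
        s = sum(self.host_segments.values())
        if abs(s - self.total_volume) > 1e-9 * max(1.0, self.total_volume):
            raise ValueError(
                f"{self.tumor_id}: segment shares sum to {s}, "
                f"expected {self.total_volume}"
            )


@dataclass(frozen=True)
class PerfusionMap:
    """Healthy-parenchyma arterial perfusion per segment (ml/min/ml)."""

    k1_healthy: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.k1_healthy.values()):
            raise ValueError("perfusions must be non-negative")

    def k1(self, segment: str) -> float:
        try:
            return self.k1_healthy[segment]
        except KeyError:
            raise KeyError(f"no healthy perfusion entry for segment {segment!r}")


@dataclass(frozen=True)
class CatheterPlacement:
    """Microcatheter tip location inside a vessel plus injection protocol.

    ``radial_offset_fraction`` = 0 is a centered tip; values approaching 1
    push the tip toward the wall along the ``azimuth`` direction in the
    vessel cross-section.
    """

    vessel_id: str
    axial_fraction: float
    radial_offset_fraction: float
    azimuth: float
    injection_velocity: float  # m/s
    injected_activity: float  # GBq
    catheter_inner_radius: float  # m

    def __post_init__(self) -> None:
        if not 0.0 <= self.axial_fraction <= 1.0:
            raise ValueError("axial_fraction must be in [0, 1]")
        if not 0.0 <= self.radial_offset_fraction < 1.0:
            raise ValueError("radial_offset_fraction must be in [0, 1)")
        if self.injection_velocity <= 0:
            raise ValueError("injection_velocity must be > 0")
        if self.injected_activity <= 0:
            raise ValueError("injected_activity must be > 0")
        if self.catheter_inner_radius <= 0:
            raise ValueError("catheter_inner_radius must be > 0")

    def check_fits(self, vessel_radius: float) -> None:
        """Reject placements whose catheter lumen leaves the vessel lumen."""
        if self.catheter_inner_radius >= vessel_radius:
            raise ValueError(
                "catheter_inner_radius must be smaller than the vessel radius"
            )
        tip_offset = self.radial_offset_fraction * vessel_radius
        if tip_offset + self.catheter_inner_radius > vessel_radius:
            raise ValueError(
                "catheter lumen extends outside the vessel lumen "
                f"(offset {tip_offset:.2e} + lumen {self.catheter_inner_radius:.2e}"
                f" > vessel radius {vessel_radius:.2e})"
            )


@dataclass(frozen=True)
class ObservedDistribution:
    """A synthetic 'measured' per-segment activity distribution (percent)."""

    percent: dict[str, float]
    noise_sd: float
    seed: int | None

    def __post_init__(self) -> None:
        vals = list(self.percent.values())
        if any(v < 0 for v in vals):
            raise ValueError("percentages must be non-negative")
        if abs(sum(vals) - 100.0) > 1e-9 * 100.0:
            raise ValueError("percentages must sum to 100")


# ---------------------------------------------------------------------------
# tree generation and validation
# ---------------------------------------------------------------------------

def _orthonormal_complement(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(ref, axis))) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def branch_frame(direction: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal frame (axis, e1, e2) for a branch, rows stacked."""
    axis = np.asarray(direction, dtype=float)
    e1, e2 = _orthonormal_complement(axis)
    return np.stack([axis, e1, e2])


def generate_tree(
    depth: int,
    root_radius: float,
    murray_exponent: float = 3.0,
    asymmetry: float = 1.0,
    seed: int | None = 0,
    length_ratio: float = 8.0,
    root_direction: np.ndarray | None = None,
    branch_angle: float = math.radians(35.0),
) -> ArterialTree:
    """Generate a full binary tree with Murray's-law radii.

    At each bifurcation a daughter-radius ratio alpha is drawn uniformly in
    [asymmetry, 1] and radii satisfy r_parent^m = r_d1^m + r_d2^m with
    m = ``murray_exponent``.  ``depth`` counts vessel generations, so a
    depth-d full tree has 2^(d-1) outlets.  Vessel length is
    ``length_ratio`` times the vessel radius.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if root_radius <= 0:
        raise ValueError("root_radius must be > 0")
    if not 0.0 < asymmetry <= 1.0:
        raise ValueError("asymmetry must be in (0, 1]")

    rng = np.random.default_rng(seed)
    if root_direction is None:
        root_direction = np.array([1.0, 0.0, 0.0])
    root_direction = np.asarray(root_direction, dtype=float)
    root_direction = root_direction / np.linalg.norm(root_direction)

    nodes: dict[str, VesselNode] = {}
    outlet_ids: list[str] = []
    m = murray_exponent

    def build(node_id: str, parent_id: str | None, radius: float,
              direction: np.ndarray, level: int) -> None:
        is_leaf = level == depth
        daughters: tuple[str, ...] = ()
        if not is_leaf:
            daughters = (node_id + "0", node_id + "1")
        nodes[node_id] = VesselNode(
            id=node_id,
            parent_id=parent_id,
            length=length_ratio * radius,
            radius=radius,
            direction=direction / np.linalg.norm(direction),
            daughter_ids=daughters,
            is_outlet=is_leaf,
        )
        if is_leaf:
            outlet_ids.append(node_id)
            return
        alpha = float(rng.uniform(asymmetry, 1.0))
        r1 = radius * (1.0 + alpha**m) ** (-1.0 / m)
        r2 = alpha * r1
        psi = float(rng.uniform(0.0, 2.0 * math.pi))
        e1, e2 = _orthonormal_complement(direction)
        lateral = math.cos(psi) * e1 + math.sin(psi) * e2
        th1 = branch_angle * (r2 / radius)  # bigger branch deviates less
        th2 = branch_angle * (r1 / radius)
        d1 = math.cos(th1) * direction + math.sin(th1) * lateral
        d2 = math.cos(th2) * direction - math.sin(th2) * lateral
        build(node_id + "0", node_id, r1, d1, level + 1)
        build(node_id + "1", node_id, r2, d2, level + 1)

    build("v", None, float(root_radius), root_direction, 1)
    outlet_ids.sort()
    return ArterialTree(nodes=nodes, root_id="v", outlet_ids=outlet_ids,
                        murray_exponent=m)


def validate_tree(tree: ArterialTree, murray_rel_tol: float = 1e-6) -> None:
    """Structural validator; raises ValueError on the first violation."""
    roots = [n.id for n in tree.nodes.values() if n.parent_id is None]
    if roots != [tree.root_id] and set(roots) != {tree.root_id}:
        raise ValueError(f"expected exactly one root, found {roots}")
    # connectivity + acyclicity by traversal from the root
    seen: set[str] = set()
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        if nid in seen:
            raise ValueError(f"cycle detected at node {nid}")
        seen.add(nid)
        node = tree.nodes[nid]
        for d in node.daughter_ids:
            if tree.nodes[d].parent_id != nid:
                raise ValueError(f"inconsistent parent link at {d}")
            stack.append(d)
    if seen != set(tree.nodes):
        raise ValueError("tree is not connected")
    leaves = sorted(n.id for n in tree.nodes.values() if not n.daughter_ids)
    if leaves != sorted(tree.outlet_ids):
        raise ValueError("outlet_ids must be exactly the leaves")
    for node in tree.nodes.values():
        if node.is_outlet != (not node.daughter_ids):
            raise ValueError(f"node {node.id}: is_outlet/leaf mismatch")
        if len(node.daughter_ids) == 2:
            m = tree.murray_exponent
            d1, d2 = (tree.nodes[d] for d in node.daughter_ids)
            lhs = node.radius**m
            rhs = d1.radius**m + d2.radius**m
            if abs(lhs - rhs) > murray_rel_tol * lhs:
                raise ValueError(
                    f"node {node.id}: branching-law violation "
                    f"({lhs:.6e} vs {rhs:.6e})"
                )


def node_positions(tree: ArterialTree) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Start/end coordinates of every vessel, root starting at the origin."""
    pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def walk(nid: str, start: np.ndarray) -> None:
        node = tree.nodes[nid]
        end = start + node.length * node.direction
        pos[nid] = (start, end)
        for d in node.daughter_ids:
            walk(d, end)

    walk(tree.root_id, np.zeros(3))
    return pos


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def tree_to_json(tree: ArterialTree) -> str:
    doc = {
        "schema_version": TREE_SCHEMA_VERSION,
        "root_id": tree.root_id,
        "outlet_ids": sorted(tree.outlet_ids),
        "murray_exponent": tree.murray_exponent,
        "nodes": [
            {
                "id": n.id,
                "parent": n.parent_id,
                "length_m": n.length,
                "radius_m": n.radius,
                "direction": [float(x) for x in n.direction],
                "daughters": list(n.daughter_ids),
                "is_outlet": n.is_outlet,
            }
            for n in sorted(tree.nodes.values(), key=lambda n: n.id)
        ],
    }
    return json.dumps(doc, indent=2)


def tree_from_json(text: str) -> ArterialTree:
    doc = json.loads(text)
    if doc.get("schema_version") != TREE_SCHEMA_VERSION:
        raise ValueError(f"unsupported tree schema_version {doc.get('schema_version')}")
    nodes = {
        d["id"]: VesselNode(
            id=d["id"],
            parent_id=d["parent"],
            length=float(d["length_m"]),
            radius=float(d["radius_m"]),
            direction=np.array(d["direction"], dtype=float),
            daughter_ids=tuple(d["daughters"]),
            is_outlet=bool(d["is_outlet"]),
        )
        for d in doc["nodes"]
    }
    tree = ArterialTree(
        nodes=nodes,
        root_id=doc["root_id"],
        outlet_ids=list(doc["outlet_ids"]),
        murray_exponent=float(doc.get("murray_exponent", 3.0)),
    )
    validate_tree(tree)
    return tree


# ---------------------------------------------------------------------------
# liver phantom
# ---------------------------------------------------------------------------

def generate_liver_phantom(
    n_tumors: int,
    seed: int | None = 0,
) -> tuple[list[LiverSegmentRecord], list[TumorRecord], PerfusionMap]:
    """Draw an 8-segment liver phantom with optional tumors.

    Healthy volumes, tumor volumes and perfusions are sampled uniformly
    inside fixed physiological envelopes (see module constants).  Tumors are
    placed in one or two host segments; a lesion spanning two segments is
    split into per-segment shares.  Per-segment tumor load is capped at the
    tumor-volume envelope.
    """
    if n_tumors < 0:
        raise ValueError("n_tumors must be >= 0")
    rng = np.random.default_rng(seed)

    healthy = {s: float(rng.uniform(20.0, HEALTHY_VOLUME_RANGE[1]))
               for s in SEGMENT_LABELS}
    k1 = {s: float(rng.uniform(*K1_RANGE)) for s in SEGMENT_LABELS}

    tumor_load = {s: 0.0 for s in SEGMENT_LABELS}
    tumors: list[TumorRecord] = []
    for i in range(n_tumors):
        volume = float(rng.uniform(1.0, 30.0))
        n_hosts = int(rng.integers(1, 3))
        cap = TUMOR_VOLUME_RANGE[1]
        eligible = [s for s in SEGMENT_LABELS
                    if tumor_load[s] + volume <= cap]
        if len(eligible) < n_hosts:
            n_hosts = 1
            eligible = [s for s in SEGMENT_LABELS if tumor_load[s] + volume <= cap]
            if not eligible:  # pathological; shrink the lesion to fit
                volume = cap - max(tumor_load.values())
                eligible = list(SEGMENT_LABELS)
        hosts = [str(s) for s in rng.choice(eligible, size=n_hosts, replace=False)]
        if n_hosts == 1:
            shares = {hosts[0]: volume}
        else:
            w = float(rng.uniform(0.2, 0.8))
            shares = {hosts[0]: w * volume, hosts[1]: (1.0 - w) * volume}
        for s, v in shares.items():
            tumor_load[s] += v
        tumors.append(TumorRecord(
            tumor_id=f"t{i + 1}",
            total_volume=volume,
            host_segments=shares,
            k2=float(rng.uniform(*K2_RANGE)),
        ))

    segments = [
        LiverSegmentRecord(segment=s, healthy_volume=healthy[s],
                           tumor_volume=tumor_load[s])
        for s in SEGMENT_LABELS
    ]
    return segments, tumors, PerfusionMap(k1_healthy=k1)


def map_outlets_to_segments(
    tree: ArterialTree,
    segments: list[LiverSegmentRecord],
    seed: int | None = 0,
) -> dict[str, str]:
    """Assign every outlet to one liver segment.

    Each segment with positive total volume receives at least one outlet;
    remaining outlets are distributed at random among positive-volume
    segments.  Zero-volume segments receive no outlets.
    """
    positive = [r.segment for r in segments if r.total_volume > 0]
    outlets = sorted(tree.outlet_ids)
    if len(outlets) < len(positive):
        raise ValueError(
            f"{len(outlets)} outlets cannot cover {len(positive)} "
            "positive-volume segments"
        )
    rng = np.random.default_rng(seed)
    order = [outlets[i] for i in rng.permutation(len(outlets))]
    mapping: dict[str, str] = {}
    for seg, out in zip(positive, order):
        mapping[out] = seg
    for out in order[len(positive):]:
        mapping[out] = positive[int(rng.integers(0, len(positive)))]
    return dict(sorted(mapping.items()))


# ---------------------------------------------------------------------------
# synthetic observation
# ---------------------------------------------------------------------------

def synthesize_observed_distribution(
    true_percent: dict[str, float],
    noise_sd: float,
    seed: int | None = 0,
) -> ObservedDistribution:
    """Perturb a true percent distribution with additive Gaussian noise.

    Percentages are perturbed independently (sd in percentage points),
    clamped at zero and renormalized to sum 100.  ``noise_sd = 0`` returns
    the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    total = sum(true_percent.values())
    if abs(total - 100.0) > 1e-6 * 100.0:
        raise ValueError(f"true distribution sums to {total}, expected 100")
    if noise_sd == 0:
        return ObservedDistribution(percent=dict(true_percent),
                                    noise_sd=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    keys = list(true_percent)
    vals = np.array([true_percent[k] for k in keys], dtype=float)
    noisy = np.clip(vals + rng.normal(0.0, noise_sd, size=vals.size), 0.0, None)
    s = float(noisy.sum())
    if s <= 0:
        raise ValueError("noise wiped out the whole distribution; lower noise_sd")
    noisy *= 100.0 / s
    # kill residual rounding so the sum invariant holds at 1e-9
    noisy[int(np.argmax(noisy))] += 100.0 - noisy.sum()
    return ObservedDistribution(
        percent={k: float(v) for k, v in zip(keys, noisy)},
        noise_sd=float(noise_sd),
        seed=seed,
    )
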