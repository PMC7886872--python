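"""Convert outlet exit tallies into per-segment activity distributions.

Activity reaching a segment is the activity leaving the domain through the
outlets irrigating that segment.  The accounting defaults carry two
independent calibration constants: the per-vial sphere count (44.48e6 spheres
per 3 GBq calibration vial) and a nominal 50 Bq per sphere; the latter is
what drives the activity bookkeeping, and both are echoed into reports.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ActivityScaling",
    "SegmentDistribution",
    "counts_to_segment_distribution",
    "distribution_to_activity",
    "combine_infusions",
]

GBQ_TO_BQ = 1e9


@dataclass(frozen=True)
class ActivityScaling:
    """Sphere-count and activity calibration for one infusion."""

    injected_activity: float                 # GBq
    spheres_per_vial: float = 44.48e6        # per vial_activity GBq
    vial_activity: float = 3.0               # GBq
    activity_per_sphere: float = 50.0        # Bq

    def __post_init__(self) -> None:
        if min(self.injected_activity, self.spheres_per_vial,
               self.vial_activity, self.activity_per_sphere) <= 0:
            raise ValueError("all scaling constants must be strictly positive")

    @property
    def injected_activity_bq(self) -> float:
        return self.injected_activity * GBQ_TO_BQ

    @property
    def represented_spheres(self) -> float:
        """Number of real microspheres the injection represents (50 Bq each)."""
        return self.injected_activity_bq / self.activity_per_sphere

    def sphere_weight(self, n_simulated: int) -> float:
        """Real microspheres represented by one simulated particle."""
        return self.represented_spheres / n_simulated


@dataclass
class SegmentDistribution:
    """Percent of exited activity per segment plus absolute accounting."""

    percent: dict[str, float]
    total_activity_bq: float = 0.0
    activity_bq: dict[str, float] | None = None
    concentration_bq_ml: dict[str, float] | None = None

    def __post_init__(self) -> None:
        vals = list(self.percent.values())
        if any(v < 0 for v in vals):
            raise ValueError("percentages must be non-negative")
        if abs(sum(vals) - 100.0) > 1e-9 * 100.0:
            raise ValueError(f"percentages sum to {sum(vals)}, expected 100")


def counts_to_segment_distribution(
    result, territory: dict[str, str]
) -> dict[str, float]:
    """Per-segment percentages of exited particles.

    ``territory`` maps outlet ids to segment labels; resident particles are
    excluded from the denominator.  Segments appearing in ``territory`` but
    receiving no particles report 0.
    """
    missing = [o for o in result.exit_counts if o not in territory]
    if missing:
        raise ValueError(f"outlets with no segment assignment: {missing}")
    total = sum(result.exit_counts.values())
    if total == 0:
        raise ValueError("no particles exited; distribution undefined")
    per_segment = {seg: 0.0 for seg in sorted(set(territory.values()))}
    for outlet, count in result.exit_counts.items():
        per_segment[territory[outlet]] += count
    return {seg: 100.0 * c / total for seg, c in per_segment.items()}


def distribution_to_activity(
    percent: dict[str, float],
    scaling: ActivityScaling,
    segments,
) -> SegmentDistribution:
    """Absolute activity (Bq) and mean concentration (Bq/ml) per segment.

    Concentration divides by the segment's total (healthy + tumor) volume.
    """
    total_pct = sum(percent.values())
    if abs(total_pct - 100.0) > 1e-6 * 100.0:
        raise ValueError(f"percentages sum to {total_pct}, expected 100")
    volume = {r.segment: r.total_volume for r in segments}
    activity = {}
    concentration = {}
    for seg, pct in percent.items():
        a = scaling.injected_activity_bq * pct / 100.0
        if a > 0 and volume.get(seg, 0.0) <= 0:
            raise RuntimeError(
                f"activity assigned to zero-volume segment {seg!r}")
        activity[seg] = a
        concentration[seg] = a / volume[seg] if volume.get(seg, 0.0) > 0 else 0.0
    return SegmentDistribution(
        percent=dict(percent),
        total_activity_bq=scaling.injected_activity_bq,
        activity_bq=activity,
        concentration_bq_ml=concentration,
    )


def combine_infusions(
    distributions: list[SegmentDistribution],
) -> SegmentDistribution:
    """Sum several infusions' absolute activities into one distribution."""
    if not distributions:
        raise ValueError("at least one infusion distribution is required")
    segs = sorted({s for d in distributions for s in d.percent})
    activity = {s: 0.0 for s in segs}
    for d in distributions:
        if d.activity_bq is None:
            raise ValueError("infusion distributions must carry absolute activity")
        for s, a in d.activity_bq.items():
            activity[s] += a
    total = sum(activity.values())
    if total <= 0:
        raise ValueError("total combined activity is zero")
    return SegmentDistribution(
        percent={s: 100.0 * a / total for s, a in activity.items()},
        total_activity_bq=total,
        activity_bq=activity,
    )
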