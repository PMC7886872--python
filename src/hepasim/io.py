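"""CSV/JSON round-trips for phantoms, boundary conditions and distributions.

Perfusion columns in CSV files use ml/min/100ml (the clinical convention);
they are converted to ml/min/ml on read and back on write.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .activity import SegmentDistribution
from .boundary import OutletBC
from .vasculature import LiverSegmentRecord, PerfusionMap, TumorRecord

__all__ = [
    "read_segments_csv",
    "write_segments_csv",
    "read_tumors_csv",
    "write_tumors_csv",
    "read_perfusion_csv",
    "write_perfusion_csv",
    "write_bc_csv",
    "read_distribution_csv",
    "write_distribution_csv",
]

SEGMENTS_COLUMNS = ["patient", "segment", "tumoral_volume_ml", "healthy_volume_ml"]
TUMORS_COLUMNS = ["tumor", "volume_ml", "k2_ml_min_100ml", "k1_ml_min_100ml",
                  "segments", "injection_velocity_m_s"]
PERFUSION_COLUMNS = ["segment", "k1_ml_min_100ml"]
BC_COLUMNS = ["outlet_id", "segment", "flow_ml_min", "flow_fraction"]
DISTRIBUTION_COLUMNS = ["segment", "percent", "activity_Bq", "concentration_Bq_ml"]


def _require_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")
    if df.empty:
        raise ValueError(f"{what}: table has no rows")


def read_segments_csv(path, patient: str | None = None) -> list[LiverSegmentRecord]:
    df = pd.read_csv(path)
    _require_columns(df, SEGMENTS_COLUMNS, f"segment table {path}")
    if patient is not None:
        df = df[df["patient"].astype(str) == str(patient)]
        if df.empty:
            raise ValueError(f"segment table {path}: no rows for patient {patient!r}")
    return [
        LiverSegmentRecord(
            segment=str(row.segment),
            healthy_volume=float(row.healthy_volume_ml),
            tumor_volume=float(row.tumoral_volume_ml),
        )
        for row in df.itertuples()
    ]


def write_segments_csv(segments: list[LiverSegmentRecord], path,
                       patient: str = "synthetic") -> None:
    df = pd.DataFrame({
        "patient": [patient] * len(segments),
        "segment": [r.segment for r in segments],
        "tumoral_volume_ml": [r.tumor_volume for r in segments],
        "healthy_volume_ml": [r.healthy_volume for r in segments],
    })
    df.to_csv(path, index=False)


def read_tumors_csv(path) -> tuple[list[TumorRecord], dict[str, float], dict[str, float]]:
    """Read a tumor table.

    Returns (tumors, k1 by segment for the segments listed, injection
    velocity by tumor id).  A tumor spanning several segments lists them
    separated by ';' and its volume is split equally among them (the table
    format does not carry per-segment shares).
    """
    df = pd.read_csv(path)
    _require_columns(df, TUMORS_COLUMNS, f"tumor table {path}")
    tumors: list[TumorRecord] = []
    k1: dict[str, float] = {}
    velocity: dict[str, float] = {}
    for row in df.itertuples():
        segs = [s.strip() for s in str(row.segments).split(";") if s.strip()]
        if not segs:
            raise ValueError(f"tumor table {path}: empty 'segments' entry "
                             f"for tumor {row.tumor}")
        vol = float(row.volume_ml)
        shares = {s: vol / len(segs) for s in segs}
        tumors.append(TumorRecord(
            tumor_id=str(row.tumor),
            total_volume=vol,
            host_segments=shares,
            k2=float(row.k2_ml_min_100ml) / 100.0,
        ))
        for s in segs:
            k1[s] = float(row.k1_ml_min_100ml) / 100.0
        velocity[str(row.tumor)] = float(row.injection_velocity_m_s)
    return tumors, k1, velocity


def write_tumors_csv(tumors: list[TumorRecord], perfusion: PerfusionMap, path,
                     injection_velocity: float = 1.0) -> None:
    rows = []
    for t in tumors:
        segs = sorted(t.host_segments)
        rows.append({
            "tumor": t.tumor_id,
            "volume_ml": t.total_volume,
            "k2_ml_min_100ml": t.k2 * 100.0,
            "k1_ml_min_100ml": perfusion.k1(segs[0]) * 100.0,
            "segments": ";".join(segs),
            "injection_velocity_m_s": injection_velocity,
        })
    pd.DataFrame(rows, columns=TUMORS_COLUMNS).to_csv(path, index=False)


def read_perfusion_csv(path) -> PerfusionMap:
    df = pd.read_csv(path)
    _require_columns(df, PERFUSION_COLUMNS, f"perfusion table {path}")
    return PerfusionMap(k1_healthy={
        str(row.segment): float(row.k1_ml_min_100ml) / 100.0
        for row in df.itertuples()
    })


def write_perfusion_csv(perfusion: PerfusionMap, path) -> None:
    items = sorted(perfusion.k1_healthy.items())
    pd.DataFrame({
        "segment": [s for s, _ in items],
        "k1_ml_min_100ml": [v * 100.0 for _, v in items],
    }).to_csv(path, index=False)


def write_bc_csv(bcs: list[OutletBC], outlet_to_segment: dict[str, str], path) -> None:
    rows = sorted(bcs, key=lambda bc: bc.outlet_id)
    pd.DataFrame({
        "outlet_id": [bc.outlet_id for bc in rows],
        "segment": [outlet_to_segment[bc.outlet_id] for bc in rows],
        "flow_ml_min": [bc.flow_rate for bc in rows],
        "flow_fraction": [bc.flow_fraction for bc in rows],
    }).to_csv(path, index=False)


def write_distribution_csv(dist: SegmentDistribution, path) -> None:
    segs = sorted(dist.percent)
    pd.DataFrame({
        "segment": segs,
        "percent": [dist.percent[s] for s in segs],
        "activity_Bq": [
            (dist.activity_bq or {}).get(s, float("nan")) for s in segs],
        "concentration_Bq_ml": [
            (dist.concentration_bq_ml or {}).get(s, float("nan")) for s in segs],
    }).to_csv(path, index=False)


def read_distribution_csv(path) -> SegmentDistribution:
    df = pd.read_csv(path)
    _require_columns(df, ["segment", "percent"], f"distribution table {path}")
    percent = {str(r.segment): float(r.percent) for r in df.itertuples()}
    activity = None
    concentration = None
    if "activity_Bq" in df.columns and not df["activity_Bq"].isna().all():
        activity = {str(r.segment): float(r.activity_Bq) for r in df.itertuples()}
    if ("concentration_Bq_ml" in df.columns
            and not df["concentration_Bq_ml"].isna().all()):
        concentration = {str(r.segment): float(r.concentration_Bq_ml)
                         for r in df.itertuples()}
    return SegmentDistribution(
        percent=percent,
        total_activity_bq=sum(activity.values()) if activity else 0.0,
        activity_bq=activity,
        concentration_bq_ml=concentration,
    )


def example_table_path(name: str) -> Path:
    """Path to a packaged example table (e.g. 'patient2_tumors.csv')."""
    p = Path(__file__).parent / "data" / name
    if not p.exists():
        raise FileNotFoundError(f"no packaged table named {name!r}")
    return p
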