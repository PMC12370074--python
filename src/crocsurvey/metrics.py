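"""Mission-level abundance indices, survey summaries and cost comparison.

Two simple indices summarize each drone mission: the relative abundance
index RAI = counts per hour of flight, and the observed density OD = counts
per km^2 of imaged surface. The module also reproduces the campaign summary
table (totals, means, sample SDs over missions) and the boat-vs-drone cost
comparison (total cost and cost per surveyed km).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up

#: conflicting printed campaign distance totals; the larger figure is the
#: pre-stitching flight distance and is the default for drone cost-per-km
TOTAL_DISTANCE_FLOWN_KM = 702.66
TOTAL_DISTANCE_STITCHED_KM = 694.2
TOTAL_SURFACE_KM2 = 44.68


@dataclass
class MissionRecord:
    """One drone mission's effort and species counts (a summary-table row)."""

    mission_id: int
    time_window: str
    distance_km: float
    flight_min: float
    surface_km2: float
    photo_count: int
    count_A: int
    count_B: int

    def __post_init__(self):
        if self.distance_km <= 0 or self.flight_min <= 0 or self.surface_km2 <= 0:
            raise ValueError("mission effort values must be positive")
        if self.count_A < 0 or self.count_B < 0:
            raise ValueError("species counts must be non-negative")


@dataclass
class SurveySummary:
    """Per-mission indices plus totals, means and sample SDs."""

    table: pd.DataFrame
    totals: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    sd_defined: bool = True


@dataclass
class CostModel:
    """One survey type's cost sheet: labor rows plus effort denominators.

    Row costs are taken as data (the printed sheets include expenses beyond
    rate x persons x days); the conservation invariant is that the total
    equals the sum of row costs.
    """

    survey_type: str
    rows: list[dict] = field(default_factory=list)
    surveyed_distance_km: float = 0.0
    surveyed_hours: float = 0.0

    @property
    def total_cost(self) -> float:
        return float(sum(r["cost_usd"] for r in self.rows))


def rai(count: int, flight_min: float) -> float:
    """Relative abundance index: detections per hour of flight."""
    if flight_min <= 0:
        raise ValueError("flight time must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return round_half_up(count / (flight_min / 60.0), 2)


def od(count: int, area_km2: float) -> float:
    """Observed density: detections per km^2 of imaged surface."""
    if area_km2 <= 0:
        raise ValueError("surface area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return round_half_up(count / area_km2, 2)


def floating_fraction(floating_count: int, total_count: int) -> int:
    """Percentage of detected animals that were floating, to the nearest 1%."""
    if total_count <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= floating_count <= total_count:
        raise ValueError("floating count must lie between 0 and the total")
    return int(round_half_up(100.0 * floating_count / total_count, 0))


def cost_per_km(model: CostModel, distance_km: float | None = None) -> float:
    """Total survey cost divided by surveyed distance, in currency per km."""
    d = model.surveyed_distance_km if distance_km is None else distance_km
    if d <= 0:
        raise ValueError("surveyed distance must be positive")
    return round_half_up(model.total_cost / d, 2)


def summarize_missions(records: list[MissionRecord]) -> SurveySummary:
    """Per-mission RAI/OD for both species plus column totals, means and
    sample SDs (n-1 denominator) over all missions, zeros included.

    With a single mission the SD is undefined; it is reported as 0 with
    ``sd_defined=False``.
    """
    if not records:
        raise ValueError("at least one mission record is required")
    rows = []
    for r in records:
        rows.append(
            {
                "mission_id": r.mission_id,
                "distance_km": r.distance_km,
                "flight_min": r.flight_min,
                "surface_km2": r.surface_km2,
                "photo_count": r.photo_count,
                "count_A": r.count_A,
                "count_B": r.count_B,
                "rai_A": r.count_A / (r.flight_min / 60.0),
                "rai_B": r.count_B / (r.flight_min / 60.0),
                "od_A": r.count_A / r.surface_km2,
                "od_B": r.count_B / r.surface_km2,
            }
        )
    df = pd.DataFrame(rows)
    totals = {
        c: float(df[c].sum())
        for c in ["distance_km", "flight_min", "surface_km2", "photo_count", "count_A", "count_B"]
    }
    stat_cols = ["distance_km", "flight_min", "surface_km2", "rai_A", "rai_B", "od_A", "od_B"]
    means = {c: float(df[c].mean()) for c in stat_cols}
    sd_defined = len(df) > 1
    sds = {c: float(df[c].std(ddof=1)) if sd_defined else 0.0 for c in stat_cols}
    return SurveySummary(table=df, totals=totals, means=means, sds=sds, sd_defined=sd_defined)


# ---------------------------------------------------------------- fixtures


def _data_path(name: str):
    return importlib.resources.files("crocsurvey.data").joinpath(name)


def load_mission_table() -> list[MissionRecord]:
    """The 27-mission campaign summary shipped with the package."""
    df = pd.read_csv(_data_path("table1_missions.csv"))
    return [
        MissionRecord(
            mission_id=int(r.mission_id),
            time_window=r.time_window,
            distance_km=float(r.distance_km),
            flight_min=float(r.flight_min),
            surface_km2=float(r.surface_km2),
            photo_count=int(r.photo_count),
            count_A=int(r.count_gharial),
            count_B=int(r.count_mugger),
        )
        for r in df.itertuples()
    ]


def load_cost_models() -> dict[str, CostModel]:
    """The boat and drone cost sheets shipped with the package."""
    df = pd.read_csv(_data_path("table3_costs.csv"))
    models = {}
    for stype, sub in df.groupby("survey_type", sort=True):
        models[stype] = CostModel(
            survey_type=stype,
            rows=[
                {
                    "role": r.role,
                    "rate_per_person_day": float(r.rate_per_person_day),
                    "persons": int(r.persons),
                    "days": int(r.days),
                    "cost_usd": float(r.cost_usd),
                }
                for r in sub.itertuples()
            ],
            surveyed_distance_km=float(sub["surveyed_distance_km"].iloc[0]),
            surveyed_hours=float(sub["surveyed_hours"].iloc[0]),
        )
    return models


def load_model_selection_table() -> pd.DataFrame:
    """The published model-selection table (AIC machinery fixture)."""
    return pd.read_csv(_data_path("table2_models.csv"))
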