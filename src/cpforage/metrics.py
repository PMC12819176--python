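"""Per-trip movement parameters and their season x status summaries.

Three parameters describe each trip: duration (h) between the departure
and return fixes; maximum distance (km), the farthest straight-line
(great-circle) point from the *colony* — always the colony, even for trips
started from a resting site, so seasonal relocations show up as large
distances; and path length (km), the summed great-circle distance over
consecutive fixes. Metrics use the original speed-filtered fixes, not the
interpolated ones (interpolation smooths the path and would deflate its
length).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import haversine_km
from .segmentation import Trip

logger = logging.getLogger(__name__)


def trip_duration_h(trip: Trip) -> float:
    """Hours between departure and return to the central location."""
    if not trip.complete:
        raise ValueError(f"trip {trip.trip_id} incomplete: duration undefined")
    return trip.duration_h


def max_distance_from_colony_km(trip: Trip, colony: tuple[float, float]) -> float:
    """Farthest great-circle distance (km) from the colony during the trip,
    regardless of which central location the trip started from."""
    f = trip.fixes
    if not len(f):
        raise ValueError("trip has no fixes")
    d = haversine_km(f["lat"].to_numpy(float), f["lon"].to_numpy(float), colony[0], colony[1])
    return float(np.max(d))


def path_length_km(trip: Trip) -> float:
    """Cumulative great-circle distance (km) over consecutive trip fixes."""
    f = trip.fixes
    if len(f) < 2:
        logger.warning("path_length_km: trip %s has < 2 fixes", trip.trip_id)
        return 0.0
    lat = f["lat"].to_numpy(float)
    lon = f["lon"].to_numpy(float)
    return float(np.sum(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))


def trip_metrics(trips: list[Trip], colonies: dict) -> pd.DataFrame:
    """One row of metrics per complete trip.

    ``colonies`` maps status ('urban'/'wild') -> (lat, lon); maximum
    distance is always referenced to the bird's colony. Incomplete trips
    are excluded and counted in the log.
    """
    rows = []
    n_skipped = 0
    for t in trips:
        if not t.complete:
            n_skipped += 1
            continue
        colony = colonies[t.status] if isinstance(colonies, dict) else colonies
        rows.append(
            {
                "trip_id": t.trip_id,
                "bird_id": t.bird_id,
                "status": t.status,
                "season": t.season,
                "central_kind": t.central.kind,
                "duration_h": trip_duration_h(t),
                "max_dist_km": max_distance_from_colony_km(t, colony),
                "path_km": path_length_km(t),
            }
        )
    if n_skipped:
        logger.info("trip_metrics: %d incomplete trip(s) excluded", n_skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "trip_id", "bird_id", "status", "season", "central_kind",
            "duration_h", "max_dist_km", "path_km",
        ],
    )


def summarize_metrics(metrics: pd.DataFrame, emmeans: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per status x season cell: n, mean and median of each metric.

    If ``emmeans`` (from the mixed models, columns status/season/response/
    emm/lcl/ucl) is given, model-based estimates are merged alongside the
    raw summaries.
    """
    value_cols = [c for c in ("duration_h", "max_dist_km", "path_km") if c in metrics.columns]
    out = (
        metrics.groupby(["status", "season"], sort=True)
        .agg(n=("trip_id", "size"), **{
            f"{c}_{stat}": (c, stat) for c in value_cols for stat in ("mean", "median")
        })
        .reset_index()
    )
    if emmeans is not None and len(emmeans):
        wide = emmeans.pivot_table(
            index=["status", "season"], columns="response", values=["emm", "lcl", "ucl"]
        )
        wide.columns = [f"{resp}_{stat}" for stat, resp in wide.columns]
        out = out.merge(wide.reset_index(), on=["status", "season"], how="left")
    return out
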