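"""Outcome statistics computed from vehicle trajectories.

The headline outcome is the **ratio of unsafe driving (RUD)**: the share of
total distance travelled at a speed above the unsafe threshold (the 90 km/h
limit by default), in percent. Because trajectory records are sampled at a
fixed timestep, each record contributes a distance increment speed × dt, so
distance weights are proportional to recorded speed and the timestep cancels
from every ratio.

Also provided: per-group RUD, the space-mean speed (total distance divided by
total travel time — the speed the Power Model crash-risk translation
expects), and position-binned speed profiles used to visualise the kangaroo
V-shape around cameras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RUDResult",
    "compute_rud",
    "compute_group_rud",
    "space_mean_speed",
    "speed_profile",
    "summarize_run",
]


@dataclass(frozen=True)
class RUDResult:
    """Per-(scenario, seed) aggregate outcomes."""

    scenario_id: str
    seed: int
    rud_pct: float
    rud_by_group: dict[str, float]
    space_mean_speed: float  # km/h
    total_distance: float  # vehicle-km
    total_time: float  # vehicle-hours


def _speeds(records: pd.DataFrame) -> np.ndarray:
    if len(records) == 0:
        raise ValueError("empty trajectory set")
    return records["speed_kmh"].to_numpy(dtype=float)


def compute_rud(records: pd.DataFrame, threshold: float = 90.0) -> float:
    """Percent of distance travelled above ``threshold`` km/h (strict).

    Distance increments are speed × dt per record; with constant dt the RUD
    reduces to a speed-weighted share of records.
    """
    v = _speeds(records)
    total = v.sum()
    if total <= 0:
        raise ValueError("zero total distance: degenerate scenario")
    return float(100.0 * v[v > threshold].sum() / total)


def compute_group_rud(
    records: pd.DataFrame, vehicles: pd.DataFrame, threshold: float = 90.0
) -> dict[str, float]:
    """RUD restricted to each driver group's vehicles.

    Groups with no recorded distance are absent from the result (not 0).
    Raises if a record's vehicle is missing from ``vehicles``.
    """
    _speeds(records)
    groups = vehicles.set_index("vehicle_id")["group"]
    g = records["vehicle_id"].map(groups)
    if g.isna().any():
        bad = records.loc[g.isna(), "vehicle_id"].iloc[0]
        raise KeyError(f"vehicle {bad} has no driver group")
    out: dict[str, float] = {}
    for name, sub in records.groupby(g.to_numpy()):
        if sub["speed_kmh"].sum() > 0:
            out[str(name)] = compute_rud(sub, threshold)
    return out


def space_mean_speed(records: pd.DataFrame, dt: float = 1.0) -> float:
    """Total distance / total travel time over all vehicle-steps, km/h.

    With one record per vehicle per timestep this is the flow-weighted
    (space-mean) traffic speed on the segment.
    """
    v = _speeds(records)
    if len(v) == 0:
        raise ValueError("zero total time")
    return float(v.mean())  # sum(v*dt) / (n*dt)


def speed_profile(
    records: pd.DataFrame,
    bin_width: float = 100.0,
    vehicles: pd.DataFrame | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Arithmetic mean recorded speed per position bin.

    Optionally restricted to one driver group (requires ``vehicles``).
    Empty bins are absent. Columns: bin_center, mean_speed_kmh, n.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = records
    if group is not None:
        if vehicles is None:
            raise ValueError("group filter requires the vehicles table")
        vids = vehicles.loc[vehicles["group"] == group, "vehicle_id"]
        sub = records[records["vehicle_id"].isin(set(vids))]
    if len(sub) == 0:
        return pd.DataFrame(columns=["bin_center", "mean_speed_kmh", "n"])
    bins = np.floor(sub["position_m"].to_numpy() / bin_width).astype(int)
    grp = sub.groupby(bins)["speed_kmh"]
    out = pd.DataFrame(
        {
            "bin_center": (grp.mean().index + 0.5) * bin_width,
            "mean_speed_kmh": grp.mean().to_numpy(),
            "n": grp.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def summarize_run(
    result, scenario, threshold: float = 90.0, dt: float = 1.0
) -> RUDResult:
    """Aggregate one simulation run into an :class:`RUDResult`."""
    records = result.records
    v = _speeds(records)
    dist_vkm = float(v.sum() * dt / 3600.0)  # (km/h)*s -> vehicle-km
    time_vh = float(len(v) * dt / 3600.0)
    return RUDResult(
        scenario_id=scenario.scenario_id,
        seed=int(scenario.seed),
        rud_pct=compute_rud(records, threshold),
        rud_by_group=compute_group_rud(records, result.vehicles, threshold),
        space_mean_speed=space_mean_speed(records, dt),
        total_distance=dist_vkm,
        total_time=time_vh,
    )
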