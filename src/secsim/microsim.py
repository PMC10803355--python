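"""Discrete-time car-following microsimulation of a camera-enforced highway.

The modelled facility is a single uninterrupted multi-lane segment (default
6 km, 3 lanes, 90 km/h limit) with no entries, exits or obstacles. Vehicles
follow a Krauss-type safe-velocity rule: each second a vehicle adopts the
minimum of its behavioural desired speed, its acceleration-limited speed, and
the safe speed with respect to its leader, minus a stochastic imperfection.
A minimal overtaking rule lets blocked vehicles move left and free vehicles
return right.

Camera layouts:

``FIX1``/``FIX2``/``FIX3``
    one, two or three fixed spot-speed cameras at the segment midpoint,
    thirds, or quartiles; each camera has an upstream detection zone
    (default 150 m) inside which kangaroo drivers drop to the limit.
``P2P``
    an average-speed (point-to-point) section between the first and third
    quartiles; kangaroo drivers comply across the whole section.

Positions are metres from the segment start; lane 0 is the rightmost lane;
speeds are stored in m/s internally and reported in km/h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .drivers import (
    GROUP_CODES,
    DriverProfile,
    PopulationSpec,
    population_frame,
    sample_population,
)

__all__ = [
    "SEC_TYPES",
    "RoadSpec",
    "CameraLayout",
    "SimParams",
    "SimulationResult",
    "Simulation",
    "behavioral_target_speed",
    "safe_speed",
    "run_simulation",
]

SEC_TYPES = ("FIX1", "FIX2", "FIX3", "P2P")

KMH = 3.6  # m/s -> km/h


@dataclass(frozen=True)
class RoadSpec:
    length: float = 6000.0  # m
    lanes: int = 3
    speed_limit: float = 90.0  # km/h

    def __post_init__(self) -> None:
        if self.length <= 0 or self.lanes < 1 or self.speed_limit <= 0:
            raise ValueError("invalid road specification")


@dataclass(frozen=True)
class CameraLayout:
    """Placement of speed enforcement cameras on the segment."""

    sec_type: str
    camera_positions: tuple[float, ...]
    detection_range: float = 150.0
    p2p_section: tuple[float, float] | None = None
    p2p_compliance: str = "cap"  # "cap" | "compensate"

    def __post_init__(self) -> None:
        if self.sec_type not in SEC_TYPES:
            raise ValueError(f"unknown sec_type {self.sec_type!r}")
        if self.detection_range <= 0:
            raise ValueError("detection_range must be positive")
        if self.sec_type == "P2P" and self.p2p_section is None:
            raise ValueError("P2P layout needs a p2p_section")
        if self.p2p_compliance not in ("cap", "compensate"):
            raise ValueError(f"unknown p2p_compliance {self.p2p_compliance!r}")

    @classmethod
    def for_type(
        cls,
        sec_type: str,
        road: RoadSpec | None = None,
        detection_range: float = 150.0,
        p2p_compliance: str = "cap",
    ) -> "CameraLayout":
        """Standard layout for a camera configuration on ``road``.

        FIX1 at L/2; FIX2 at the thirds; FIX3 at the quartiles; P2P between
        the first and third quartiles.
        """
        L = (road or RoadSpec()).length
        if sec_type == "FIX1":
            cams: tuple[float, ...] = (L / 2,)
        elif sec_type == "FIX2":
            cams = (L / 3, 2 * L / 3)
        elif sec_type == "FIX3":
            cams = (L / 4, L / 2, 3 * L / 4)
        elif sec_type == "P2P":
            return cls(
                "P2P",
                (L / 4, 3 * L / 4),
                detection_range,
                (L / 4, 3 * L / 4),
                p2p_compliance,
            )
        else:
            raise ValueError(f"unknown sec_type {sec_type!r}")
        return cls(sec_type, cams, detection_range)

    @property
    def mode(self) -> int:
        if self.sec_type != "P2P":
            return _kernel.MODE_FIXED
        return (
            _kernel.MODE_P2P_CAP
            if self.p2p_compliance == "cap"
            else _kernel.MODE_P2P_COMPENSATE
        )


@dataclass(frozen=True)
class SimParams:
    """Kinematic and run-length parameters (SUMO-like defaults)."""

    dt: float = 1.0  # s
    max_accel: float = 2.6  # m/s^2
    max_decel: float = 4.5  # m/s^2
    reaction_time: float = 1.0  # s
    sigma: float = 0.5  # driver imperfection, dimensionless
    vehicle_length: float = 5.0  # m
    min_gap: float = 2.5  # m
    duration: float = 3600.0  # s of recorded simulation
    warmup: float = 600.0  # s discarded before recording

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.max_accel <= 0 or self.max_decel <= 0:
            raise ValueError("dt and accelerations must be positive")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")


class CollisionError(RuntimeError):
    """Spacing invariant violated — indicates a simulator bug."""


def behavioral_target_speed(
    driver: DriverProfile, position: float, layout: CameraLayout, limit: float = 90.0
) -> float:
    """Desired speed (km/h) of ``driver`` at ``position`` under ``layout``.

    For P2P layouts this evaluates the default instantaneous-cap compliance;
    the time-dependent "compensate" mode lives in the stepping kernel.
    """
    if position < 0:
        raise ValueError(f"position must be non-negative, got {position}")
    lo, hi = layout.p2p_section if layout.p2p_section else (0.0, -1.0)
    mode = layout.mode
    if mode == _kernel.MODE_P2P_COMPENSATE:
        mode = _kernel.MODE_P2P_CAP
    v = _kernel.target_speed_ms(
        GROUP_CODES[driver.group],
        driver.dffs / KMH,
        driver.telematics,
        float(position),
        mode,
        np.asarray(layout.camera_positions, dtype=np.float64),
        layout.detection_range,
        lo,
        hi,
        limit / KMH,
    )
    return float(v) * KMH


def safe_speed(leader_speed: float, gap: float, params: SimParams) -> float:
    """Krauss safe velocity (m/s) behind a leader at ``leader_speed`` m/s with
    net gap ``gap`` m."""
    if gap < 0:
        raise ValueError(f"negative gap ({gap} m): collision already occurred")
    return float(
        _kernel.safe_speed_ms(
            float(leader_speed), float(gap), params.max_decel, params.reaction_time
        )
    )


@dataclass
class SimulationResult:
    """Trajectories plus the vehicle/driver mapping of one run."""

    records: pd.DataFrame  # vehicle_id, time_s, position_m, speed_kmh, lane
    vehicles: pd.DataFrame  # vehicle_id, driver_id, group, dffs_kmh, telematics
    n_inserted: int
    n_exited: int
    n_on_road_end: int


class Simulation:
    """Mutable world state of one microsimulation run.

    Vehicles are stored in flat arrays indexed by vehicle id (insertion
    order). The heavy per-step work is delegated to the numba kernel; this
    class owns insertion, the driver pool, and trajectory recording.
    """

    _GROW = 256

    def __init__(
        self,
        road: RoadSpec,
        layout: CameraLayout,
        params: SimParams,
        population: Sequence[DriverProfile],
        seed: int,
    ):
        if not population:
            raise ValueError("population must be non-empty")
        self.road = road
        self.layout = layout
        self.params = params
        self.population = list(population)
        self.rng = np.random.default_rng(seed)
        self.noise_seed = int(seed) % 2**31
        self.step_index = 0

        self._pool_dffs = np.array([d.dffs for d in self.population]) / KMH
        self._pool_group = np.array(
            [GROUP_CODES[d.group] for d in self.population], dtype=np.int8
        )
        self._pool_telem = np.array(
            [d.telematics for d in self.population], dtype=np.bool_
        )
        self._pool_order = self.rng.permutation(len(self.population))
        self._pool_ptr = 0

        cap = self._GROW
        self.pos = np.zeros(cap)
        self.speed = np.zeros(cap)
        self.lane = np.zeros(cap, dtype=np.int64)
        self.active = np.zeros(cap, dtype=np.bool_)
        self.veh_driver = np.zeros(cap, dtype=np.int64)
        self._veh_group = np.zeros(cap, dtype=np.int8)
        self._veh_dffs = np.zeros(cap)
        self._veh_telem = np.zeros(cap, dtype=np.bool_)
        self._p2p_entry = np.full(cap, -1.0)

        self.n_vehicles = 0
        self.n_exited = 0
        self.time = 0.0
        self.queue: list[int] = []  # pool indices awaiting insertion

        self._cam = np.asarray(layout.camera_positions, dtype=np.float64)
        self._p2p_lo, self._p2p_hi = (
            layout.p2p_section if layout.p2p_section else (0.0, -1.0)
        )

    # -- vehicle management -------------------------------------------------

    def _grow(self) -> None:
        for name in (
            "pos",
            "speed",
            "lane",
            "active",
            "veh_driver",
            "_veh_group",
            "_veh_dffs",
            "_veh_telem",
            "_p2p_entry",
        ):
            a = getattr(self, name)
            extra = np.full(
                len(a), -1.0 if name == "_p2p_entry" else 0, dtype=a.dtype
            )
            setattr(self, name, np.concatenate([a, extra]))

    def add_vehicle(
        self, pool_index: int, position: float, lane: int, speed_ms: float
    ) -> int:
        """Place a vehicle on the road; returns its vehicle id."""
        if self.n_vehicles == len(self.pos):
            self._grow()
        vid = self.n_vehicles
        self.n_vehicles += 1
        self.pos[vid] = position
        self.speed[vid] = speed_ms
        self.lane[vid] = lane
        self.active[vid] = True
        self.veh_driver[vid] = pool_index
        self._veh_group[vid] = self._pool_group[pool_index]
        self._veh_dffs[vid] = self._pool_dffs[pool_index]
        self._veh_telem[vid] = self._pool_telem[pool_index]
        self._p2p_entry[vid] = -1.0
        return vid

    def _next_driver(self) -> int:
        """Next driver from the pool, cycling with reshuffle when exhausted."""
        if self._pool_ptr == len(self._pool_order):
            self._pool_order = self.rng.permutation(len(self.population))
            self._pool_ptr = 0
        i = int(self._pool_order[self._pool_ptr])
        self._pool_ptr += 1
        return i

    # -- per-step operations -------------------------------------------------

    def insert_vehicles(self, demand_vph: float) -> int:
        """Poisson arrivals at ``demand_vph`` total over all lanes.

        Each arrival is queued with a driver drawn from the pool; queued
        vehicles enter at position 0 in the lane with the largest entry
        headway, at speed min(DFFS, limit), deferred while the entry gap is
        below min_gap + vehicle_length.
        """
        if demand_vph < 0:
            raise ValueError("demand must be non-negative")
        n_arrivals = int(self.rng.poisson(demand_vph / 3600.0 * self.params.dt))
        for _ in range(n_arrivals):
            self.queue.append(self._next_driver())

        inserted = 0
        need = self.params.min_gap + self.params.vehicle_length
        limit_ms = self.road.speed_limit / KMH
        while self.queue:
            headway = np.full(self.road.lanes, np.inf)
            lead_speed = np.zeros(self.road.lanes)
            act = self.active[: self.n_vehicles]
            if act.any():
                lanes = self.lane[: self.n_vehicles][act]
                ps = self.pos[: self.n_vehicles][act]
                vs = self.speed[: self.n_vehicles][act]
                for l in range(self.road.lanes):
                    in_l = lanes == l
                    if in_l.any():
                        j = np.argmin(ps[in_l])
                        headway[l] = ps[in_l][j]
                        lead_speed[l] = vs[in_l][j]
            best = int(np.argmax(headway))
            if headway[best] < need:
                break
            pool_i = self.queue.pop(0)
            v0 = min(self._pool_dffs[pool_i], limit_ms)
            if np.isfinite(headway[best]):
                # cap at the safe speed so the entrant honours the Krauss
                # invariant from its first step
                v0 = min(v0, safe_speed(lead_speed[best], headway[best] - need, self.params))
            self.add_vehicle(pool_i, 0.0, best, v0)
            inserted += 1
        return inserted

    def step(self) -> int:
        """One timestep of lane changes, car following and motion.

        Returns the number of vehicles that left the segment. Raises
        :class:`CollisionError` if the spacing invariant is violated.
        """
        p = self.params
        n_exit, err = _kernel.step_kernel(
            self.pos,
            self.speed,
            self.lane,
            self.active,
            self._veh_group,
            self._veh_dffs,
            self._veh_telem,
            self._p2p_entry,
            self.time,
            self.step_index,
            self.noise_seed,
            self.road.lanes,
            self.road.length,
            self.layout.mode,
            self._cam,
            self.layout.detection_range,
            self._p2p_lo,
            self._p2p_hi,
            self.road.speed_limit / KMH,
            p.max_accel,
            p.max_decel,
            p.reaction_time,
            p.sigma,
            p.vehicle_length,
            p.min_gap,
            p.dt,
        )
        if err != _kernel.ERR_NONE:
            raise CollisionError(
                f"vehicle overlap detected at t={self.time:.1f}s "
                f"(code {err}); state dump: n_active={int(self.active.sum())}"
            )
        self.n_exited += n_exit
        self.time += p.dt
        self.step_index += 1
        return n_exit

    @property
    def n_on_road(self) -> int:
        return int(self.active[: self.n_vehicles].sum())

    def vehicles_frame(self) -> pd.DataFrame:
        n = self.n_vehicles
        drv = self.veh_driver[:n]
        pop = population_frame(self.population)
        out = pd.DataFrame({"vehicle_id": np.arange(n), "driver_id": drv})
        return out.merge(pop, on="driver_id", how="left")


def run_simulation(
    scenario,
    road: RoadSpec | None = None,
    params: SimParams | None = None,
    pop_spec: PopulationSpec | None = None,
    layout: CameraLayout | None = None,
) -> SimulationResult:
    """Run one scenario-seed cell end to end and return its trajectories.

    ``scenario`` provides sec_type, telematics_pct, pct_b, pct_c, demand_vph
    and seed (see :class:`secsim.scenarios.ScenarioSpec`). All randomness —
    population sampling, arrival process, driver imperfection — derives from
    ``scenario.seed``, so a repeated call is bit-identical. The driver pool
    size is the expected vehicle count over the whole run, at least 200.
    Records are kept from the end of the warmup onwards.
    """
    road = road or RoadSpec()
    params = params or SimParams()
    if scenario.seed is None:
        raise ValueError("scenario has no seed; use expand_seeds or set one")
    seed = int(scenario.seed)
    total_time = params.warmup + params.duration
    if pop_spec is None:
        pop_spec = PopulationSpec(
            pct_b=scenario.pct_b,
            pct_c=scenario.pct_c,
            pct_telematics=scenario.telematics_pct,
            speed_limit=road.speed_limit,
        )
    n_pool = max(200, int(round(scenario.demand_vph * total_time / 3600.0)))
    pop_rng = np.random.default_rng(seed)
    population = sample_population(pop_spec, n_pool, pop_rng)
    layout = layout or CameraLayout.for_type(scenario.sec_type, road)

    sim = Simulation(road, layout, params, population, seed)
    n_steps = int(round(total_time / params.dt))
    rec_vid: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []
    rec_pos: list[np.ndarray] = []
    rec_v: list[np.ndarray] = []
    rec_lane: list[np.ndarray] = []
    for k in range(n_steps):
        sim.insert_vehicles(scenario.demand_vph)
        sim.step()
        t_now = (k + 1) * params.dt
        if t_now >= params.warmup:
            act = sim.active[: sim.n_vehicles]
            ids = np.flatnonzero(act)
            if ids.size:
                rec_vid.append(ids.astype(np.int64))
                rec_t.append(np.full(ids.size, t_now))
                rec_pos.append(sim.pos[ids].copy())
                rec_v.append(sim.speed[ids] * KMH)
                rec_lane.append(sim.lane[ids].copy())

    if rec_vid:
        records = pd.DataFrame(
            {
                "vehicle_id": np.concatenate(rec_vid),
                "time_s": np.concatenate(rec_t),
                "position_m": np.concatenate(rec_pos),
                "speed_kmh": np.concatenate(rec_v),
                "lane": np.concatenate(rec_lane),
            }
        )
    else:
        records = pd.DataFrame(
            columns=["vehicle_id", "time_s", "position_m", "speed_kmh", "lane"]
        )
    return SimulationResult(
        records=records,
        vehicles=sim.vehicles_frame(),
        n_inserted=sim.n_vehicles,
        n_exited=sim.n_exited,
        n_on_road_end=sim.n_on_road,
    )
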