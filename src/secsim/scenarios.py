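"""Scenario grids, seed expansion and reproducible batch execution.

The study design is a full factorial over five factors: camera layout
(FIX1/FIX2/FIX3/P2P), telematics installation among violators (0-10 %),
share of kangaroo drivers (10-50 % by 5), share of consistent speeders
(1-5 % by 1) and traffic demand (500-3500 VPH by 500) — 13,860 scenarios,
each replicated over independent random seeds (30 in the full design,
415,800 runs).

Replicate seeds are derived counter-style from a master seed and are shared
by every scenario: the r-th replicate of any two scenarios uses the same
seed, so contrasts between camera layouts are paired comparisons under
common random numbers (same driver population, same arrival stream).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import summarize_run
from .microsim import SEC_TYPES, RoadSpec, SimParams, run_simulation

__all__ = [
    "ScenarioSpec",
    "GridConfig",
    "enumerate_scenarios",
    "expand_seeds",
    "replicate_seeds",
    "enumerate_spillover_grid",
    "run_scenario",
    "run_batch",
    "RESULT_COLUMNS",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "scenario_id",
    "seed",
    "sec_type",
    "telematics_pct",
    "pct_B",
    "pct_C",
    "demand_vph",
    "rud_pct",
    "rud_A",
    "rud_B",
    "rud_C",
    "mean_speed_kmh",
    "distance_vkm",
    "time_vh",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factor grid, optionally bound to a seed."""

    sec_type: str
    telematics_pct: float
    pct_b: float
    pct_c: float
    demand_vph: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sec_type not in SEC_TYPES:
            raise ValueError(f"unknown sec_type {self.sec_type!r}")

    @property
    def scenario_id(self) -> str:
        return (
            f"{self.sec_type}-t{self.telematics_pct:g}-b{self.pct_b:g}"
            f"-c{self.pct_c:g}-d{self.demand_vph:g}"
        )

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=int(seed))


def _default_levels() -> dict[str, list]:
    return {
        "sec_type": list(SEC_TYPES),
        "telematics_pct": list(range(0, 11)),
        "pct_b": list(range(10, 55, 5)),
        "pct_c": list(range(1, 6)),
        "demand_vph": list(range(500, 4000, 500)),
    }


@dataclass(frozen=True)
class GridConfig:
    """Factor levels of the scenario grid (defaults: the full study grid)."""

    sec_type: Sequence[str] = field(default_factory=lambda: list(SEC_TYPES))
    telematics_pct: Sequence[float] = field(
        default_factory=lambda: list(range(0, 11))
    )
    pct_b: Sequence[float] = field(default_factory=lambda: list(range(10, 55, 5)))
    pct_c: Sequence[float] = field(default_factory=lambda: list(range(1, 6)))
    demand_vph: Sequence[float] = field(
        default_factory=lambda: list(range(500, 4000, 500))
    )

    def factors(self) -> dict[str, Sequence]:
        return {
            "sec_type": self.sec_type,
            "telematics_pct": self.telematics_pct,
            "pct_b": self.pct_b,
            "pct_c": self.pct_c,
            "demand_vph": self.demand_vph,
        }


def enumerate_scenarios(grid: GridConfig | None = None) -> list[ScenarioSpec]:
    """Full Cartesian product of the grid factors, lexicographic order."""
    grid = grid or GridConfig()
    factors = grid.factors()
    for name, levels in factors.items():
        if len(levels) == 0:
            raise ValueError(f"factor {name!r} has no levels")
    return [
        ScenarioSpec(s, t, b, c, d)
        for s, t, b, c, d in product(*factors.values())
    ]


def replicate_seeds(n_seeds: int, master_seed: int = 0) -> list[int]:
    """Deterministic replicate seeds, counter-based from the master seed.

    Seed r depends only on (master_seed, r), so extending the scenario list
    never perturbs existing seeds, and every scenario shares the same
    replicate seeds (common random numbers across layouts).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    return [
        int(np.random.SeedSequence([int(master_seed), r]).generate_state(1)[0] % 2**31)
        for r in range(n_seeds)
    ]


def expand_seeds(
    scenarios: Iterable[ScenarioSpec], n_seeds: int = 30, master_seed: int = 0
) -> list[ScenarioSpec]:
    """Replicate each scenario with ``n_seeds`` derived seeds."""
    seeds = replicate_seeds(n_seeds, master_seed)
    return [s.with_seed(seed) for s in scenarios for seed in seeds]


def enumerate_spillover_grid() -> list[ScenarioSpec]:
    """High-telematics grid probing for spill-over effects.

    Telematics 10-90 % in steps of 10, demand above 1500 VPH, at the average
    community composition (30 % B, 3 % C), for all four camera layouts.
    """
    return [
        ScenarioSpec(s, t, 30.0, 3.0, d)
        for s in SEC_TYPES
        for t in range(10, 100, 10)
        for d in (2000, 2500, 3000, 3500)
    ]


def run_scenario(
    spec: ScenarioSpec,
    road: RoadSpec | None = None,
    params: SimParams | None = None,
    threshold: float = 90.0,
    **sim_kwargs,
) -> dict:
    """Simulate one seeded scenario and reduce it to a results row."""
    params = params or SimParams()
    result = run_simulation(spec, road=road, params=params, **sim_kwargs)
    summary = summarize_run(result, spec, threshold=threshold, dt=params.dt)
    row = {
        "scenario_id": spec.scenario_id,
        "seed": int(spec.seed),
        "sec_type": spec.sec_type,
        "telematics_pct": spec.telematics_pct,
        "pct_B": spec.pct_b,
        "pct_C": spec.pct_c,
        "demand_vph": spec.demand_vph,
        "rud_pct": summary.rud_pct,
        "rud_A": summary.rud_by_group.get("A", np.nan),
        "rud_B": summary.rud_by_group.get("B", np.nan),
        "rud_C": summary.rud_by_group.get("C", np.nan),
        "mean_speed_kmh": summary.space_mean_speed,
        "distance_vkm": summary.total_distance,
        "time_vh": summary.total_time,
    }
    return row


def run_batch(
    specs: Sequence[ScenarioSpec],
    out_path,
    road: RoadSpec | None = None,
    params: SimParams | None = None,
    n_jobs: int = 1,
    resume: bool = True,
    log_every: int = 50,
) -> pd.DataFrame:
    """Execute a batch of seeded scenarios, appending rows to ``out_path``.

    Resumable: (scenario_id, seed) pairs already present in the output CSV
    are skipped, so an interrupted batch re-run converges to the same table
    as an uninterrupted one. Each row is flushed as soon as it is computed.
    Per-scenario failures are logged and collected; if any occurred a
    RuntimeError is raised after the batch finishes.
    """
    out_path = str(out_path)
    done: set[tuple[str, int]] = set()
    if resume and os.path.exists(out_path):
        prev = pd.read_csv(out_path)
        done = set(zip(prev["scenario_id"], prev["seed"].astype(int)))

    todo = [s for s in specs if (s.scenario_id, int(s.seed)) not in done]
    log.info("batch: %d specs, %d already done", len(specs), len(specs) - len(todo))

    failures: list[tuple[ScenarioSpec, Exception]] = []

    def _one(spec):
        try:
            return run_scenario(spec, road=road, params=params), None
        except Exception as exc:  # noqa: BLE001 - batch must continue
            return None, exc

    rows: list[dict] = []
    if n_jobs > 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs, return_as="generator")(
            delayed(_one)(s) for s in todo
        )
    else:
        results = map(_one, todo)
    for k, (spec, (row, exc)) in enumerate(zip(todo, results)):
        if exc is not None:
            log.error("scenario %s seed %s failed: %s", spec.scenario_id, spec.seed, exc)
            failures.append((spec, exc))
            continue
        rows.append(row)
        _append_row(out_path, row)
        if (k + 1) % log_every == 0:
            log.info("batch progress: %d/%d", k + 1, len(todo))

    if failures:
        raise RuntimeError(
            f"{len(failures)} scenario runs failed; first: "
            f"{failures[0][0].scenario_id} seed {failures[0][0].seed}: {failures[0][1]}"
        )
    return pd.read_csv(out_path) if os.path.exists(out_path) else pd.DataFrame(rows)


def _append_row(path: str, row: dict) -> None:
    new = not os.path.exists(path)
    pd.DataFrame([row], columns=RESULT_COLUMNS).to_csv(
        path, mode="a", header=new, index=False
    )
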