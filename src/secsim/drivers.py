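"""Synthetic driver populations.

Drivers fall into three behavioural classes with respect to a posted speed
limit (default 90 km/h):

* **A — law-abiding**: desired free-flow speed (DFFS) at or below the limit;
  they never speed, with or without enforcement.
* **B — kangaroo drivers**: DFFS above the limit, but they brake to the limit
  inside camera detection zones and re-accelerate afterwards (the distance
  halo effect).
* **C — consistent speeders**: DFFS above the limit, ignore cameras entirely.

DFFS is each driver's chosen cruising speed under free-flow conditions
(operationally, a high percentile of observed free speeds). Telematics
devices — in-vehicle GPS enforcement that forces full limit compliance — are
installed on a random subset of the violator pool (groups B and C only).

Group DFFS distributions are truncated normals whose truncation intervals
encode the class definitions: group A is truncated at the limit from above,
groups B and C from below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "DffsParams",
    "DriverProfile",
    "PopulationSpec",
    "sample_dffs",
    "sample_population",
    "population_frame",
    "write_population",
    "read_population",
]

GROUPS = ("A", "B", "C")

#: integer codes used in the simulation kernel
GROUP_CODES = {"A": 0, "B": 1, "C": 2}


@dataclass(frozen=True)
class DffsParams:
    """Truncated-normal DFFS distribution for one driver group (km/h)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")

    def distribution(self) -> stats.rv_continuous:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def truncated_mean(self) -> float:
        return float(self.distribution().mean())


def default_dffs_params(speed_limit: float = 90.0) -> dict[str, DffsParams]:
    """Default per-group DFFS distributions around a 90 km/h limit.

    A sits just under the limit, B above it, C fastest — reproducing the
    qualitative separation the behavioural classes are defined by.
    """
    return {
        "A": DffsParams(mean=84.0, sd=4.0, lower=0.0, upper=speed_limit),
        "B": DffsParams(mean=100.0, sd=6.0, lower=speed_limit, upper=140.0),
        "C": DffsParams(mean=110.0, sd=8.0, lower=speed_limit, upper=160.0),
    }


@dataclass(frozen=True)
class DriverProfile:
    driver_id: int
    group: str
    dffs: float  # km/h
    telematics: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 < self.dffs < 200.0:
            raise ValueError(f"dffs out of sane range: {self.dffs}")
        if self.telematics and self.group == "A":
            raise ValueError("telematics devices are installed on violators (B/C) only")


@dataclass(frozen=True)
class PopulationSpec:
    """Composition of a driver population.

    Percentages are of the whole population for ``pct_b``/``pct_c`` and of the
    violator pool (B ∪ C) for ``pct_telematics``.
    """

    pct_b: float
    pct_c: float
    pct_telematics: float = 0.0
    speed_limit: float = 90.0
    dffs_params: dict[str, DffsParams] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("pct_b", "pct_c", "pct_telematics"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.pct_b + self.pct_c > 100.0:
            raise ValueError(
                f"pct_b + pct_c = {self.pct_b + self.pct_c} exceeds 100"
            )
        if self.dffs_params is None:
            object.__setattr__(self, "dffs_params", default_dffs_params(self.speed_limit))

    @property
    def pct_a(self) -> float:
        return 100.0 - self.pct_b - self.pct_c

    def with_telematics(self, pct: float) -> "PopulationSpec":
        return replace(self, pct_telematics=pct)


def sample_dffs(
    group: str,
    spec: PopulationSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw desired free-flow speeds (km/h) for one group.

    Values respect the group invariant by construction: A ≤ limit, B/C > limit
    (the truncation bound for B/C is nudged strictly above the limit).
    """
    try:
        params = spec.dffs_params[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}") from None
    lower = params.lower
    if group in ("B", "C"):
        lower = np.nextafter(max(lower, spec.speed_limit), np.inf)
    dist = DffsParams(params.mean, params.sd, lower, params.upper).distribution()
    out = dist.rvs(size=1 if size is None else size, random_state=rng)
    return float(out[0]) if size is None else np.asarray(out, dtype=float)


def largest_remainder_counts(n: int, shares_pct: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` into integer counts matching percentage shares.

    Largest-remainder (Hamilton) rounding; remainder ties broken in the fixed
    key order of ``shares_pct`` so a scenario's nominal composition is exact
    and deterministic.
    """
    keys = list(shares_pct)
    quotas = np.array([shares_pct[k] / 100.0 * n for k in keys])
    counts = np.floor(quotas).astype(int)
    short = n - int(counts.sum())
    if short:
        remainders = quotas - counts
        # stable sort keeps key order on ties
        for i in np.argsort(-remainders, kind="stable")[:short]:
            counts[i] += 1
    return dict(zip(keys, (int(c) for c in counts)))


def sample_population(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> list[DriverProfile]:
    """Sample ``n`` drivers with deterministic group counts.

    Group counts are the largest-remainder rounded shares of ``n`` (not a
    multinomial draw), DFFS values are drawn per group, and telematics flags
    are assigned to a uniform without-replacement subset of the violator pool
    of size round(pct_telematics/100 · |B ∪ C|).
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    counts = largest_remainder_counts(
        n, {"A": spec.pct_a, "B": spec.pct_b, "C": spec.pct_c}
    )
    groups: list[str] = []
    dffs: list[np.ndarray] = []
    for g in GROUPS:
        if counts[g]:
            groups.extend([g] * counts[g])
            dffs.append(np.atleast_1d(sample_dffs(g, spec, rng, size=counts[g])))
    dffs_all = np.concatenate(dffs) if dffs else np.empty(0)

    telem = np.zeros(n, dtype=bool)
    violators = np.flatnonzero([g != "A" for g in groups])
    if violators.size:
        k = int(np.floor(spec.pct_telematics / 100.0 * violators.size + 0.5))
        k = min(k, violators.size)
        if k:
            telem[rng.choice(violators, size=k, replace=False)] = True

    return [
        DriverProfile(i, groups[i], float(dffs_all[i]), bool(telem[i]))
        for i in range(n)
    ]


def population_frame(population: list[DriverProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "driver_id": [d.driver_id for d in population],
            "group": [d.group for d in population],
            "dffs_kmh": [d.dffs for d in population],
            "telematics": [int(d.telematics) for d in population],
        }
    )


def write_population(population: list[DriverProfile], path) -> None:
    # 17 significant digits so DFFS values round-trip exactly
    population_frame(population).to_csv(path, index=False, float_format="%.17g")


def read_population(path) -> list[DriverProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        DriverProfile(int(r.driver_id), str(r.group), float(r.dffs_kmh), bool(r.telematics))
        for r in df.itertuples(index=False)
    ]
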