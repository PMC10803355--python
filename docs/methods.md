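# Methods

## The question and the model

Fixed speed-enforcement cameras (SECs) measure spot speed at a point;
average (point-to-point, P2P) cameras measure the mean speed over a road
section. Their population-level effect depends on how drivers behave
*between* cameras, not just at them. `secsim` probes this with an
agent-based microsimulation of a single uninterrupted highway segment
(6 km, 3 lanes, 90 km/h limit by default) populated by three behavioural
classes of driver:

* **Group A (law-abiding)** — desired free-flow speed (DFFS) at or below
  the limit; enforcement is irrelevant to them.
* **Group B (kangaroo drivers)** — DFFS above the limit; they brake to the
  limit inside camera detection zones (150 m upstream of each fixed camera,
  or the whole P2P section) and re-accelerate afterwards, producing the
  V-shaped speed profile known as the distance-halo effect.
* **Group C (consistent speeders)** — DFFS above the limit, ignore cameras.

Telematics enforcement (in-vehicle GPS monitoring) is modelled as forcing
full limit compliance for the equipped subset of violators (B ∪ C).

The headline outcome is the **ratio of unsafe driving (RUD)**: the percent
of total vehicle-distance travelled strictly above the 90 km/h threshold.
Scenario-level mean speeds are translated into crash relative risk with the
Power Model, RR = (v₂/v₁)ⁿ with n = 3, the exponent associated with fatal
and serious injury crashes.

## Driver populations

Group shares are exact by construction: a population of n drivers is split
by largest-remainder (Hamilton) rounding of the nominal percentages, so a
scenario's composition carries no sampling noise. DFFS values are drawn
from truncated normal distributions whose truncation encodes the class
definitions (A truncated above at the limit; B and C strictly above it):

| group | mean (km/h) | sd | support |
|-------|------------|----|---------|
| A | 84 | 4 | (0, 90] |
| B | 100 | 6 | (90, 140] |
| C | 110 | 8 | (90, 160] |

These parameters are configurable; the defaults reproduce the qualitative
ordering median(A) < median(B) < median(C) and the >limit violation
structure the classes are defined by, which is all the downstream analysis
relies on. Telematics devices are assigned by sampling without replacement
from the violator pool, so the realized installation count is exactly
round(p·|B∪C|).

## Car following, lane changing, insertion

Vehicles follow the Krauss safe-velocity model (the default in mainstream
microsimulators) at a 1 s timestep: the candidate speed is
min(behavioural target, v + a·dt, v_safe), where
v_safe = −bτ + sqrt((bτ)² + v_lead² + 2·b·gap) with acceleration a =
2.6 m/s², deceleration b = 4.5 m/s², reaction time τ = 1 s, vehicle length
5 m, minimum gap 2.5 m. A stochastic imperfection σ·a·dt·U (σ = 0.5,
U ~ Uniform(0,1)) is subtracted, and the result is floored at v − b·dt:
deceleration is physically bounded, and collision freedom follows from the
invariant that every vehicle's speed never exceeds its safe speed with
respect to its leader. Lane changes and insertions are only admitted when
they preserve that invariant, which is why the simulator can assert a hard
spacing invariant (follower + length + min-gap ≤ leader) after every step
and abort on violation rather than tolerate overlaps.

Lane changing is a minimal overtaking rule: a vehicle held below 80 % of
its target speed moves one lane left when the target lane offers a strictly
better safe speed and its new follower remains safe; an unconstrained
vehicle returns right symmetrically. Arrivals are Poisson with the
scenario's total demand (vehicles/hour) across all lanes; each arrival
draws the next driver from the population (cycling with reshuffle), enters
at the lane with the largest entry headway at min(DFFS, limit) capped by
the safe speed, and is queued while the entry gap is insufficient.

The imperfection draw is **counter-based**: U is a hash of
(seed, vehicle id, timestep) rather than a draw from a sequential stream.
Together with seed-keyed population sampling and arrivals, this makes runs
with the same seed but different camera layouts share *every* random input
— identical drivers, arrival times and dawdling — so layout contrasts are
paired comparisons under common random numbers. This matters because the
incremental effect of a second or third fixed camera on the 6 km mean
speed is of order 0.01–0.05 km/h, far below the between-seed standard
deviation of an unpaired comparison.

For P2P sections two group-B compliance modes exist: the default `cap`
(hold the limit across the whole section, guaranteeing a compliant section
average) and `compensate` (drive at DFFS through the first half, then slow
to 2·limit − DFFS so the section's time-mean speed still meets the limit —
a simple model of drivers who game average enforcement).

## Run structure and metrics

Each scenario-seed cell runs 600 s of warmup plus 3600 s of recorded
simulation; every vehicle emits one record per second (position, speed,
lane). The driver pool size is the expected vehicle count over the run,
at least 200. Distance increments are speed × dt, so RUD reduces to a
speed-weighted share of records and the space-mean speed (total distance /
total time — the quantity the Power Model expects) to the arithmetic mean
over vehicle-seconds. Group-level RUD is the same computation restricted
to one class's vehicles; groups with no recorded distance are reported as
absent rather than zero. Group RUDs are reported in percent throughout.

## Scenario grid and inference

The full factorial design crosses camera layout (4) × telematics 0–10 %
(11) × %B ∈ {10,…,50} (9) × %C ∈ {1,…,5} (5) × demand ∈ {500,…,3500} VPH
(7) = 13,860 scenarios × 30 shared replicate seeds = 415,800 runs. Seeds
are derived counter-style from a master seed, so extending the grid never
changes existing seeds. A separate spill-over grid raises telematics to
10–90 % (step 10) at the average composition (30 % B, 3 % C) for demands
above 1500 VPH.

Per-run RUD is regressed (OLS, classical standard errors, α = 0.05) on
layout indicators (FIX1 reference), demand per 1000 VPH, %B, %C and
telematics %. The design matrix is checked for rank and the offending
columns named on failure; p-values below 0.001 are printed as "<0.001".

For the crash-risk table, scenarios are classified into implementation
cells: community behaviour (law-abiding: B 10–20, C 1–2; average: B 20–30,
C 3; law-avoiding: B 35–50, C 3; law-carefree: B 20–30, C 4–5; boundary
ties resolve in that priority order), traffic (low 500–1500, moderate
2500–3500; 2000 VPH falls between the bins and is excluded), and
telematics (none 0–1 %, enforcement 8–10 %). Within a cell, distance and
time are pooled across all runs of a layout *before* dividing — the Power
Model wants one traffic-level speed, not a mean of per-run means — and
each layout is compared against FIX1.

Spill-over is assessed by fitting a line to mean RUD vs telematics % per
(layout × demand); a high R² (the tests require ≥ 0.95) indicates the
absence of nonlinear spill-over.

## Problem sizes used by the tests and the acceptance script

The shipped test suite and `scripts/acceptance.py` run the complete factor
structure at reduced replication: eight community compositions × four
demand levels × two telematics levels × four layouts (256 scenarios), with
three seeds in the tests and two in the acceptance script, plus the
144-scenario spill-over grid at one seed. Every implementation cell then
pools eight scenario runs per layout per seed, which (with common random
numbers) resolves the small fixed-camera contrasts. The safety-invariant
sweep uses 100 random grid cells at shortened (300 s + 60 s) runs.

## Numerical choices and edge cases

* Group counts: largest-remainder rounding, remainder ties broken in fixed
  A, B, C order. Telematics count: round-half-up of p·|B∪C|.
* Unsafe is strictly above the threshold (a record at exactly 90 km/h is
  safe); RUD with an empty or zero-distance record set is a hard error.
* Vehicles are removed once their position exceeds the segment length; the
  overshooting sample is not recorded, so trajectories never contain
  positions beyond the segment.
* Records begin at the first step at or after the warmup boundary.
* Spacing tolerance 1e-6 m in the post-step invariant check; lane-change
  hysteresis 0.1 m/s to prevent flapping.
* Population CSVs are written with 17 significant digits and re-read with
  round-trip float parsing, so populations survive a disk round-trip
  bit-exactly.

## What the synthetic generator does and does not emulate

The generator reproduces the *structure* the analysis assumes — three
classes with exact shares, DFFS distributions separated around the limit,
random telematics assignment among violators — but not any particular
empirical DFFS shape estimated from real GPS traces, nor driver covariates
(age, vehicle type), nor day-to-day behavioural drift (the time-halo
effect). Passing tests therefore demonstrate that the pipeline recovers
the qualitative enforcement effects implied by the behavioural model
(directions, orderings, linearity), not that any specific real road would
show coefficients of the same magnitude.

## Known limitations

* The Krauss model with a 1 s step is a coarse kinematic model; queue
  discharge and capacity are approximate, and demand above ~3500 VPH on
  three lanes saturates the entry.
* Crash risk is computed analytically from mean speeds; crashes are not
  simulated events, and the Power Model's own validity caveats apply.
* Single segment, homogeneous vehicles, no ramps or intersections.
* The regression treats scenario-seed runs as independent observations
  (classical OLS), mirroring the plain linear-regression analysis the
  pipeline is designed around; no clustering by scenario.
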