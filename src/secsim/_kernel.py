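"""Numba kernels for the car-following microsimulation.

One discrete-time step of a Krauss-type safe-velocity model on a multi-lane
segment, plus the per-driver behavioural target-speed rule around speed
enforcement cameras. All speeds here are m/s, positions metres, lane 0 is the
rightmost lane.

The kernels are plain callables (njit functions) so unit tests exercise the
same code the batch runner does. Randomness inside the kernel (driver
imperfection draws) uses numba's global np.random state; seed it with
:func:`seed_kernel` before a run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# sec_type behavioural modes
MODE_FIXED = 0
MODE_P2P_CAP = 1
MODE_P2P_COMPENSATE = 2

ERR_NONE = 0
ERR_OVERLAP_BEFORE = 1
ERR_OVERLAP_AFTER = 2

#: hysteresis (m/s) a left lane change must gain before it is taken
_LC_GAIN = 0.1


@njit(cache=True)
def counter_uniform(seed, vehicle_id, step):
    """Counter-based U(0,1) draw keyed by (seed, vehicle, step).

    Splitmix64 finalizer over a combined key. Using a counter-based stream —
    rather than one sequential stream — makes the imperfection draw of a
    given vehicle at a given time identical across camera layouts run with
    the same seed, so layout contrasts are paired comparisons under common
    random numbers.
    """
    z = (
        np.uint64(seed)
        + np.uint64(vehicle_id) * np.uint64(0x9E3779B97F4A7C15)
        + np.uint64(step) * np.uint64(0xBF58476D1CE4E5B9)
    )
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return float(z) / 18446744073709551616.0


@njit(cache=True)
def safe_speed_ms(v_leader, gap, decel, tau):
    """Krauss safe velocity: fastest speed that still allows stopping behind
    a leader which brakes at ``decel``, given net gap ``gap`` (m)."""
    bt = decel * tau
    return -bt + np.sqrt(bt * bt + v_leader * v_leader + 2.0 * decel * gap)


@njit(cache=True)
def target_speed_ms(
    group,
    dffs,
    telem,
    pos,
    mode,
    cam_pos,
    det_range,
    p2p_lo,
    p2p_hi,
    limit,
):
    """Behavioural desired speed of one driver at one position (m/s).

    Group A drivers want their DFFS (below the limit by construction);
    telematics-equipped violators are capped at the limit everywhere; kangaroo
    (B) drivers drop to the limit inside fixed-camera detection zones or the
    point-to-point section; consistent speeders (C) ignore cameras.
    """
    if group == 0:
        return dffs
    if telem:
        return min(dffs, limit)
    if group == 2:
        return dffs
    # group B
    if mode == MODE_FIXED:
        for k in range(cam_pos.shape[0]):
            c = cam_pos[k]
            if c - det_range <= pos <= c:
                return limit
        return dffs
    if pos < p2p_lo or pos > p2p_hi:
        return dffs
    if mode == MODE_P2P_CAP:
        return min(dffs, limit)
    # compensate: speed through the first half of the section, then slow so the
    # section's time-mean speed still comes out at or below the limit
    if pos < 0.5 * (p2p_lo + p2p_hi):
        return dffs
    slow = 2.0 * limit - dffs
    if slow < 1.0:
        slow = 1.0
    return min(dffs, slow)


@njit(cache=True)
def _neighbors_in_lane(
    i, p_i, tlane, bucket, starts, p, cur_ln, changed, n_changed
):
    """Nearest leader/follower of a probe position in ``tlane``.

    Uses the start-of-step per-lane buckets (sorted by position) corrected for
    vehicles that already switched lanes during this sweep. Returns local
    indices, -1 when absent.
    """
    lo = starts[tlane]
    hi = starts[tlane + 1]
    # binary search: first bucket slot with position > p_i
    a, b = lo, hi
    while a < b:
        m = (a + b) // 2
        if p[bucket[m]] <= p_i:
            a = m + 1
        else:
            b = m
    leader = -1
    j = a
    while j < hi:
        k = bucket[j]
        if k != i and cur_ln[k] == tlane:
            leader = k
            break
        j += 1
    follower = -1
    j = a - 1
    while j >= lo:
        k = bucket[j]
        if k != i and cur_ln[k] == tlane:
            follower = k
            break
        j -= 1
    for c in range(n_changed):
        k = changed[c]
        if k == i or cur_ln[k] != tlane:
            continue
        if p[k] > p_i:
            if leader == -1 or p[k] < p[leader]:
                leader = k
        else:
            if follower == -1 or p[k] > p[follower]:
                follower = k
    return leader, follower


@njit(cache=True)
def step_kernel(
    pos,
    speed,
    lane,
    active,
    drv_group,
    drv_dffs_ms,
    drv_telem,
    p2p_entry,
    t,
    step_index,
    noise_seed,
    n_lanes,
    length,
    mode,
    cam_pos,
    det_range,
    p2p_lo,
    p2p_hi,
    limit_ms,
    accel,
    decel,
    tau,
    sigma,
    veh_len,
    min_gap,
    dt,
):
    """Advance every active vehicle by one timestep (parallel update).

    Mutates pos/speed/lane/active/p2p_entry in place. Returns
    (n_exited, error_code); a nonzero error means the spacing invariant
    (follower + vehicle_length + min_gap <= leader) was violated.
    """
    idx = np.where(active)[0]
    n = idx.shape[0]
    if n == 0:
        return 0, ERR_NONE

    p = pos[idx].copy()
    v = speed[idx].copy()
    ln = lane[idx].copy()

    order = np.argsort(p)

    # per-lane buckets, ascending position
    counts = np.zeros(n_lanes + 1, dtype=np.int64)
    for k in range(n):
        counts[ln[k] + 1] += 1
    starts = np.cumsum(counts)
    fill = starts[:-1].copy()
    bucket = np.empty(n, dtype=np.int64)
    for kk in range(n):
        i = order[kk]
        bucket[fill[ln[i]]] = i
        fill[ln[i]] += 1

    # start-of-step same-lane leaders
    leader0 = np.full(n, -1, dtype=np.int64)
    for l in range(n_lanes):
        for j in range(starts[l], starts[l + 1] - 1):
            leader0[bucket[j]] = bucket[j + 1]

    # behavioural targets and currently attainable speeds
    v_des = np.empty(n)
    v_pos0 = np.empty(n)
    err = ERR_NONE
    for k in range(n):
        gi = idx[k]
        if mode != MODE_FIXED:
            if p2p_lo <= p[k] <= p2p_hi and p2p_entry[gi] < 0.0:
                p2p_entry[gi] = t
        v_des[k] = target_speed_ms(
            drv_group[gi],
            drv_dffs_ms[gi],
            drv_telem[gi],
            p[k],
            mode,
            cam_pos,
            det_range,
            p2p_lo,
            p2p_hi,
            limit_ms,
        )
        vt = min(v_des[k], v[k] + accel * dt)
        j = leader0[k]
        if j >= 0:
            gap = p[j] - p[k] - veh_len - min_gap
            if gap < -1e-6:
                err = ERR_OVERLAP_BEFORE
                gap = 0.0
            elif gap < 0.0:
                gap = 0.0
            vs = safe_speed_ms(v[j], gap, decel, tau)
            if vs < vt:
                vt = vs
        v_pos0[k] = vt

    # lane-change sweep, front to back; minimal overtaking rule
    cur_ln = ln.copy()
    changed = np.empty(n, dtype=np.int64)
    n_changed = 0
    for kk in range(n - 1, -1, -1):
        i = order[kk]
        blocked = v_pos0[i] < 0.8 * v_des[i]
        tlane = -1
        if blocked and cur_ln[i] + 1 < n_lanes:
            tlane = cur_ln[i] + 1
        elif (not blocked) and cur_ln[i] > 0:
            tlane = cur_ln[i] - 1
        if tlane < 0:
            continue
        nl, nf = _neighbors_in_lane(
            i, p[i], tlane, bucket, starts, p, cur_ln, changed, n_changed
        )
        ok = True
        vs_new = 1.0e12
        if nl >= 0:
            gap_l = p[nl] - p[i] - veh_len - min_gap
            if gap_l < 0.0:
                ok = False
            else:
                vs_new = safe_speed_ms(v[nl], gap_l, decel, tau)
                # keep the inductive safety invariant: never change into a
                # lane where the current speed already exceeds the safe speed
                if vs_new < v[i]:
                    ok = False
        if ok and nf >= 0:
            gap_f = p[i] - p[nf] - veh_len - min_gap
            if gap_f < 0.0 or safe_speed_ms(v[i], gap_f, decel, tau) < v[nf]:
                ok = False
        if not ok:
            continue
        unconstrained = min(v_des[i], v[i] + accel * dt)
        if blocked:
            if min(unconstrained, vs_new) <= v_pos0[i] + _LC_GAIN:
                continue
        else:
            if vs_new < unconstrained:
                continue
        cur_ln[i] = tlane
        changed[n_changed] = i
        n_changed += 1

    # final same-lane leaders after lane changes
    leader_fin = np.full(n, -1, dtype=np.int64)
    last_seen = np.full(n_lanes, -1, dtype=np.int64)
    for kk in range(n - 1, -1, -1):
        i = order[kk]
        leader_fin[i] = last_seen[cur_ln[i]]
        last_seen[cur_ln[i]] = i

    # parallel speed/position update with stochastic imperfection
    v_new = np.empty(n)
    for k in range(n):
        vt = min(v_des[k], v[k] + accel * dt)
        j = leader_fin[k]
        if j >= 0:
            gap = p[j] - p[k] - veh_len - min_gap
            if gap < -1e-6:
                err = ERR_OVERLAP_BEFORE
                gap = 0.0
            elif gap < 0.0:
                gap = 0.0
            vs = safe_speed_ms(v[j], gap, decel, tau)
            if vs < vt:
                vt = vs
        vn = vt
        if sigma > 0.0:
            u = counter_uniform(noise_seed, idx[k], step_index)
            vn = vt - sigma * accel * dt * u
        # deceleration is physically bounded; collision freedom then relies on
        # every pair satisfying v <= v_safe(leader), which lane changes and
        # insertions preserve by construction
        floor = v[k] - decel * dt
        if vn < floor:
            vn = floor
        if vn < 0.0:
            vn = 0.0
        v_new[k] = vn
    p_new = p + v_new * dt

    # spacing invariant after the parallel move
    prev = np.full(n_lanes, -1, dtype=np.int64)
    for kk in range(n):
        i = order[kk]
        l = cur_ln[i]
        q = prev[l]
        if q >= 0 and p_new[i] - p_new[q] - veh_len - min_gap < -1e-6:
            err = ERR_OVERLAP_AFTER
        prev[l] = i

    # scatter back, handle exits
    n_exit = 0
    for k in range(n):
        gi = idx[k]
        if p_new[k] > length:
            active[gi] = False
            n_exit += 1
        pos[gi] = p_new[k]
        speed[gi] = v_new[k]
        lane[gi] = cur_ln[k]
    return n_exit, err
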