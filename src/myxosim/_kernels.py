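"""Compiled (numba) fused update loop.

One call advances the whole world by ``n_steps`` integration steps in
working units (pN / μm / min). The math is the exact composition of the
reference operations in :mod:`mechanics`, :mod:`behavior` and
:mod:`slime`; an equivalence test drives both paths over identical
worlds. The slime field decays lazily here (per-element timestamps,
materialized on read), which is numerically equivalent to the
reference's eager per-step exponential decay.

Parameter packing (see ``pack_params`` in :mod:`myxosim.engine`):

``P`` (float64): 0 L, 1 l0, 2 W_c, 3 k_l, 4 k_b, 5 F_p, 6 c, 7 k_a,
8 F_a_max, 9 k_ev, 10 τ_r, 11 τ_t, 12 turn_duration, 13 turn_angle,
14 ε_s, 15 S_r, 16 k_d, 17 S_thr, 18 S0_ref, 19 accept_frac, 20 dt,
21 slime element width, 22 sense radius, 23 lateral-adhesion peak force,
24 d_thr, 25 head transverse drag factor.

``IFLAGS`` (int64): 0 reversals, 1 turns, 2 slime, 3 lateral adhesion,
4 n_sectors, 5 sense stride, 6 slime grid size, 7 contact grid size.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-12
_U32 = np.uint64(0xFFFFFFFF)
# half-neighborhood offsets for the broad-phase cell sweep
_OFF_I = np.array([0, 1, 1, 0, -1], dtype=np.int64)
_OFF_J = np.array([0, 0, 1, 1, 1], dtype=np.int64)


@njit(cache=True, inline="always")
def _mi(x: float, L: float) -> float:
    return x - L * round(x / L)


@njit(cache=True)
def _tie_u(agent_id: int, gstep: int) -> float:
    h = (np.uint64(agent_id + 1) * np.uint64(2654435761)
         + np.uint64(gstep) * np.uint64(2246822519)) & _U32
    h ^= h >> np.uint64(16)
    h = (h * np.uint64(2654435761)) & _U32
    h ^= h >> np.uint64(13)
    return np.float64(h) / 4294967296.0


@njit(cache=True, inline="always")
def _seg_dist(p0x, p0y, p1x, p1y, q0x, q0y, q1x, q1y):
    """Closest distance between two 2-D segments.

    Returns (dist, s, t, nx, ny); n is the unit vector from the P-side
    closest point to the Q-side closest point.
    """
    d1x = p1x - p0x
    d1y = p1y - p0y
    d2x = q1x - q0x
    d2y = q1y - q0y
    rx = p0x - q0x
    ry = p0y - q0y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    if a <= 1e-18 and e <= 1e-18:
        s = 0.0
        t = 0.0
    elif a <= 1e-18:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = d1x * rx + d1y * ry
        if e <= 1e-18:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = d1x * d2x + d1y * d2y
            denom = a * e - b * b
            if denom > 1e-18:
                s = min(1.0, max(0.0, (b * f - c * e) / denom))
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    cpx = p0x + s * d1x
    cpy = p0y + s * d1y
    cqx = q0x + t * d2x
    cqy = q0y + t * d2y
    dx = cqx - cpx
    dy = cqy - cpy
    dist = math.sqrt(dx * dx + dy * dy)
    if dist > 1e-12:
        nx = dx / dist
        ny = dy / dist
    else:
        if a > 1e-18:
            axx, axy = d1x, d1y
        else:
            axx, axy = d2x, d2y
        nrm = math.sqrt(axx * axx + axy * axy)
        if nrm > 1e-12:
            nx = -axy / nrm
            ny = axx / nrm
        else:
            nx = 1.0
            ny = 0.0
    return dist, s, t, nx, ny


@njit(cache=True)
def _slime_read(slv, slt, gi, gj, te, kd, sthr):
    """Lazily decayed wet value of one element (0.0 if dry)."""
    v = slv[gi, gj]
    if v <= 0.0:
        return 0.0
    ve = v * math.exp(-kd * (te - slt[gi, gj]))
    if ve < sthr:
        return 0.0
    return ve


@njit(cache=True)
def _sense(slv, slt, te, hx, hy, ehx, ehy, kd, sthr, slw, G, R,
           n_sectors, accfrac, agent_id, gstep):
    """Sector search of the forward semicircle. Returns
    (found, e_s_x, e_s_y, S_local)."""
    hi = int(math.floor(hx / slw))
    hj = int(math.floor(hy / slw))
    span = int(math.ceil(R / slw)) + 1
    sums = np.zeros(n_sectors)
    maxs = np.zeros(n_sectors)
    half_pi = 0.5 * math.pi
    sector_w = math.pi / n_sectors
    for di in range(-span, span + 1):
        for dj in range(-span, span + 1):
            if di == 0 and dj == 0:
                continue
            cx = (hi + di + 0.5) * slw - hx
            cy = (hj + dj + 0.5) * slw - hy
            if cx * cx + cy * cy > R * R:
                continue
            dot = cx * ehx + cy * ehy
            if dot <= 0.0:
                continue
            gi = (hi + di) % G
            gj = (hj + dj) % G
            S = _slime_read(slv, slt, gi, gj, te, kd, sthr)
            if S <= 0.0:
                continue
            cross = ehx * cy - ehy * cx
            ang = math.atan2(cross, dot)
            b = int((ang + half_pi) / sector_w)
            if b < 0:
                b = 0
            elif b > n_sectors - 1:
                b = n_sectors - 1
            sums[b] += S
            if S > maxs[b]:
                maxs[b] = S
    s_max = 0.0
    for b in range(n_sectors):
        if sums[b] > s_max:
            s_max = sums[b]
    if s_max <= 0.0:
        return False, 0.0, 0.0, 0.0
    thresh = accfrac * s_max - 1e-12
    min_abs = 1e30
    for b in range(n_sectors):
        if sums[b] >= thresh:
            ca = abs(-half_pi + (b + 0.5) * sector_w)
            if ca < min_abs:
                min_abs = ca
    lo = -1
    hi_b = -1
    for b in range(n_sectors):
        if sums[b] >= thresh:
            ca = abs(-half_pi + (b + 0.5) * sector_w)
            if ca <= min_abs + 1e-12:
                if lo < 0:
                    lo = b
                hi_b = b
    if lo == hi_b:
        b = lo
    else:
        b = lo if _tie_u(agent_id, gstep) < 0.5 else hi_b
    ang = -half_pi + (b + 0.5) * sector_w
    cosr = math.cos(ang)
    sinr = math.sin(ang)
    esx = cosr * ehx - sinr * ehy
    esy = sinr * ehx + cosr * ehy
    return True, esx, esy, maxs[b]


@njit(cache=True)
def sync_slime(slv, slt, t_now, kd, sthr):
    """Materialize lazy decay: bring every element to time ``t_now``.

    Sub-threshold ("dry") slime is kept — it is invisible to sensing but
    keeps decaying and may be re-wetted by later deposits."""
    G = slv.shape[0]
    for i in range(G):
        for j in range(G):
            v = slv[i, j]
            if v > 0.0:
                slv[i, j] = v * math.exp(-kd * (t_now - slt[i, j]))
            slt[i, j] = t_now


@njit(cache=True)
def integrate_chunk(pos, anchors, rev_clock, turn_clock, turn_active,
                    turn_dir, turn_left, turn_tx, turn_ty, turn_u,
                    turn_idx, polarity, slv, slt, sense_has, sense_es,
                    sense_sloc, P, IFLAGS, n_steps, step0, t0):
    """Advance the world ``n_steps`` integration steps in place.

    Returns the simulated time after the last step.
    """
    M = pos.shape[0]
    N = pos.shape[1]
    L = P[0]
    l0 = P[1]
    Wc = P[2]
    kl = P[3]
    kb = P[4]
    Fp = P[5]
    cdrag = P[6]
    ka = P[7]
    Famax2 = P[8] * P[8]
    kev = P[9]
    taur = P[10]
    taut = P[11]
    turndur = P[12]
    turnang = P[13]
    epss = P[14]
    Sr = P[15]
    kd = P[16]
    sthr = P[17]
    S0ref = P[18]
    accfrac = P[19]
    dt = P[20]
    slw = P[21]
    Rsense = P[22]
    f_adh_peak = P[23]
    dthr = P[24]
    chi_head = P[25]

    rev_on = IFLAGS[0] == 1
    turn_on = IFLAGS[1] == 1
    slime_on = IFLAGS[2] == 1
    adh_on = IFLAGS[3] == 1
    n_sectors = int(IFLAGS[4])
    stride = int(IFLAGS[5])
    G = int(IFLAGS[6])
    ncell = int(IFLAGS[7])

    nseg = N - 1
    nsegs = M * nseg
    F = np.zeros((M, N, 2))
    tang = np.zeros((M, N, 2))
    turn_now = np.zeros(M, dtype=np.uint8)   # steering active this step
    strong = np.zeros(M, dtype=np.uint8)     # trail claims the head
    seg = np.zeros((nsegs, 6))      # x0 y0 x1 y1 midx midy
    sseg = np.zeros((nsegs, 6))     # cell-sorted copy
    sown = np.zeros(nsegs, dtype=np.int64)
    skid = np.zeros(nsegs, dtype=np.int64)
    use_grid = ncell >= 4 and M > 1
    ncells2 = ncell * ncell if use_grid else 1
    counts = np.zeros(ncells2 + 1, dtype=np.int64)
    fill = np.zeros(ncells2 + 1, dtype=np.int64)
    cellid = np.zeros(nsegs, dtype=np.int64)
    cellw = L / ncell if use_grid else L
    # midpoint quick-reject radius: two half-segments (with stretch
    # allowance) plus the contact cutoff
    reach2 = (1.5 * l0 + Wc) ** 2

    t = t0
    for istep in range(n_steps):
        gstep = step0 + istep
        te = t + dt  # end-of-step time: slime clock

        # ---- 1. behavior: reversals and turn events -------------------
        for i in range(M):
            if rev_on:
                rev_clock[i] += dt
                if rev_clock[i] >= taur - _EPS:
                    rev_clock[i] -= taur
                    for k in range(N // 2):
                        k2 = N - 1 - k
                        for d in range(2):
                            tmp = pos[i, k, d]
                            pos[i, k, d] = pos[i, k2, d]
                            pos[i, k2, d] = tmp
                            tmp = anchors[i, k, d]
                            anchors[i, k, d] = anchors[i, k2, d]
                            anchors[i, k2, d] = tmp
                    anchors[i, 0, 0] = np.nan
                    anchors[i, 0, 1] = np.nan
                    anchors[i, N - 1, 0] = np.nan
                    anchors[i, N - 1, 1] = np.nan
                    polarity[i] = -polarity[i]
            if turn_on:
                turn_clock[i] += dt
                if turn_clock[i] >= taut - _EPS and turn_active[i] == 0:
                    turn_clock[i] -= taut
                    u = turn_u[i, turn_idx[i]]
                    turn_idx[i] += 1
                    turn_dir[i] = -1 if u < 0.5 else 1
                    turn_active[i] = 1
                    turn_left[i] = turndur
                    # lab-frame steering target: heading at onset ±90°
                    hx = _mi(pos[i, 0, 0] - pos[i, 1, 0], L)
                    hy = _mi(pos[i, 0, 1] - pos[i, 1, 1], L)
                    nrm = math.sqrt(hx * hx + hy * hy)
                    hx /= nrm
                    hy /= nrm
                    ca = math.cos(turn_dir[i] * turnang)
                    sa = math.sin(turn_dir[i] * turnang)
                    turn_tx[i] = ca * hx - sa * hy
                    turn_ty[i] = sa * hx + ca * hy
                turn_now[i] = turn_active[i]
                if turn_active[i] == 1:
                    turn_left[i] -= dt
                    if turn_left[i] <= _EPS:
                        turn_active[i] = 0

        # ---- node tangents (headward propulsion directions) -----------
        for i in range(M):
            for k in range(N):
                kk = 0 if k == 0 else k - 1
                dx = _mi(pos[i, kk, 0] - pos[i, kk + 1, 0], L)
                dy = _mi(pos[i, kk, 1] - pos[i, kk + 1, 1], L)
                nrm = math.sqrt(dx * dx + dy * dy)
                if nrm < 1e-12:
                    nrm = 1.0
                tang[i, k, 0] = dx / nrm
                tang[i, k, 1] = dy / nrm

        # ---- 2+3. slime: deposit, then sector sensing at stride -------
        if slime_on:
            for i in range(M):
                gi = int(math.floor(pos[i, N - 1, 0] / slw)) % G
                gj = int(math.floor(pos[i, N - 1, 1] / slw)) % G
                v = slv[gi, gj]
                ve = v * math.exp(-kd * (te - slt[gi, gj])) if v > 0.0 else 0.0
                slv[gi, gj] = ve + Sr * dt
                slt[gi, gj] = te
            if gstep % stride == 0:
                for i in range(M):
                    # trails are an orientation memory: sense along the
                    # body tangent, not the turn target
                    ehx = tang[i, 0, 0]
                    ehy = tang[i, 0, 1]
                    found, esx, esy, sloc = _sense(
                        slv, slt, te, pos[i, 0, 0], pos[i, 0, 1], ehx, ehy,
                        kd, sthr, slw, G, Rsense, n_sectors, accfrac,
                        i, gstep)
                    sense_has[i] = 1 if found else 0
                    sense_es[i, 0] = esx
                    sense_es[i, 1] = esy
                    sense_sloc[i] = sloc

        # ---- 4. forces -------------------------------------------------
        for i in range(M):
            for k in range(N):
                F[i, k, 0] = 0.0
                F[i, k, 1] = 0.0

        for i in range(M):
            # linear springs
            for k in range(N - 1):
                dx = _mi(pos[i, k + 1, 0] - pos[i, k, 0], L)
                dy = _mi(pos[i, k + 1, 1] - pos[i, k, 1], L)
                ln = math.sqrt(dx * dx + dy * dy)
                if ln < 1e-12:
                    ln = 1e-12
                fmag = kl * (ln - l0) / ln
                fx = fmag * dx
                fy = fmag * dy
                F[i, k, 0] += fx
                F[i, k, 1] += fy
                F[i, k + 1, 0] -= fx
                F[i, k + 1, 1] -= fy
            # bending
            for j in range(1, N - 1):
                ax = _mi(pos[i, j, 0] - pos[i, j - 1, 0], L)
                ay = _mi(pos[i, j, 1] - pos[i, j - 1, 1], L)
                bx = _mi(pos[i, j + 1, 0] - pos[i, j, 0], L)
                by = _mi(pos[i, j + 1, 1] - pos[i, j, 1], L)
                la2 = ax * ax + ay * ay
                lb2 = bx * bx + by * by
                if la2 < 1e-24 or lb2 < 1e-24:
                    continue
                phi = math.atan2(ax * by - ay * bx, ax * bx + ay * by)
                pax = -ay / la2
                pay = ax / la2
                pbx = -by / lb2
                pby = bx / lb2
                coef = kb * phi
                F[i, j - 1, 0] -= coef * pax
                F[i, j - 1, 1] -= coef * pay
                F[i, j, 0] -= coef * (-pax - pbx)
                F[i, j, 1] -= coef * (-pay - pby)
                F[i, j + 1, 0] -= coef * pbx
                F[i, j + 1, 1] -= coef * pby
            # propulsion: head with turn steering + slime steering; a
            # sensed trail suppresses the turn override (orientation
            # memory)
            on_trail = slime_on and sense_has[i] == 1
            frac = 0.0
            if on_trail:
                frac = sense_sloc[i] / S0ref
                if frac > 1.0:
                    frac = 1.0
            fs = epss * frac * Fp
            strong[i] = 1 if on_trail else 0
            if turn_now[i] == 1 and strong[i] == 0:
                ehx = turn_tx[i]
                ehy = turn_ty[i]
            else:
                ehx = tang[i, 0, 0]
                ehy = tang[i, 0, 1]
            if on_trail:
                F[i, 0, 0] += fs * sense_es[i, 0] + (Fp - fs) * ehx
                F[i, 0, 1] += fs * sense_es[i, 1] + (Fp - fs) * ehy
            else:
                F[i, 0, 0] += Fp * ehx
                F[i, 0, 1] += Fp * ehy
            for k in range(1, N - 1):
                F[i, k, 0] += Fp * tang[i, k, 0]
                F[i, k, 1] += Fp * tang[i, k, 1]
            # substrate adhesion (lateral spring, breakable)
            for k in range(N):
                ax_ = anchors[i, k, 0]
                if math.isnan(ax_):
                    continue
                dx = _mi(ax_ - pos[i, k, 0], L)
                dy = _mi(anchors[i, k, 1] - pos[i, k, 1], L)
                tx = tang[i, k, 0]
                ty = tang[i, k, 1]
                proj = dx * tx + dy * ty
                lx = dx - proj * tx
                ly = dy - proj * ty
                fx = ka * lx
                fy = ka * ly
                if fx * fx + fy * fy > Famax2:
                    anchors[i, k, 0] = pos[i, k, 0]
                    anchors[i, k, 1] = pos[i, k, 1]
                else:
                    F[i, k, 0] += fx
                    F[i, k, 1] += fy

        # ---- excluded volume (capsule contacts) ------------------------
        # broad phase: segments binned by midpoint into a uniform grid,
        # gathered cell-sorted; narrow phase inlined below (capsule
        # overlap -> penalty force split to segment endpoints)
        if M > 1:
            for i in range(M):
                for k in range(nseg):
                    sidx = i * nseg + k
                    x0 = pos[i, k, 0]
                    y0 = pos[i, k, 1]
                    x1 = x0 + _mi(pos[i, k + 1, 0] - x0, L)
                    y1 = y0 + _mi(pos[i, k + 1, 1] - y0, L)
                    seg[sidx, 0] = x0
                    seg[sidx, 1] = y0
                    seg[sidx, 2] = x1
                    seg[sidx, 3] = y1
                    seg[sidx, 4] = 0.5 * (x0 + x1)
                    seg[sidx, 5] = 0.5 * (y0 + y1)
            if use_grid:
                for cidx in range(ncells2 + 1):
                    counts[cidx] = 0
                for sidx in range(nsegs):
                    ci = int(math.floor(seg[sidx, 4] / cellw)) % ncell
                    cj = int(math.floor(seg[sidx, 5] / cellw)) % ncell
                    cellid[sidx] = ci * ncell + cj
                    counts[cellid[sidx] + 1] += 1
                for cidx in range(ncells2):
                    counts[cidx + 1] += counts[cidx]
                for cidx in range(ncells2 + 1):
                    fill[cidx] = counts[cidx]
                for sidx in range(nsegs):
                    dst = fill[cellid[sidx]]
                    fill[cellid[sidx]] += 1
                    for q in range(6):
                        sseg[dst, q] = seg[sidx, q]
                    sown[dst] = sidx // nseg
                    skid[dst] = sidx % nseg
                for ci in range(ncell):
                    for cj in range(ncell):
                        c1 = ci * ncell + cj
                        a0 = counts[c1]
                        a1 = counts[c1 + 1]
                        if a0 == a1:
                            continue
                        for o in range(5):
                            c2 = ((ci + _OFF_I[o]) % ncell) * ncell \
                                + (cj + _OFF_J[o]) % ncell
                            b1 = counts[c2 + 1]
                            for ia in range(a0, a1):
                                max_ = sseg[ia, 4]
                                may_ = sseg[ia, 5]
                                owna = sown[ia]
                                jb0 = counts[c2] if c2 != c1 else ia + 1
                                for ib in range(jb0, b1):
                                    ddx = sseg[ib, 4] - max_
                                    ddy = sseg[ib, 5] - may_
                                    mdx = _mi(ddx, L)
                                    mdy = _mi(ddy, L)
                                    if mdx * mdx + mdy * mdy > reach2:
                                        continue
                                    if sown[ib] == owna:
                                        continue
                                    offx = mdx - ddx
                                    offy = mdy - ddy
                                    dist, sP, tQ, nx, ny = _seg_dist(
                                        sseg[ia, 0], sseg[ia, 1],
                                        sseg[ia, 2], sseg[ia, 3],
                                        sseg[ib, 0] + offx,
                                        sseg[ib, 1] + offy,
                                        sseg[ib, 2] + offx,
                                        sseg[ib, 3] + offy)
                                    delta = Wc - dist
                                    if delta <= 0.0:
                                        continue
                                    fmag = kev * delta
                                    iB = sown[ib]
                                    kA = skid[ia]
                                    kB = skid[ib]
                                    F[owna, kA, 0] += -fmag * (1.0 - sP) * nx
                                    F[owna, kA, 1] += -fmag * (1.0 - sP) * ny
                                    F[owna, kA + 1, 0] += -fmag * sP * nx
                                    F[owna, kA + 1, 1] += -fmag * sP * ny
                                    F[iB, kB, 0] += fmag * (1.0 - tQ) * nx
                                    F[iB, kB, 1] += fmag * (1.0 - tQ) * ny
                                    F[iB, kB + 1, 0] += fmag * tQ * nx
                                    F[iB, kB + 1, 1] += fmag * tQ * ny
            else:
                for sa in range(nsegs):
                    for sb in range(sa + 1, nsegs):
                        if sa // nseg == sb // nseg:
                            continue
                        ddx = seg[sb, 4] - seg[sa, 4]
                        ddy = seg[sb, 5] - seg[sa, 5]
                        mdx = _mi(ddx, L)
                        mdy = _mi(ddy, L)
                        if mdx * mdx + mdy * mdy > reach2:
                            continue
                        offx = mdx - ddx
                        offy = mdy - ddy
                        dist, sP, tQ, nx, ny = _seg_dist(
                            seg[sa, 0], seg[sa, 1], seg[sa, 2], seg[sa, 3],
                            seg[sb, 0] + offx, seg[sb, 1] + offy,
                            seg[sb, 2] + offx, seg[sb, 3] + offy)
                        delta = Wc - dist
                        if delta <= 0.0:
                            continue
                        fmag = kev * delta
                        iA = sa // nseg
                        iB = sb // nseg
                        kA = sa % nseg
                        kB = sb % nseg
                        F[iA, kA, 0] += -fmag * (1.0 - sP) * nx
                        F[iA, kA, 1] += -fmag * (1.0 - sP) * ny
                        F[iA, kA + 1, 0] += -fmag * sP * nx
                        F[iA, kA + 1, 1] += -fmag * sP * ny
                        F[iB, kB, 0] += fmag * (1.0 - tQ) * nx
                        F[iB, kB, 1] += fmag * (1.0 - tQ) * ny
                        F[iB, kB + 1, 0] += fmag * tQ * nx
                        F[iB, kB + 1, 1] += fmag * tQ * ny

        # ---- lateral cell-cell adhesion (optional) ---------------------
        if adh_on:
            for i in range(M):
                for j in range(M):
                    if j == i:
                        continue
                    for k in range(N):
                        best = 1e30
                        bx_ = 0.0
                        by_ = 0.0
                        for kk in range(N):
                            dx = _mi(pos[j, kk, 0] - pos[i, k, 0], L)
                            dy = _mi(pos[j, kk, 1] - pos[i, k, 1], L)
                            d2 = dx * dx + dy * dy
                            if d2 < best:
                                best = d2
                                bx_ = dx
                                by_ = dy
                        dperp = math.sqrt(best)
                        if Wc <= dperp < dthr:
                            mag = (dperp - Wc) / (dthr - Wc) * f_adh_peak
                            nx = -tang[i, k, 1]
                            ny = tang[i, k, 0]
                            if nx * bx_ + ny * by_ < 0.0:
                                nx = -nx
                                ny = -ny
                            F[i, k, 0] += mag * nx
                            F[i, k, 1] += mag * ny

        # ---- 5. overdamped integration (head node: reduced transverse
        # mobility from nascent-adhesion friction) -----------------------
        inv_c_dt = dt / cdrag
        for i in range(M):
            # a dominant trail lubricates: full transverse mobility
            chi = 1.0 if strong[i] == 1 else chi_head
            tx = tang[i, 0, 0]
            ty = tang[i, 0, 1]
            fax = F[i, 0, 0] * tx + F[i, 0, 1] * ty
            flx = F[i, 0, 0] - fax * tx
            fly = F[i, 0, 1] - fax * ty
            pos[i, 0, 0] += (fax * tx + flx / chi) * inv_c_dt
            pos[i, 0, 1] += (fax * ty + fly / chi) * inv_c_dt
            for k in range(1, N):
                pos[i, k, 0] += F[i, k, 0] * inv_c_dt
                pos[i, k, 1] += F[i, k, 1] * inv_c_dt

        # ---- 6. anchor maintenance: slide axially with the node --------
        for i in range(M):
            for k in range(N):
                kk = 0 if k == 0 else k - 1
                dx = _mi(pos[i, kk, 0] - pos[i, kk + 1, 0], L)
                dy = _mi(pos[i, kk, 1] - pos[i, kk + 1, 1], L)
                nrm = math.sqrt(dx * dx + dy * dy)
                if nrm < 1e-12:
                    continue
                tx = dx / nrm
                ty = dy / nrm
                ax_ = anchors[i, k, 0]
                if math.isnan(ax_):
                    continue
                ddx = _mi(ax_ - pos[i, k, 0], L)
                ddy = _mi(anchors[i, k, 1] - pos[i, k, 1], L)
                proj = ddx * tx + ddy * ty
                anchors[i, k, 0] = pos[i, k, 0] + (ddx - proj * tx)
                anchors[i, k, 1] = pos[i, k, 1] + (ddy - proj * ty)

        # ---- 7. periodic wrap ------------------------------------------
        for i in range(M):
            for k in range(N):
                for d in range(2):
                    pos[i, k, d] -= L * math.floor(pos[i, k, d] / L)
                    if not math.isnan(anchors[i, k, d]):
                        anchors[i, k, d] -= L * math.floor(
                            anchors[i, k, d] / L)

        t = t + dt
    return t


@njit(cache=True)
def agent_pair_min_dist(pa, pb, L):
    """Minimum capsule center-line distance between two node chains
    (minimum image). Used by cluster detection."""
    na = pa.shape[0] - 1
    nb = pb.shape[0] - 1
    best = 1e30
    for i in range(na):
        ax0 = pa[i, 0]
        ay0 = pa[i, 1]
        ax1 = ax0 + _mi(pa[i + 1, 0] - ax0, L)
        ay1 = ay0 + _mi(pa[i + 1, 1] - ay0, L)
        for j in range(nb):
            bx0 = pb[j, 0]
            by0 = pb[j, 1]
            bx1 = bx0 + _mi(pb[j + 1, 0] - bx0, L)
            by1 = by0 + _mi(pb[j + 1, 1] - by0, L)
            max_ = 0.5 * (ax0 + ax1)
            may_ = 0.5 * (ay0 + ay1)
            mbx = 0.5 * (bx0 + bx1)
            mby = 0.5 * (by0 + by1)
            offx = _mi(mbx - max_, L) - (mbx - max_)
            offy = _mi(mby - may_, L) - (mby - may_)
            dist, _, _, _, _ = _seg_dist(ax0, ay0, ax1, ay1,
                                         bx0 + offx, by0 + offy,
                                         bx1 + offx, by1 + offy)
            if dist < best:
                best = dist
    return best
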