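"""Slime field: deposition, drying, trail sensing and head steering.

Cells deposit slime (a polymeric gel) at a constant rate S_r into a
square grid of element width ≈ W_c covering the periodic domain; each
element dries exponentially (dS/dt = −k_d·S) and counts as a *wet* trail
element while its volume is at least the absolute detection threshold
S_thr. A gliding cell senses wet slime in the five 36° sectors of the
forward semicircle of radius L_c/2 ahead of its head node, picks the
qualifying sector closest to its heading, and redirects part of its head
propulsion along that trail (the stigmergic steering that lets reversing
cells keep clustering).

The trail length behind a single glider follows in closed form:
τ1 = W_c/v_c is the residence time over one element, the fresh deposit is
S_τ1 = (1 − e^{−k_d·τ1})·S_r/k_d, it dries below S_thr after
t_thr = ln(S_τ1/S_thr)/k_d, and L_s = t_thr·v_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import AgentState, ModelParams, rotate

__all__ = [
    "SlimeField",
    "deposit",
    "decay",
    "sense_trail",
    "steering_split",
    "trail_length",
    "rate_for_trail_length",
    "tie_uniform",
]


@dataclass
class SlimeField:
    """Dense wet-slime volume grid over the periodic domain.

    ``values[i, j]`` is the slime volume in the element whose lower-left
    corner is (i·width, j·width); indices wrap. ``S0_ref`` is the fresh
    per-crossing deposit volume used to normalize steering.
    """
    values: np.ndarray          # (G, G) volumes
    width: float                # element width, μm (≈ W_c)
    L: float                    # domain edge, μm
    S0_ref: float               # reference deposit volume per crossing

    @classmethod
    def empty(cls, p: ModelParams) -> "SlimeField":
        G = p.grid_n
        return cls(values=np.zeros((G, G)), width=p.L_sim / G,
                   L=p.L_sim, S0_ref=p.S0_ref)

    @property
    def G(self) -> int:
        return self.values.shape[0]

    def element_index(self, point: np.ndarray) -> tuple:
        i = int(math.floor(point[0] / self.width)) % self.G
        j = int(math.floor(point[1] / self.width)) % self.G
        return i, j

    def value_at(self, point: np.ndarray) -> float:
        return float(self.values[self.element_index(point)])

    def total(self) -> float:
        return float(self.values.sum())

    def save(self, path, png: bool = False) -> None:
        """Export the field: compressed HDF5 matrix plus grid metadata;
        optionally a grayscale PNG alongside (trail-network snapshots)."""
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("slime", data=self.values,
                                 compression="gzip")
            d.attrs["width_um"] = self.width
            d.attrs["L_um"] = self.L
            d.attrs["S0_ref"] = self.S0_ref
        if png:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            img = np.log10(self.values.T + 1e-6)
            plt.imsave(str(path) + ".png", img, origin="lower",
                       cmap="gray")


def deposit(field: SlimeField, agent: AgentState, dt: float,
            p: ModelParams) -> SlimeField:
    """Deposit S_r·dt into the element containing the agent's tail node.

    Tail-only deposition lays a one-element-wide trail behind the moving
    cell, matching the W_c-wide trail geometry of the L_s formula.
    """
    i, j = field.element_index(agent.positions[-1])
    field.values[i, j] += p.S_r * dt
    return field


def decay(field: SlimeField, dt: float, p: ModelParams,
          prune: bool = True) -> SlimeField:
    """Exact exponential drying: S ← S·exp(−k_d·dt); dry elements
    (S < S_thr) are zeroed when ``prune``."""
    field.values *= math.exp(-p.k_d * dt)
    if prune:
        field.values[field.values < p.S_thr] = 0.0
    return field


def tie_uniform(agent_id: int, step: int) -> float:
    """Deterministic unbiased uniform in [0,1) for sector tie-breaks.

    A 32-bit integer hash of (agent id, step index); identical in the
    reference path and the compiled kernel so both follow bit-identical
    trajectories.
    """
    h = ((agent_id + 1) * 2654435761 + step * 2246822519) & 0xFFFFFFFF
    h ^= h >> 16
    h = (h * 2654435761) & 0xFFFFFFFF
    h ^= h >> 13
    return h / 4294967296.0


def sense_trail(field: SlimeField, head_pos: np.ndarray, e_h: np.ndarray,
                rng, p: ModelParams, include_own: bool = False):
    """Find the dominant wet trail ahead of the head node.

    Wet slime is summed over grid elements whose centers fall inside the
    forward semicircle of radius L_c/2, split into ``n_sectors`` equal
    angular bins; the head's own element is excluded. Among bins holding
    ≥ sector_accept_frac·S_max, the one with least angular deviation from
    ``e_h`` wins; a symmetric two-bin tie is broken by ``rng`` (any object
    with ``.random()``).

    Returns ``(e_s, S_local)`` — the winning sector's center-line unit
    vector and the strongest wet element volume within that sector (the
    local trail strength driving the steering magnitude) — or ``None``
    when no wet slime lies ahead.
    """
    w = field.width
    G = field.G
    R = p.L_c / 2.0
    n = p.n_sectors
    hi = math.floor(head_pos[0] / w)
    hj = math.floor(head_pos[1] / w)
    span = int(math.ceil(R / w)) + 1
    sums = np.zeros(n)
    maxs = np.zeros(n)
    for di in range(-span, span + 1):
        for dj in range(-span, span + 1):
            if di == 0 and dj == 0 and not include_own:
                continue  # a cell does not follow the slime it stands on
            cx = (hi + di + 0.5) * w - head_pos[0]
            cy = (hj + dj + 0.5) * w - head_pos[1]
            if cx * cx + cy * cy > R * R:
                continue
            dot = cx * e_h[0] + cy * e_h[1]
            if dot <= 0.0:
                continue
            S = field.values[(hi + di) % G, (hj + dj) % G]
            if S < p.S_thr:
                continue
            cross = e_h[0] * cy - e_h[1] * cx
            ang = math.atan2(cross, dot)
            b = int((ang + math.pi / 2.0) / (math.pi / n))
            b = min(max(b, 0), n - 1)
            sums[b] += S
            if S > maxs[b]:
                maxs[b] = S
    s_max = sums.max()
    if s_max <= 0.0:
        return None
    centers = -math.pi / 2.0 + (np.arange(n) + 0.5) * math.pi / n
    qual = sums >= p.sector_accept_frac * s_max - 1e-12
    abs_ok = np.where(qual, np.abs(centers), np.inf)
    min_abs = abs_ok.min()
    cands = np.flatnonzero(abs_ok <= min_abs + 1e-12)
    if len(cands) == 1:
        b = int(cands[0])
    else:  # symmetric pair on opposite sides of ê_h
        b = int(cands[0]) if rng.random() < 0.5 else int(cands[-1])
    e_s = rotate(np.asarray(e_h, dtype=float), centers[b])
    return e_s, float(maxs[b])


def steering_split(e_s: np.ndarray, e_h: np.ndarray, S_local: float,
                   p: ModelParams):
    """Split the head propulsion between trail and heading directions.

    |F_s| = ε_s·min(1, S_local/S0_ref)·F_T/(N−1) along ê_s;
    |F_c| = F_T/(N−1) − |F_s| along ê_h. The component magnitudes always
    sum to the undisturbed head propulsion (the resultant norm is not
    preserved; the decomposition is applied exactly as defined).
    """
    if S_local < 0:
        raise ValueError("S_local must be ≥ 0")
    fp = p.Fp_w
    fs = p.eps_s * min(1.0, S_local / p.S0_ref) * fp
    return fs * np.asarray(e_s, float), (fp - fs) * np.asarray(e_h, float)


def _ls_of(sr: float, kd: float, p: ModelParams) -> float:
    """Trail length for given rates; 0 when the deposit never exceeds S_thr."""
    tau1 = p.W_c / p.v_c
    s_tau1 = (1.0 - math.exp(-kd * tau1)) * sr / kd
    if s_tau1 <= p.S_thr:
        return 0.0
    return math.log(s_tau1 / p.S_thr) / kd * p.v_c


def trail_length(p: ModelParams) -> float:
    """Closed-form wet-trail length L_s = t_thr·v_c behind a single glider."""
    if min(p.S_r, p.k_d, p.v_c, p.W_c) <= 0:
        raise ValueError("S_r, k_d, v_c, W_c must be positive")
    ls = _ls_of(p.S_r, p.k_d, p)
    if ls <= 0.0:
        raise ValueError("trail shorter than one element: the per-crossing "
                         "deposit never exceeds S_thr")
    return ls


_F_LO, _F_HI = 1e-4, 1e4


def rate_for_trail_length(L_s_target: float, p: ModelParams):
    """Rates (f·S_r, f·k_d) producing trail length ``L_s_target``.

    Scaling production and drying by the same factor keeps the steady
    total slime volume S_r/k_d in the region constant while shortening
    (f > 1) or lengthening (f < 1) individual trails. L_s(f) rises from 0
    at the existence boundary to a single maximum and then decreases; the
    experimentally motivated branch is the decreasing one, so f is solved
    there by bisection (|L_s − target| ≤ 1e-3 μm).
    """
    if L_s_target <= 0:
        raise ValueError("L_s_target must be positive")
    sr0, kd0 = p.S_r, p.k_d

    def ls(f: float) -> float:
        return _ls_of(f * sr0, f * kd0, p)

    # locate the peak of the unimodal L_s(f) by golden-section search
    lo, hi = _F_LO, _F_HI
    grid = np.geomspace(lo, hi, 200)
    vals = np.array([ls(f) for f in grid])
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    for _ in range(80):
        if ls(x1) < ls(x2):
            a = x1
            x1, x2 = x2, a + invphi * (b - a)
        else:
            b = x2
            x2, x1 = x1, b - invphi * (b - a)
    f_peak = 0.5 * (a + b)
    if L_s_target > ls(f_peak) or L_s_target < ls(_F_HI):
        raise ValueError(
            f"trail length {L_s_target} μm unreachable by rescaling rates "
            f"within f ∈ [{_F_LO:g}, {_F_HI:g}] "
            f"(attainable on the decreasing branch: "
            f"[{ls(_F_HI):.3g}, {ls(f_peak):.3g}] μm)")
    a, b = f_peak, _F_HI
    for _ in range(200):
        mid = math.sqrt(a * b)
        if ls(mid) > L_s_target:
            a = mid
        else:
            b = mid
        if abs(ls(mid) - L_s_target) <= 1e-4:
            break
    f = 0.5 * (a + b)
    return f * sr0, f * kd0
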