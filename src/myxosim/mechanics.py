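"""Forces on agent nodes.

All per-node forces of the bead-spring cell model: linear (stretch) and
angular (bending) springs, distributed propulsion, viscous drag,
breakable substrate adhesions, capsule excluded-volume penalties and the
optional lateral cell-cell adhesion ramp. Forces are in pN, positions in
μm (see :mod:`myxosim.model_core` for conventions).

These are the reference (numpy) implementations; :mod:`myxosim._kernels`
fuses the same math into one compiled update loop for production runs and
is tested against the composition of the functions here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import AgentState, ModelParams, WorldState, unit

__all__ = [
    "ForceSet",
    "force_breakdown",
    "linear_spring_forces",
    "bending_forces",
    "propulsion_forces",
    "drag_forces",
    "substrate_adhesion",
    "excluded_volume_forces",
    "lateral_adhesion_forces",
    "segment_segment_distance",
    "capsule_pair_distance",
    "min_image",
]

_SOURCES = ("spring", "bend", "propel", "drag", "adhesion", "contact", "lateral")


@dataclass
class ForceSet:
    """Per-node force accumulators, tagged by source.

    ``shape`` is (N, 2) for single-agent force laws and (M, N, 2) for
    world-level (pairwise) force laws.
    """
    shape: tuple
    by_source: dict = field(default_factory=dict)

    def add(self, source: str, forces: np.ndarray) -> None:
        if source not in _SOURCES:
            raise KeyError(f"unknown force source {source!r}")
        if source in self.by_source:
            self.by_source[source] = self.by_source[source] + forces
        else:
            self.by_source[source] = np.asarray(forces, dtype=float)

    def get(self, source: str) -> np.ndarray:
        return self.by_source.get(source, np.zeros(self.shape))

    def total(self) -> np.ndarray:
        out = np.zeros(self.shape)
        for f in self.by_source.values():
            out = out + f
        return out


def force_breakdown(world: WorldState) -> "object":
    """Tidy per-node force table for debugging: one row per
    (agent, node, source, component). Single-agent sources only (the
    engine composes pairwise sources during stepping)."""
    import pandas as pd

    p = world.params
    rows = []
    for a in world.agents:
        per_source = {
            "spring": linear_spring_forces(a, p, p.L_sim).total(),
            "bend": bending_forces(a, p, p.L_sim).total(),
            "drag": drag_forces(a, p).total(),
        }
        for src, F in per_source.items():
            for k in range(a.n_nodes):
                rows.append({"agent": a.id, "node": k, "source": src,
                             "fx_pN": F[k, 0], "fy_pN": F[k, 1]})
    return pd.DataFrame(rows)


def min_image(d: np.ndarray, L: float | None) -> np.ndarray:
    """Minimum-image displacement under a periodic square box of edge L."""
    if L is None:
        return d
    return d - L * np.round(d / L)


# ----------------------------------------------------------------------
# internal elastic forces
# ----------------------------------------------------------------------

def _bond_vectors(agent: AgentState, p: ModelParams, L_box=None) -> np.ndarray:
    d = np.diff(agent.positions, axis=0)          # r_{i+1} - r_i
    d = min_image(d, L_box)
    lens = np.linalg.norm(d, axis=1)
    if np.any(lens < 1e-12):
        raise ValueError("coincident adjacent nodes: undefined direction")
    return d, lens


def linear_spring_forces(agent: AgentState, p: ModelParams,
                         L_box: float | None = None) -> ForceSet:
    """−∇ of E_l = ½ k_l Σ (|r_{i+1}−r_i| − l0)²; net force is zero."""
    if agent.n_nodes < 2:
        raise ValueError("need ≥ 2 nodes for linear springs")
    d, lens = _bond_vectors(agent, p, L_box)
    u = d / lens[:, None]
    f_mag = p.kl_w * (lens - p.l0)                # >0 when stretched
    F = np.zeros_like(agent.positions)
    np.add.at(F, np.arange(len(d)), f_mag[:, None] * u)       # node i pulled fwd
    np.add.at(F, np.arange(1, len(d) + 1), -f_mag[:, None] * u)
    fs = ForceSet(F.shape)
    fs.add("spring", F)
    return fs


def bending_forces(agent: AgentState, p: ModelParams,
                   L_box: float | None = None) -> ForceSet:
    """−∇ of E_b = ½ k_b Σ_j φ_j² with φ_j the signed turning angle at
    interior node j (deviation from collinearity); zero net force/torque."""
    if agent.n_nodes < 3:
        raise ValueError("need ≥ 3 nodes for bending")
    d, lens = _bond_vectors(agent, p, L_box)
    F = np.zeros_like(agent.positions)
    for j in range(1, agent.n_nodes - 1):
        a, b = d[j - 1], d[j]
        la2, lb2 = lens[j - 1] ** 2, lens[j] ** 2
        phi = math.atan2(a[0] * b[1] - a[1] * b[0], a[0] * b[0] + a[1] * b[1])
        pa = np.array([-a[1], a[0]]) / la2        # ∇_a θ_a
        pb = np.array([-b[1], b[0]]) / lb2
        # φ = θ_b − θ_a;  a = r_j − r_{j−1},  b = r_{j+1} − r_j
        g_prev = pa                                # ∂φ/∂r_{j−1}
        g_next = pb                                # ∂φ/∂r_{j+1}
        g_self = -pa - pb                          # ∂φ/∂r_j
        F[j - 1] -= p.kb_w * phi * g_prev
        F[j] -= p.kb_w * phi * g_self
        F[j + 1] -= p.kb_w * phi * g_next
    fs = ForceSet(F.shape)
    fs.add("bend", F)
    return fs


# ----------------------------------------------------------------------
# propulsion and drag
# ----------------------------------------------------------------------

def propulsion_forces(agent: AgentState, head_dir: np.ndarray,
                      p: ModelParams, L_box: float | None = None) -> ForceSet:
    """Distributed gliding propulsion.

    Every node except the tail receives F_T/(N−1) tangentially toward the
    next node headward; the head node's force acts along ``head_dir``
    (already turn-rotated / slime-steered by the caller).
    """
    N = agent.n_nodes
    F = np.zeros_like(agent.positions)
    F[0] = p.Fp_w * head_dir
    for i in range(1, N - 1):
        u = unit(min_image(agent.positions[i - 1] - agent.positions[i], L_box))
        F[i] = p.Fp_w * u
    fs = ForceSet(F.shape)
    fs.add("propel", F)
    return fs


def drag_forces(agent: AgentState, p: ModelParams) -> ForceSet:
    """Viscous drag F_d = −c·v per node."""
    fs = ForceSet(agent.positions.shape)
    fs.add("drag", -p.c_w * agent.velocities)
    return fs


# ----------------------------------------------------------------------
# substrate adhesion
# ----------------------------------------------------------------------

def _node_tangents(agent: AgentState, L_box=None) -> np.ndarray:
    """Unit propulsion tangents: node i points toward node i−1 (headward);
    the head uses its own forward tangent."""
    pos = agent.positions
    t = np.zeros_like(pos)
    t[0] = unit(min_image(pos[0] - pos[1], L_box))
    for i in range(1, len(pos)):
        t[i] = unit(min_image(pos[i - 1] - pos[i], L_box))
    return t


def substrate_adhesion(agent: AgentState, p: ModelParams,
                       L_box: float | None = None):
    """Breakable focal-adhesion springs resisting lateral node displacement.

    The anchor force is k_a times the component of (anchor − node)
    perpendicular to the node's propulsion tangent — adhesions translocate
    freely along the gliding axis and only pin the cell sideways. When the
    force exceeds F_a,max the anchor detaches and immediately re-anchors
    at the node's current position (force drops to zero for that step).
    Only interior nodes carry anchors: the tail sheds them and the
    leading pole's nascent adhesions are modeled as transverse viscous
    drag (see the engine's overdamped update) rather than a spring.

    Returns ``(ForceSet, new_anchors)``; the end nodes carry no anchor.
    (Axial anchor translocation itself is engine bookkeeping applied after
    integration; see :func:`myxosim.engine.slide_anchors`.)
    """
    pos = agent.positions
    tang = _node_tangents(agent, L_box)
    F = np.zeros_like(pos)
    new_anchors = agent.anchors.copy()
    for i in range(agent.n_nodes):
        a = agent.anchors[i]
        if np.any(np.isnan(a)):
            continue
        d = min_image(a - pos[i], L_box)
        d_lat = d - np.dot(d, tang[i]) * tang[i]
        f = p.ka_w * d_lat
        if np.linalg.norm(f) > p.Famax_w:
            new_anchors[i] = pos[i]               # detach + re-anchor
        else:
            F[i] = f
    fs = ForceSet(F.shape)
    fs.add("adhesion", F)
    return fs, new_anchors


# ----------------------------------------------------------------------
# excluded volume (capsule contacts)
# ----------------------------------------------------------------------

def segment_segment_distance(p0, p1, q0, q1):
    """Closest distance between 2-D segments and its barycentric params.

    Returns ``(dist, s, t, n)``: closest points are ``p0+s·(p1−p0)`` and
    ``q0+t·(q1−q0)``; ``n`` is the unit vector from the P- to the Q-side
    closest point (an arbitrary perpendicular if coincident).
    """
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-18 and e <= 1e-18:
        s = t = 0.0
    elif a <= 1e-18:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = float(d1 @ r)
        if e <= 1e-18:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = min(1.0, max(0.0, (b * f - c * e) / denom)) if denom > 1e-18 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    cp = p0 + s * d1
    cq = q0 + t * d2
    diff = cq - cp
    dist = math.hypot(diff[0], diff[1])
    if dist > 1e-12:
        n = diff / dist
    else:
        axis = d1 if a > 1e-18 else d2
        nrm = math.hypot(axis[0], axis[1])
        n = (np.array([-axis[1], axis[0]]) / nrm) if nrm > 1e-12 else np.array([1.0, 0.0])
    return dist, s, t, n


def _agent_segments(agent: AgentState, L_box):
    """Segment endpoints as locally-unwrapped coordinates (e0, e1)."""
    pos = agent.positions
    e0 = pos[:-1]
    e1 = e0 + min_image(pos[1:] - e0, L_box)
    return e0, e1


def capsule_pair_distance(a: AgentState, b: AgentState,
                          p: ModelParams) -> float:
    """Minimum center-line distance between two capsule chains under the
    periodic box of ``p`` (minimum-image convention)."""
    L_box = p.L_sim
    a0, a1 = _agent_segments(a, L_box)
    b0, b1 = _agent_segments(b, L_box)
    best = math.inf
    for i in range(len(a0)):
        for j in range(len(b0)):
            # shift the b-segment next to the a-segment (minimum image)
            mid_a = 0.5 * (a0[i] + a1[i])
            mid_b = 0.5 * (b0[j] + b1[j])
            off = min_image(mid_b - mid_a, L_box) - (mid_b - mid_a)
            d, _, _, _ = segment_segment_distance(a0[i], a1[i],
                                                  b0[j] + off, b1[j] + off)
            best = min(best, d)
    return best


def excluded_volume_forces(world: WorldState) -> ForceSet:
    """Penalty contacts between overlapping capsules of distinct agents.

    For every inter-agent segment pair whose center-lines come closer than
    W_c (surface overlap δ > 0) a force k_ev·δ acts along the mutual
    normal, split to the four segment endpoints by closest-point
    barycentric weights. Newton's third law holds pairwise.
    """
    p = world.params
    L = p.L_sim
    M = world.M
    N = p.N
    F = np.zeros((M, N, 2))
    segs = [_agent_segments(a, L) for a in world.agents]
    for ia in range(M):
        a0, a1 = segs[ia]
        for ib in range(ia + 1, M):
            b0, b1 = segs[ib]
            for i in range(N - 1):
                for j in range(N - 1):
                    mid_a = 0.5 * (a0[i] + a1[i])
                    mid_b = 0.5 * (b0[j] + b1[j])
                    off = min_image(mid_b - mid_a, L) - (mid_b - mid_a)
                    d, s, t, n = segment_segment_distance(
                        a0[i], a1[i], b0[j] + off, b1[j] + off)
                    delta = p.W_c - d
                    if delta > 0:
                        fmag = p.k_ev_w * delta
                        # push a away from b (n points a→b)
                        F[ia, i] += -fmag * (1 - s) * n
                        F[ia, i + 1] += -fmag * s * n
                        F[ib, j] += fmag * (1 - t) * n
                        F[ib, j + 1] += fmag * t * n
    fs = ForceSet(F.shape)
    fs.add("contact", F)
    return fs


# ----------------------------------------------------------------------
# lateral cell-cell adhesion (optional)
# ----------------------------------------------------------------------

def lateral_adhesion_forces(world: WorldState) -> ForceSet:
    """EPS-mediated attraction between nearby nodes of neighbouring cells.

    For each node, the nearest node of each neighbour agent at
    perpendicular (point-to-point) distance W_c ≤ d⊥ < d_thr attracts it
    with magnitude ((d⊥−W_c)/(d_thr−W_c))·k_adh·F_T/N, applied normal to
    the node's propulsion tangent, signed toward the neighbour. At most
    one partner per node per neighbour agent.
    """
    p = world.params
    if not p.adhesion_enabled:
        raise ValueError("lateral adhesion requested but adhesion_enabled is False")
    L = p.L_sim
    M = world.M
    F = np.zeros((M, p.N, 2))
    tangents = [_node_tangents(a, L) for a in world.agents]
    fmax = p.k_adh * p.FT_w / p.N
    for ia in range(M):
        pa = world.agents[ia].positions
        for ib in range(M):
            if ib == ia:
                continue
            pb = world.agents[ib].positions
            for i in range(p.N):
                d = min_image(pb - pa[i], L)
                dist = np.linalg.norm(d, axis=1)
                j = int(np.argmin(dist))
                dperp = dist[j]
                if p.W_c <= dperp < p.d_thr:
                    mag = (dperp - p.W_c) / (p.d_thr - p.W_c) * fmax
                    t = tangents[ia][i]
                    n = np.array([-t[1], t[0]])
                    if np.dot(n, d[j]) < 0:
                        n = -n
                    F[ia, i] += mag * n
    fs = ForceSet(F.shape)
    fs.add("lateral", F)
    return fs
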