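"""World initialization, the per-step update loop and trajectory recording.

The update order of one integration step is fixed:

1. behavior (reversal, turn event) per agent in id order;
2. slime drying then deposition;
3. head-direction composition: tangent → turn steering → trail steering
   (trail sensing is refreshed every ``SENSE_INTERVAL`` minutes);
4. all mechanical forces;
5. overdamped update v = F/c, x += v·dt;
6. anchor maintenance (axial translocation);
7. periodic wrapping.

:func:`step` is the readable reference implementation operating on
:class:`~myxosim.model_core.WorldState` objects; :func:`run` drives the
compiled kernel in :mod:`myxosim._kernels` over whole snapshot intervals
and records a :class:`Snapshot` every minute. Both paths follow the same
trajectory (verified to machine precision on short runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels, behavior, mechanics
from .model_core import (AgentState, ModelParams, TurnState, WorldState,
                         validate_params)
from .slime import SlimeField, decay, deposit, sense_trail, steering_split, tie_uniform

__all__ = [
    "Snapshot",
    "Trajectory",
    "SENSE_INTERVAL",
    "initialize_world",
    "step",
    "run",
    "run_world",
    "slide_anchors",
    "save_trajectory",
    "load_trajectory",
]

#: trail sensing cadence, min (sector search is refreshed this often)
SENSE_INTERVAL = 0.01

_MAX_INIT_ATTEMPT_FACTOR = 100_000


@dataclass
class Snapshot:
    """Per-minute record of the agent configuration."""
    time: float
    positions: np.ndarray        # (M, N, 2), wrapped into [0, L)²
    orientations: np.ndarray     # (M,) tail→head angle, [0, 2π)
    polarity: np.ndarray         # (M,) ±1


@dataclass
class Trajectory:
    snapshots: list
    params: ModelParams
    events: list = field(default_factory=list)

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def at(self, t: float) -> Snapshot:
        k = int(np.argmin(np.abs(self.times() - t)))
        return self.snapshots[k]


def _sense_stride(p: ModelParams) -> int:
    return max(1, int(round(SENSE_INTERVAL / p.dt)))


def _contact_grid_n(p: ModelParams) -> int:
    # broad-phase cell edge ≥ the segment interaction reach (half-lengths
    # with stretch allowance plus the contact cutoff)
    target = 1.5 * p.l0 + p.W_c
    return max(1, int(p.L_sim / target))


def initialize_world(p: ModelParams,
                     rng: Optional[np.random.Generator] = None) -> WorldState:
    """Place M straight agents without overlap, assign heads and clocks.

    Uniform random positions/orientations with rejection of any placement
    whose capsule overlaps an accepted agent; the head end is then chosen
    by fair coin and timer phases randomized. Deterministic in
    (params, seed).
    """
    if not p._validated:
        p = validate_params(p)
    if rng is None:
        rng = np.random.default_rng(p.seed)
    M = p.M
    L = p.L_sim

    # coarse bin grid for candidate overlap checks
    bin_w = p.L_c + p.W_c
    nb = max(1, int(L / bin_w))
    bins: dict = {}
    ends = np.zeros((M, 2, 2))      # accepted axis segments (head, tail)

    agents = []
    attempts = 0
    max_attempts = _MAX_INIT_ATTEMPT_FACTOR * M
    for i in range(M):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"initialization failed: {attempts} rejection-sampling "
                    f"attempts exceeded for eta={p.eta}")
            cx, cy = rng.uniform(0.0, L, 2)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            u = np.array([math.cos(theta), math.sin(theta)])
            h = np.array([cx, cy]) + 0.5 * p.L_c * u
            tl = np.array([cx, cy]) - 0.5 * p.L_c * u
            bi = int(cx / bin_w) % nb
            bj = int(cy / bin_w) % nb
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for jdx in bins.get(((bi + di) % nb, (bj + dj) % nb), ()):
                        oh, ot = ends[jdx]
                        mid_o = 0.5 * (oh + ot)
                        mid_n = np.array([cx, cy])
                        off = mechanics.min_image(mid_o - mid_n, L) - (mid_o - mid_n)
                        d, _, _, _ = mechanics.segment_segment_distance(
                            h, tl, oh + off, ot + off)
                        if d < p.W_c:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                break
        ends[i, 0] = h
        ends[i, 1] = tl
        bins.setdefault((bi, bj), []).append(i)
        a = AgentState.straight(np.array([cx, cy]), theta, p, agent_id=i)
        a.positions %= L
        a.anchors[1:-1] = a.positions[1:-1]
        agents.append(a)

    for a in agents:                 # head chosen by fair coin
        if rng.random() < 0.5:
            behavior.reverse_agent(a)
            a.polarity = 1           # the coin sets the initial labelling
    for a in agents:
        behavior.init_clocks(a, rng, p)

    K = int(p.t_end / p.tau_t) + 3
    world = WorldState(
        agents=agents, slime=SlimeField.empty(p), params=p, time=0.0,
        rng=rng, turn_u=rng.random((M, K)),
        turn_idx=np.zeros(M, dtype=np.int64),
        sense_has=np.zeros(M, dtype=np.uint8),
        sense_es=np.zeros((M, 2)), sense_sloc=np.zeros(M))
    return world


# ----------------------------------------------------------------------
# reference step
# ----------------------------------------------------------------------

class _SeqRng:
    """Draw adapter feeding an agent's pre-drawn turn uniforms."""

    def __init__(self, world: WorldState, i: int):
        self.world = world
        self.i = i

    def random(self) -> float:
        u = self.world.turn_u[self.i, self.world.turn_idx[self.i]]
        self.world.turn_idx[self.i] += 1
        return float(u)


class _FixedU:
    def __init__(self, u: float):
        self.u = u

    def random(self) -> float:
        return self.u


def slide_anchors(agent: AgentState, p: ModelParams, L: float) -> None:
    """Translocate anchors axially: keep only the lateral offset relative
    to the node's (post-move) propulsion tangent."""
    tang = mechanics._node_tangents(agent, L)
    for k in range(agent.n_nodes):
        a = agent.anchors[k]
        if np.any(np.isnan(a)):
            continue
        d = mechanics.min_image(a - agent.positions[k], L)
        d_lat = d - np.dot(d, tang[k]) * tang[k]
        agent.anchors[k] = agent.positions[k] + d_lat


def step(world: WorldState) -> WorldState:
    """One integration step (reference implementation)."""
    p = world.params
    L = p.L_sim
    dt = p.dt
    M = world.M
    gstep = world.step_index
    overrides = [None] * M

    # 1. behavior
    for i, a in enumerate(world.agents):
        behavior.update_reversal(a, dt, p)
        _, overrides[i] = behavior.update_turn(a, dt, _SeqRng(world, i), p)

    # 2. slime drying + deposition (no pruning in the dynamic loop:
    # sub-threshold slime is merely invisible to sensing, and fresh
    # deposits must be allowed to accumulate across steps)
    if p.slime_enabled:
        decay(world.slime, dt, p, prune=False)
        for a in world.agents:
            deposit(world.slime, a, dt, p)
        # 3. trail sensing at the sensing cadence (along the body
        # tangent: trails, not turn targets, set the reference frame)
        if gstep % _sense_stride(p) == 0:
            for i, a in enumerate(world.agents):
                e_h = a.heading(L)
                res = sense_trail(world.slime, a.positions[0], e_h,
                                  _FixedU(tie_uniform(i, gstep)), p)
                if res is None:
                    world.sense_has[i] = 0
                else:
                    world.sense_has[i] = 1
                    world.sense_es[i] = res[0]
                    world.sense_sloc[i] = res[1]

    # 4. forces
    forces = np.zeros((M, p.N, 2))
    strong = np.zeros(M, dtype=bool)
    for i, a in enumerate(world.agents):
        # a sensed trail suppresses the turn override (orientation
        # memory) and lubricates the head
        on_trail = bool(p.slime_enabled and world.sense_has[i])
        strong[i] = on_trail
        if overrides[i] is not None and not strong[i]:
            e_h = overrides[i]
        else:
            e_h = a.heading(L)
        f = mechanics.linear_spring_forces(a, p, L).total()
        f += mechanics.bending_forces(a, p, L).total()
        prop = mechanics.propulsion_forces(a, e_h, p, L).total()
        if on_trail:
            F_s, F_c = steering_split(world.sense_es[i], e_h,
                                      world.sense_sloc[i], p)
            prop[0] = F_s + F_c
        f += prop
        fa, new_anchors = mechanics.substrate_adhesion(a, p, L)
        a.anchors = new_anchors
        f += fa.total()
        forces[i] = f
    forces += mechanics.excluded_volume_forces(world).total()
    if p.adhesion_enabled:
        forces += mechanics.lateral_adhesion_forces(world).total()

    # 5. overdamped integration; the head node's transverse mobility is
    # reduced by head_drag_factor (nascent-adhesion friction) except on
    # a dominant trail, which acts as a low-resistance path
    for i, a in enumerate(world.agents):
        v = forces[i] / p.c_w
        chi = 1.0 if strong[i] else p.head_drag_factor
        t0h = a.heading(L)
        f_ax = np.dot(forces[i][0], t0h) * t0h
        f_lat = forces[i][0] - f_ax
        v[0] = (f_ax + f_lat / chi) / p.c_w
        a.velocities = v
        a.positions = a.positions + v * dt
        if not np.all(np.isfinite(a.positions)):
            raise RuntimeError(
                f"non-finite position for agent {i} at t={world.time:.4f} min")

    # 6.+7. anchor maintenance and wrapping
    for a in world.agents:
        slide_anchors(a, p, L)
        a.positions %= L
        mask = ~np.isnan(a.anchors)
        a.anchors[mask] %= L

    world.time += dt
    world.step_index += 1
    return world


# ----------------------------------------------------------------------
# kernel-driven run
# ----------------------------------------------------------------------

def _pack_params(p: ModelParams):
    P = np.array([
        p.L_sim, p.l0, p.W_c, p.kl_w, p.kb_w, p.Fp_w, p.c_w, p.ka_w,
        p.Famax_w, p.k_ev_w, p.tau_r, p.tau_t, p.turn_duration,
        p.turn_angle_rad, p.eps_s, p.S_r, p.k_d, p.S_thr, p.S0_ref,
        p.sector_accept_frac, p.dt, p.L_sim / p.grid_n, p.L_c / 2.0,
        p.k_adh * p.FT_w / p.N, p.d_thr, p.head_drag_factor,
    ])
    iflags = np.array([
        1 if p.reversals_enabled else 0,
        1 if p.turns_enabled else 0,
        1 if p.slime_enabled else 0,
        1 if p.adhesion_enabled else 0,
        p.n_sectors, _sense_stride(p), p.grid_n, _contact_grid_n(p),
    ], dtype=np.int64)
    return P, iflags


def _pack_world(world: WorldState):
    M = world.M
    N = world.params.N
    pos = np.stack([a.positions for a in world.agents]).astype(float)
    anchors = np.stack([a.anchors for a in world.agents]).astype(float)
    rev_clock = np.array([a.reversal_clock for a in world.agents])
    turn_clock = np.array([a.turn_clock for a in world.agents])
    turn_active = np.array([1 if a.turn.active else 0 for a in world.agents],
                           dtype=np.uint8)
    turn_dir = np.array([a.turn.direction for a in world.agents],
                        dtype=np.int8)
    turn_left = np.array([a.turn.time_remaining for a in world.agents])
    turn_t = np.zeros((M, 2))
    for i, a in enumerate(world.agents):
        if a.turn.target is not None:
            turn_t[i] = a.turn.target
    polarity = np.array([a.polarity for a in world.agents], dtype=np.int8)
    return (pos, anchors, rev_clock, turn_clock, turn_active, turn_dir,
            turn_left, turn_t, polarity)


def _unpack_world(world: WorldState, pos, anchors, rev_clock, turn_clock,
                  turn_active, turn_dir, turn_left, turn_t, polarity) -> None:
    for i, a in enumerate(world.agents):
        a.positions = pos[i].copy()
        a.anchors = anchors[i].copy()
        a.reversal_clock = float(rev_clock[i])
        a.turn_clock = float(turn_clock[i])
        a.turn = TurnState(active=bool(turn_active[i]),
                           direction=int(turn_dir[i]),
                           time_remaining=float(turn_left[i]),
                           target=turn_t[i].copy() if turn_active[i] else None)
        a.polarity = int(polarity[i])


def _orientations(pos: np.ndarray, L: float) -> np.ndarray:
    d = pos[:, 0, :] - pos[:, -1, :]
    d -= L * np.round(d / L)
    return np.mod(np.arctan2(d[:, 1], d[:, 0]), 2.0 * math.pi)


_EVENT_FIELDS = {"reversals_enabled", "turns_enabled", "slime_enabled",
                 "adhesion_enabled", "tau_r", "tau_t", "eps_s"}


def run_world(world: WorldState, events: Optional[list] = None,
              t_final: Optional[float] = None) -> Trajectory:
    """Advance ``world`` to ``t_final`` recording a snapshot every
    ``snapshot_interval``; ``events`` is a list of ``(time, overrides)``
    applied at snapshot boundaries (flag/timer overrides only)."""
    p0 = world.params
    p = p0
    if t_final is None:
        t_final = p.t_end
    events = sorted(events or [], key=lambda e: e[0])
    for _, ov in events:
        bad = set(ov) - _EVENT_FIELDS
        if bad:
            raise ValueError(f"events may only override {_EVENT_FIELDS}, "
                             f"got {sorted(bad)}")

    (pos, anchors, rev_clock, turn_clock, turn_active, turn_dir, turn_left,
     turn_t, polarity) = _pack_world(world)
    slv = world.slime.values
    slt = np.full_like(slv, world.time)
    P, iflags = _pack_params(p)
    steps_per_chunk = max(1, int(round(p.snapshot_interval / p.dt)))
    n_chunks = int(round((t_final - world.time) / p.snapshot_interval))

    snaps = [Snapshot(world.time, pos.copy(),
                      _orientations(pos, p.L_sim), polarity.copy())]
    ev_i = 0
    t = world.time
    for _ in range(n_chunks):
        while ev_i < len(events) and events[ev_i][0] <= t + 1e-9:
            _kernels.sync_slime(slv, slt, t, p.k_d, p.S_thr)
            p = replace(p, **events[ev_i][1])
            P, iflags = _pack_params(p)
            ev_i += 1
        t = _kernels.integrate_chunk(
            pos, anchors, rev_clock, turn_clock, turn_active, turn_dir,
            turn_left, turn_t[:, 0], turn_t[:, 1], world.turn_u,
            world.turn_idx, polarity, slv, slt,
            world.sense_has, world.sense_es, world.sense_sloc,
            P, iflags, steps_per_chunk, world.step_index, t)
        world.step_index += steps_per_chunk
        if not np.isfinite(pos).all():
            bad = int(np.argwhere(~np.isfinite(pos))[0, 0])
            raise RuntimeError(
                f"non-finite position for agent {bad} at t={t:.4f} min "
                f"(instability: reduce dt or stiffness)")
        snaps.append(Snapshot(t, pos.copy(), _orientations(pos, p.L_sim),
                              polarity.copy()))

    _kernels.sync_slime(slv, slt, t, p.k_d, p.S_thr)
    _unpack_world(world, pos, anchors, rev_clock, turn_clock, turn_active,
                  turn_dir, turn_left, turn_t, polarity)
    world.time = t
    world.params = p
    return Trajectory(snapshots=snaps, params=p0, events=events)


def run(p: ModelParams, events: Optional[list] = None) -> Trajectory:
    """Simulate a full run from scratch: validate, initialize, integrate.

    Returns the per-minute snapshot trajectory (t = 0 included). A run is
    a pure function of (params, seed).
    """
    p = validate_params(p)
    world = initialize_world(p)
    return run_world(world, events=events)


# ----------------------------------------------------------------------
# trajectory I/O (HDF5)
# ----------------------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["params_yaml"] = traj.params.to_yaml()
        f.attrs["n_snapshots"] = len(traj.snapshots)
        if traj.events:
            f.attrs["events"] = repr(traj.events)
        for k, s in enumerate(traj.snapshots):
            g = f.create_group(f"snapshots/{k}")
            g.attrs["time"] = s.time
            g.create_dataset("positions", data=s.positions,
                             compression="gzip")
            g.create_dataset("orientations", data=s.orientations)
            g.create_dataset("polarity", data=s.polarity)


def load_trajectory(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        p = ModelParams.from_yaml(f.attrs["params_yaml"])
        snaps = []
        for k in range(int(f.attrs["n_snapshots"])):
            g = f[f"snapshots/{k}"]
            snaps.append(Snapshot(float(g.attrs["time"]),
                                  g["positions"][...],
                                  g["orientations"][...],
                                  g["polarity"][...]))
    return Trajectory(snapshots=snaps, params=p)
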