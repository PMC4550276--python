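"""Shared domain types and the validated parameter set.

Unit conventions (fixed; there is no unit-system abstraction):

* lengths in micrometres (μm), times in minutes (min);
* mechanical constants are *configured* in SI, as customary in the
  gliding-motility literature (spring constants N/m, bending stiffness
  N·m, forces N, drag N·s/m);
* all force computation happens in "working units" pN / μm / min, exposed
  through the read-only properties ``kl_w``, ``kb_w`` ... of
  :class:`ModelParams`.

Conversion factors: 1 N/m = 1e6 pN/μm, 1 N·m = 1e18 pN·μm, 1 N = 1e12 pN,
1 N·s/m = 1e6/60 pN·min/μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Vec2",
    "vec2",
    "unit",
    "rotate",
    "perp",
    "ModelParams",
    "TurnState",
    "AgentState",
    "WorldState",
    "validate_params",
    "agent_count",
]

# ----------------------------------------------------------------------
# Vec2: plain 2-element float arrays; helpers only.
# ----------------------------------------------------------------------

Vec2 = np.ndarray  # shape (2,), float64


def vec2(x: float, y: float) -> Vec2:
    return np.array([float(x), float(y)])


def unit(v: Vec2) -> Vec2:
    n = math.hypot(v[0], v[1])
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def rotate(v: Vec2, angle: float) -> Vec2:
    """Rotate ``v`` by ``angle`` radians (CCW positive)."""
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def perp(v: Vec2) -> Vec2:
    """90° CCW rotation."""
    return np.array([-v[1], v[0]])


# head-on compression overlap fraction fixing the contact stiffness
_EV_OVERLAP_FRAC = 0.046

# unit conversions (SI -> working units)
_NPM_TO_PNPUM = 1e6          # N/m      -> pN/μm
_NM_TO_PNUM = 1e18           # N·m      -> pN·μm
_N_TO_PN = 1e12              # N        -> pN
_NSPM_TO_PNMINPUM = 1e6 / 60.0   # N·s/m -> pN·min/μm


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

@dataclass
class ModelParams:
    """Complete parameter set for one simulation run.

    Defaults correspond to the standard operating point: flexible 7-node
    cells of length 5 μm gliding at 4 μm/min, reversing every 8 min with
    90° turn noise every 5 min, following slime trails of length 11 μm
    with full effectiveness, at area fraction 0.24 in a 100 μm periodic
    box.
    """

    # geometry / discretization
    N: int = 7                       # nodes per agent
    L_c: float = 5.0                 # cell length, μm
    W_c: float = 0.5                 # cell width (capsule diameter), μm

    # mechanics (SI at this surface)
    k_l: float = 2e-4                # linear spring constant, N/m
    k_b: float = 1e-17               # bending stiffness, N·m
    F_T: float = 30e-12              # total propulsion force per cell, N
    c: Optional[float] = None        # per-node drag, N·s/m (derived if None)
    k_a: float = 2e-4                # substrate-adhesion spring constant, N/m
    F_a_max: float = 50e-12          # adhesion breaking force, N
    head_drag_factor: float = 25.0   # transverse drag multiplier of the
    #                                  head node on bare substrate
    #                                  (nascent-adhesion friction; wet
    #                                  slime restores full mobility)

    # reversals
    tau_r: float = 8.0               # reversal period, min
    reversals_enabled: bool = True

    # turn noise
    tau_t: float = 5.0               # turn-event interval, min
    turn_duration: float = 1.0       # min
    turn_angle: float = 90.0         # degrees at this surface
    turns_enabled: bool = True

    # slime
    eps_s: float = 1.0               # slime effectiveness factor, 0–1
    S_r: float = 1.0                 # slime production rate, volume/min
    k_d: float = 1.0                 # slime degradation constant, 1/min
    L_s: Optional[float] = 11.0      # target trail length, μm; when set,
    #                                  (S_r, k_d) are rescaled to hit it
    S_thr: float = 0.01              # wet-slime detection threshold (volume)
    n_sectors: int = 5               # slime search bins (odd)
    sector_accept_frac: float = 0.8
    slime_enabled: bool = True

    # lateral cell-cell adhesion (off in the baseline model)
    k_adh: float = 2.8               # dimensionless
    d_thr: float = 0.75              # lateral adhesion cutoff, μm
    adhesion_enabled: bool = False

    # run / domain
    eta: float = 0.24                # target area fraction
    L_sim: float = 100.0             # domain edge length, μm
    v_c: float = 4.0                 # free-glide speed, μm/min
    dt: float = 8e-4                 # integration step, min
    t_end: float = 180.0             # run length, min
    snapshot_interval: float = 1.0   # min
    seed: int = 0

    _validated: bool = field(default=False, repr=False, compare=False)

    # ---- derived quantities (working units) ------------------------------

    @property
    def l0(self) -> float:
        """Rest length of one internode spring, μm."""
        return self.L_c / (self.N - 1)

    @property
    def kl_w(self) -> float:
        return self.k_l * _NPM_TO_PNPUM

    @property
    def kb_w(self) -> float:
        return self.k_b * _NM_TO_PNUM

    @property
    def FT_w(self) -> float:
        return self.F_T * _N_TO_PN

    @property
    def ka_w(self) -> float:
        return self.k_a * _NPM_TO_PNPUM

    @property
    def Famax_w(self) -> float:
        return self.F_a_max * _N_TO_PN


    @property
    def c_w(self) -> float:
        if self.c is None:
            # calibrated so a free glider runs at v_c: F_T = N·c·v_c
            return self.FT_w / (self.N * self.v_c)
        return self.c * _NSPM_TO_PNMINPUM

    @property
    def k_ev_w(self) -> float:
        """Excluded-volume penalty stiffness, pN/μm.

        Tied to the propulsion scale so that a head-on two-cell
        compression at full F_T equilibrates at 4.6% of W_c overlap
        (< the 5% bound) for any propulsion strength; because the drag
        coefficient is calibrated to F_T as well, the stability limit
        c/k_ev ≈ 0.046·W_c/(N·v_c) is independent of F_T and admits the
        default dt.
        """
        return self.FT_w / (_EV_OVERLAP_FRAC * self.W_c)

    @property
    def Fp_w(self) -> float:
        """Per-node propulsion magnitude F_T/(N−1), pN."""
        return self.FT_w / (self.N - 1)

    @property
    def turn_angle_rad(self) -> float:
        return math.radians(self.turn_angle)

    @property
    def M(self) -> int:
        """Number of agents implied by (eta, L_sim, L_c, W_c)."""
        return agent_count(self.eta, self.L_sim, self.L_c, self.W_c)

    @property
    def grid_n(self) -> int:
        """Slime/visit grid resolution (element width ≈ W_c)."""
        return max(1, int(round(self.L_sim / self.W_c)))

    @property
    def S0_ref(self) -> float:
        """Reference fresh-deposit volume: slime laid in one element during
        one crossing, S_τ1 = (1 − exp(−k_d·τ1))·S_r/k_d with τ1 = W_c/v_c."""
        tau1 = self.W_c / self.v_c
        return (1.0 - math.exp(-self.k_d * tau1)) * self.S_r / self.k_d

    @property
    def dt_max(self) -> float:
        """Stability bound for explicit overdamped Euler, min.

        The factor 2 on k_l covers the stiffest normal mode of the spring
        chain (eigenvalue 4·k_l → dt < 2c/(4·k_l)); contact and adhesion
        springs act per node (one-sided, barycentric-split contacts), for
        which c/k is already conservative.
        """
        return self.c_w / max(2.0 * self.kl_w, self.k_ev_w, self.ka_w)

    # ---- serialization ---------------------------------------------------

    _YAML_EXCLUDE = ("_validated",)

    def to_yaml(self) -> str:
        d = {}
        for f in fields(self):
            if f.name in self._YAML_EXCLUDE:
                continue
            v = getattr(self, f.name)
            d[f.name] = v
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParams":
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError("parameter YAML must be a flat mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)} - set(cls._YAML_EXCLUDE)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


def agent_count(eta: float, L_sim: float, L_c: float, W_c: float) -> int:
    """Number of agents M = round(η·L_sim² / (L_c·W_c)), at least 1.

    The cell footprint is taken as the L_c×W_c rectangle; η is a nominal
    density dial, not an exact covered fraction.
    """
    if min(eta, L_sim, L_c, W_c) <= 0:
        raise ValueError("agent_count arguments must be positive")
    if eta >= 1:
        raise ValueError("eta out of (0,1)")
    return max(1, int(round(eta * L_sim * L_sim / (L_c * W_c))))


def _fail(name: str, msg: str) -> None:
    raise ValueError(f"{name}: {msg}")


def validate_params(p: ModelParams) -> ModelParams:
    """Validate every invariant; derive dependent defaults.

    Returns a validated copy (idempotent). Raises ``ValueError`` naming the
    first violated invariant. Derivations performed here:

    * drag coefficient ``c`` from the free-glide calibration F_T = N·c·v_c
      when unset;
    * ``(S_r, k_d)`` rescaled to hit the target trail length ``L_s`` when
      ``L_s`` is set (see :func:`myxosim.slime.rate_for_trail_length`).
    """
    if p.N < 3:
        _fail("N", "node count must be ≥ 3")
    if not (0.0 <= p.eps_s <= 1.0):
        _fail("eps_s", "out of [0,1]")
    if not (0.0 < p.S_thr < 1.0):
        _fail("S_thr", "out of (0,1)")
    for name in ("L_c", "W_c", "k_l", "k_b", "F_T", "k_a", "F_a_max",
                 "S_r", "k_d", "k_adh", "v_c", "t_end",
                 "snapshot_interval"):
        if getattr(p, name) <= 0:
            _fail(name, "must be strictly positive")
    if p.c is not None and p.c <= 0:
        _fail("c", "must be strictly positive")
    if p.d_thr <= p.W_c:
        _fail("d_thr", f"d_thr ≤ W_c ({p.d_thr} ≤ {p.W_c}); the adhesion "
                       "ramp W_c ≤ d⊥ < d_thr would be empty")
    if not (0.0 < p.eta < 1.0):
        _fail("eta", "out of (0,1)")
    if p.L_sim <= p.L_c:
        _fail("L_sim", "domain must exceed one cell length")
    if p.dt <= 0:
        _fail("dt", "must be strictly positive")
    if p.tau_r <= 0 or p.tau_t <= 0 or p.turn_duration <= 0:
        _fail("tau_r/tau_t/turn_duration", "must be strictly positive")
    if p.tau_t <= p.turn_duration:
        _fail("tau_t", "turn interval must exceed turn duration "
                       "(turn events must not overlap)")
    if p.head_drag_factor < 1.0:
        _fail("head_drag_factor", "must be ≥ 1 (head cannot be slipperier "
                                  "than the body)")
    if p.n_sectors < 3 or p.n_sectors % 2 == 0:
        _fail("n_sectors", "must be odd and ≥ 3 (central bin on the heading)")
    if not (0.0 < p.sector_accept_frac <= 1.0):
        _fail("sector_accept_frac", "out of (0,1]")
    if p.L_s is not None and p.L_s <= 0:
        _fail("L_s", "target trail length must be positive")

    out = p
    if out.c is None:
        c_si = (out.FT_w / (out.N * out.v_c)) / _NSPM_TO_PNMINPUM
        out = replace(out, c=c_si)
    if out.L_s is not None:
        from .slime import rate_for_trail_length, trail_length
        try:
            solved = abs(trail_length(out) - out.L_s) <= 1.1e-3
        except ValueError:
            solved = False
        if not solved:                # idempotent: skip when already on target
            sr, kd = rate_for_trail_length(out.L_s, out)
            out = replace(out, S_r=sr, k_d=kd)

    if out.dt > out.dt_max * (1 + 1e-9):
        _fail("dt", f"exceeds overdamped stability bound "
                    f"c/max(k) = {out.dt_max:.3e} min")
    out = replace(out, _validated=True)
    return out


# ----------------------------------------------------------------------
# State containers
# ----------------------------------------------------------------------

@dataclass
class TurnState:
    """State of the stochastic 90° turn event of one agent.

    ``target`` is the lab-frame unit direction the head propulsion is
    steered toward during the event: the heading at event onset rotated
    by ``direction``·turn_angle. Steering toward a fixed target produces
    a net ≈90° course change per event.
    """
    active: bool = False
    direction: int = 0           # +1 CCW, −1 CW
    time_remaining: float = 0.0  # min
    target: Optional[np.ndarray] = None  # unit Vec2, lab frame


@dataclass
class AgentState:
    """One flexible cell: an ordered chain of N nodes, head at index 0.

    A reversal reverses the node order in place (positions are untouched,
    only the labelling flips). The end nodes carry no substrate anchor
    (the head's nascent adhesions are modeled as transverse viscous drag
    instead); absent anchors are NaN rows.
    """
    positions: np.ndarray            # (N, 2) μm
    velocities: np.ndarray           # (N, 2) μm/min
    anchors: np.ndarray              # (N, 2) μm; NaN row = no anchor
    reversal_clock: float = 0.0      # min since last reversal
    turn_clock: float = 0.0          # min since last turn event
    turn: TurnState = field(default_factory=TurnState)
    polarity: int = 1                # flips sign at each reversal
    id: int = 0

    @classmethod
    def straight(cls, center: Vec2, theta: float, p: ModelParams,
                 agent_id: int = 0) -> "AgentState":
        """Straight-line agent with tail→head orientation ``theta``."""
        u = np.array([math.cos(theta), math.sin(theta)])
        k = np.arange(p.N)[:, None]
        pos = center[None, :] + (p.L_c / 2.0 - k * p.l0) * u[None, :]
        anchors = pos.copy()
        anchors[0] = np.nan          # leading pole: nascent adhesions act
        anchors[p.N - 1] = np.nan    # as viscous drag, not a spring
        return cls(positions=pos, velocities=np.zeros((p.N, 2)),
                   anchors=anchors, id=agent_id)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def orientation(self, L_box: Optional[float] = None) -> float:
        """Angle of the tail→head vector with the x-axis, in [0, 2π)."""
        d = self.positions[0] - self.positions[-1]
        if L_box is not None:
            d = d - L_box * np.round(d / L_box)
        return math.atan2(d[1], d[0]) % (2.0 * math.pi)

    def heading(self, L_box: Optional[float] = None) -> Vec2:
        """Unit head-node tangent ê_h (node 2 → node 1)."""
        d = self.positions[0] - self.positions[1]
        if L_box is not None:
            d = d - L_box * np.round(d / L_box)
        return unit(d)


@dataclass
class WorldState:
    """All agents, the slime field and the clocks of one instant."""
    agents: list                     # list[AgentState]
    slime: "object"                  # SlimeField (slime module)
    params: ModelParams
    time: float = 0.0
    rng: np.random.Generator = None
    turn_u: np.ndarray = None        # (M, K) pre-drawn uniforms for turn signs
    turn_idx: np.ndarray = None      # (M,) next index into turn_u
    step_index: int = 0              # integration steps taken
    # slime-sensing cache, refreshed every sense stride (see engine)
    sense_has: np.ndarray = None     # (M,) uint8
    sense_es: np.ndarray = None      # (M, 2) trail directions
    sense_sloc: np.ndarray = None    # (M,) head-element wet volumes

    @property
    def M(self) -> int:
        return len(self.agents)

    def positions_array(self) -> np.ndarray:
        return np.stack([a.positions for a in self.agents])
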