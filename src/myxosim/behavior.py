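"""Per-agent timers and events: periodic reversals and 90° turn noise.

Reversals flip head and tail every τ_r minutes (deterministic timers,
asynchronous across agents). Turn events fire every τ_t minutes and
rotate the head propulsion direction by ±90° for a fixed 1-minute
episode — the model's orientational noise. Timers reset by carrying the
overshoot (clock −= τ) so long-run event frequency is exactly 1/τ
regardless of dt.
"""

from __future__ import annotations

import numpy as np

from .model_core import AgentState, ModelParams, TurnState, rotate

__all__ = ["update_reversal", "update_turn", "init_clocks", "reverse_agent"]

_EPS = 1e-12


def reverse_agent(agent: AgentState) -> AgentState:
    """Flip polarity: reverse node order in place; positions untouched.

    Both end nodes are unanchored (the new head's nascent adhesions act
    as transverse friction, the new tail sheds its anchor), so a flip
    just reverses the arrays: interior anchors ride along.
    """
    agent.positions = agent.positions[::-1].copy()
    agent.velocities = agent.velocities[::-1].copy()
    agent.anchors = agent.anchors[::-1].copy()
    agent.anchors[0] = np.nan
    agent.anchors[-1] = np.nan
    agent.polarity = -agent.polarity
    return agent


def update_reversal(agent: AgentState, dt: float, p: ModelParams) -> AgentState:
    """Advance the reversal timer; flip head/tail when it expires."""
    if not p.reversals_enabled:
        return agent
    agent.reversal_clock += dt
    if agent.reversal_clock >= p.tau_r - _EPS:
        agent.reversal_clock -= p.tau_r
        reverse_agent(agent)
    return agent


def update_turn(agent: AgentState, dt: float, rng, p: ModelParams):
    """Advance the turn timer; start/continue/end a turn episode.

    Returns ``(agent, heading_override)``: during an active episode the
    head propulsion is steered toward a lab-frame unit direction fixed at
    event onset — the heading at that instant rotated by ±turn_angle
    (episode sign drawn equiprobably from ``rng``) — so each event
    produces a net ≈90° course change; outside an episode the override
    is ``None`` and the head force follows the body tangent.
    """
    if not p.turns_enabled:
        return agent, None
    agent.turn_clock += dt
    if agent.turn_clock >= p.tau_t - _EPS and not agent.turn.active:
        agent.turn_clock -= p.tau_t
        direction = -1 if rng.random() < 0.5 else 1
        target = rotate(agent.heading(p.L_sim),
                        direction * p.turn_angle_rad)
        agent.turn = TurnState(active=True, direction=direction,
                               time_remaining=p.turn_duration,
                               target=target)
    override = None
    if agent.turn.active:
        override = agent.turn.target
        agent.turn.time_remaining -= dt
        if agent.turn.time_remaining <= _EPS:
            agent.turn = TurnState()
    return agent, override


def init_clocks(agent: AgentState, rng, p: ModelParams) -> AgentState:
    """Randomize timer phases: reversal ~ U[0,τ_r), turn ~ U[0,τ_t)."""
    agent.reversal_clock = float(rng.uniform(0.0, p.tau_r))
    agent.turn_clock = float(rng.uniform(0.0, p.tau_t))
    agent.turn = TurnState()
    return agent
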