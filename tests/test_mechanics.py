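"""Force laws checked against independent oracles.

Elastic forces are compared with central finite differences of their
energies (implemented here from the energy definitions, not by calling
package internals); contacts are compared with a dense point-sampling
distance oracle.
"""

import math

import numpy as np
import pytest

from myxosim import AgentState, ModelParams, WorldState, validate_params
from myxosim.mechanics import (bending_forces, capsule_pair_distance,
                               drag_forces, excluded_volume_forces,
                               lateral_adhesion_forces, linear_spring_forces,
                               propulsion_forces, substrate_adhesion)
from myxosim.slime import SlimeField

from conftest import random_chain


def spring_energy(pos, p):
    d = np.diff(pos, axis=0)
    lens = np.linalg.norm(d, axis=1)
    return 0.5 * p.kl_w * np.sum((lens - p.l0) ** 2)


def bend_energy(pos, p):
    e = 0.0
    for j in range(1, len(pos) - 1):
        a = pos[j] - pos[j - 1]
        b = pos[j + 1] - pos[j]
        phi = math.atan2(a[0] * b[1] - a[1] * b[0], a[0] * b[0] + a[1] * b[1])
        e += 0.5 * p.kb_w * phi * phi
    return e


def numeric_gradient(energy, pos, eps=1e-6):
    g = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(2):
            pp = pos.copy()
            pp[i, d] += eps
            pm = pos.copy()
            pm[i, d] -= eps
            g[i, d] = (energy(pp) - energy(pm)) / (2 * eps)
    return g


class TestElasticOracles:
    def test_straight_chain_has_no_elastic_forces(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.3, p)
        assert np.allclose(linear_spring_forces(a, p).total(), 0, atol=1e-9)
        assert np.allclose(bending_forces(a, p).total(), 0, atol=1e-9)

    def test_two_node_hookes_law(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        delta = 0.07
        a.positions = np.array([[0.0, 0.0], [p.l0 + delta, 0.0]])
        a.anchors = np.full((2, 2), np.nan)
        F = linear_spring_forces(a, p).total()
        assert F[0, 0] == pytest.approx(p.kl_w * delta, rel=1e-12)
        assert F[1, 0] == pytest.approx(-p.kl_w * delta, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_forces_match_energy_gradients(self, quiet_params, seed):
        p = quiet_params
        rng = np.random.default_rng(seed)
        a = random_chain(rng, p, bend=0.6)
        for force_fn, energy_fn in [
            (linear_spring_forces, spring_energy),
            (bending_forces, bend_energy),
        ]:
            F = force_fn(a, p).total()
            G = -numeric_gradient(lambda x: energy_fn(x, p), a.positions)
            scale = max(np.abs(F).max(), 1e-12)
            assert np.abs(F - G).max() / scale < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_internal_forces_conserve_momentum(self, quiet_params, seed):
        p = quiet_params
        rng = np.random.default_rng(100 + seed)
        a = random_chain(rng, p, bend=0.8)
        for fn in (linear_spring_forces, bending_forces):
            F = fn(a, p).total()
            assert np.abs(F.sum(axis=0)).max() < 1e-9 * max(np.abs(F).max(), 1)
            r = a.positions - a.positions.mean(axis=0)
            torque = np.sum(r[:, 0] * F[:, 1] - r[:, 1] * F[:, 0])
            assert abs(torque) < 1e-9 * max(np.abs(F).max(), 1)

    def test_coincident_nodes_rejected(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        a.positions[1] = a.positions[0]
        with pytest.raises(ValueError, match="coincident"):
            linear_spring_forces(a, p)


class TestPropulsionAndDrag:
    def test_distributed_propulsion_pattern(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        F = propulsion_forces(a, np.array([1.0, 0.0]), p).total()
        expect = p.FT_w / (p.N - 1)
        for i in range(p.N - 1):
            assert F[i, 0] == pytest.approx(expect, rel=1e-12)
            assert F[i, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(F[p.N - 1], 0.0)          # tail node is passive
        assert np.linalg.norm(F, axis=1).sum() == pytest.approx(
            p.FT_w, rel=1e-12)

    def test_drag_proportional_to_velocity(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        a.velocities[:] = [p.v_c, 0.0]
        F = drag_forces(a, p).total()
        assert np.allclose(F, [-p.c_w * p.v_c, 0.0])


class TestSubstrateAdhesion:
    def _lateral_setup(self, p, lateral):
        # straight chain along +x; offset node 2's anchor purely laterally
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        a.anchors[1:-1] = a.positions[1:-1]
        a.anchors[2, 1] += lateral
        return a

    def test_node_at_anchor_feels_nothing(self, quiet_params):
        p = quiet_params
        a = self._lateral_setup(p, 0.0)
        F, _ = substrate_adhesion(a, p)
        assert np.allclose(F.total(), 0.0)

    def test_below_breaking_force_holds(self, quiet_params):
        p = quiet_params
        d = 49.0 / p.ka_w                      # k_a·d = 49 pN < 50 pN
        a = self._lateral_setup(p, d)
        F, anchors = substrate_adhesion(a, p)
        f = F.total()[2]
        assert np.linalg.norm(f) == pytest.approx(49.0, rel=1e-6)
        assert f[1] > 0                         # pulled toward the anchor
        assert np.allclose(anchors[2], a.positions[2] + [0, d])

    def test_above_breaking_force_detaches_and_reanchors(self, quiet_params):
        p = quiet_params
        d = 51.0 / p.ka_w                      # k_a·d = 51 pN > 50 pN
        a = self._lateral_setup(p, d)
        F, anchors = substrate_adhesion(a, p)
        assert np.allclose(F.total()[2], 0.0)
        assert np.allclose(anchors[2], a.positions[2])

    def test_axial_displacement_is_free(self, quiet_params):
        # adhesions translocate along the gliding axis: no axial force
        p = quiet_params
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, p)
        a.anchors[1:-1] = a.positions[1:-1]
        a.positions[:, 0] += 0.2               # everyone slides forward
        F, _ = substrate_adhesion(a, p)
        assert np.allclose(F.total(), 0.0, atol=1e-12)


def sampled_capsule_distance(pa, pb, n=60):
    """Independent oracle: dense point sampling along both chains."""
    ta = np.linspace(0, 1, n)
    A = np.concatenate([pa[i] + ta[:, None] * (pa[i + 1] - pa[i])
                        for i in range(len(pa) - 1)])
    B = np.concatenate([pb[i] + ta[:, None] * (pb[i + 1] - pb[i])
                        for i in range(len(pb) - 1)])
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return d.min()


class TestExcludedVolume:
    def _world(self, p, agents):
        for i, a in enumerate(agents):
            a.id = i
        return WorldState(agents=agents, slime=SlimeField.empty(p),
                          params=p, rng=np.random.default_rng(0))

    def test_separated_capsules_feel_nothing(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([10.0, 10.0]), 0.0, p)
        b = AgentState.straight(np.array([10.0, 10.0 + 2 * p.W_c]), 0.0, p)
        F = excluded_volume_forces(self._world(p, [a, b])).total()
        assert np.allclose(F, 0.0)

    def test_parallel_overlap_newtons_third_law(self, quiet_params):
        p = quiet_params
        a = AgentState.straight(np.array([10.0, 10.0]), 0.0, p)
        b = AgentState.straight(np.array([10.0, 10.0 + 0.8 * p.W_c]), 0.0, p)
        F = excluded_volume_forces(self._world(p, [a, b])).total()
        assert np.abs(F[0] + F[1]).max() < 1e-9
        assert F[0][:, 1].sum() < 0            # a pushed down, b up
        assert F[1][:, 1].sum() > 0

    @pytest.mark.parametrize("seed", range(20))
    def test_contact_set_matches_sampling_oracle(self, quiet_params, seed):
        """Random small scenes: pairs in contact per the implementation
        equal pairs with capsule distance < W_c per an independent
        point-sampling oracle (ambiguous near-threshold pairs skipped)."""
        p = quiet_params
        rng = np.random.default_rng(seed)
        n_agents = rng.integers(3, 9)
        agents = []
        for i in range(n_agents):
            c = rng.uniform(12, 28, 2)
            a = AgentState.straight(c, rng.uniform(0, 2 * np.pi), p, agent_id=i)
            agents.append(a)
        world = self._world(p, agents)
        fs = excluded_volume_forces(world).total()
        for i in range(n_agents):
            for j in range(i + 1, n_agents):
                d_oracle = sampled_capsule_distance(
                    agents[i].positions, agents[j].positions)
                if abs(d_oracle - p.W_c) < 0.02:
                    continue
                d_impl = capsule_pair_distance(agents[i], agents[j], p)
                assert (d_impl < p.W_c) == (d_oracle < p.W_c)

    def test_pair_distance_matches_sampling(self, quiet_params):
        p = quiet_params
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = AgentState.straight(rng.uniform(10, 30, 2),
                                    rng.uniform(0, 2 * np.pi), p)
            b = AgentState.straight(rng.uniform(10, 30, 2),
                                    rng.uniform(0, 2 * np.pi), p)
            assert capsule_pair_distance(a, b, p) == pytest.approx(
                sampled_capsule_distance(a.positions, b.positions), abs=1e-3)


class TestLateralAdhesion:
    def _pair_world(self, p, gap):
        a = AgentState.straight(np.array([10.0, 10.0]), 0.0, p)
        b = AgentState.straight(np.array([10.0, 10.0 + gap]), 0.0, p)
        b.id = 1
        return WorldState(agents=[a, b], slime=SlimeField.empty(p),
                          params=p, rng=np.random.default_rng(0))

    @pytest.mark.parametrize("gap,expect_frac", [
        (0.75, 0.0),                            # at the cutoff: zero
        (0.5, 0.0),                             # at contact: ramp bottom
        (0.625, 0.5),                           # ramp midpoint
    ])
    def test_ramp_values(self, gap, expect_frac):
        p = validate_params(ModelParams(
            L_sim=40.0, adhesion_enabled=True, reversals_enabled=False,
            turns_enabled=False, slime_enabled=False))
        world = self._pair_world(p, gap)
        F = lateral_adhesion_forces(world).total()
        fmax = p.k_adh * p.FT_w / p.N
        got = np.linalg.norm(F[0], axis=1).max()
        assert got == pytest.approx(expect_frac * fmax, abs=1e-9)

    def test_attraction_points_toward_neighbour(self):
        p = validate_params(ModelParams(
            L_sim=40.0, adhesion_enabled=True, reversals_enabled=False,
            turns_enabled=False, slime_enabled=False))
        world = self._pair_world(p, 0.6)
        F = lateral_adhesion_forces(world).total()
        assert F[0][:, 1].sum() > 0             # a attracted upward toward b
        assert F[1][:, 1].sum() < 0
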