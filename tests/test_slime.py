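"""Slime field: deposition, drying, sensing, steering, trail length."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myxosim import AgentState, ModelParams, validate_params
from myxosim.model_core import rotate
from myxosim.slime import (SlimeField, decay, deposit, rate_for_trail_length,
                           sense_trail, steering_split, trail_length)


class _U:
    def __init__(self, u):
        self.u = u

    def random(self):
        return self.u


@pytest.fixture
def sp():
    return validate_params(ModelParams(
        L_sim=40.0, slime_enabled=True, reversals_enabled=False,
        turns_enabled=False, L_s=None, S_r=1.0, k_d=1.0))


class TestDeposit:
    def test_rate_times_time(self, sp):
        f = SlimeField.empty(sp)
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, sp)
        for _ in range(100):
            deposit(f, a, sp.dt, sp)
        assert f.total() == pytest.approx(100 * sp.S_r * sp.dt, rel=1e-9)
        i, j = f.element_index(a.positions[-1])
        assert f.values[i, j] == f.total()      # all in the tail's element

    def test_two_agents_add(self, sp):
        f = SlimeField.empty(sp)
        a = AgentState.straight(np.array([20.0, 20.0]), 0.0, sp)
        b = AgentState.straight(np.array([20.0, 20.0]), 0.0, sp)
        deposit(f, a, sp.dt, sp)
        deposit(f, b, sp.dt, sp)
        i, j = f.element_index(a.positions[-1])
        assert f.values[i, j] == pytest.approx(2 * sp.S_r * sp.dt)

    def test_moving_agent_lays_contiguous_trail(self, sp):
        from myxosim import engine
        from myxosim.io_cli import make_fixture

        w = make_fixture("single_glider", sp)
        engine.run_world(w, t_final=3.0)
        wet = w.slime.values >= sp.S_thr
        rows = np.unique(np.argwhere(wet)[:, 1])
        assert len(rows) == 1                   # one element wide
        cols = np.sort(np.argwhere(wet)[:, 0])
        assert np.all(np.diff(cols) == 1)       # contiguous


class TestDecay:
    def test_zero_rate_is_identity(self, sp):
        f = SlimeField.empty(sp)
        f.values[3, 3] = 1.0
        import dataclasses
        p0 = dataclasses.replace(sp, k_d=1e-300, _validated=True)
        decay(f, 5.0, p0)
        assert f.values[3, 3] == pytest.approx(1.0)

    def test_one_percent_after_ln100_over_kd(self, sp):
        f = SlimeField.empty(sp)
        f.values[3, 3] = 1.0
        decay(f, math.log(100.0) / sp.k_d, sp, prune=False)
        assert f.values[3, 3] == pytest.approx(0.01, rel=1e-12)
        decay(f, 0.0, sp, prune=True)           # 0.01 < S_thr? equal: kept
        f.values[3, 3] = 0.99 * sp.S_thr
        decay(f, 0.0, sp, prune=True)
        assert f.values[3, 3] == 0.0            # sub-threshold pruned

    def test_semigroup_property(self, sp):
        f1 = SlimeField.empty(sp)
        f2 = SlimeField.empty(sp)
        f1.values[1, 1] = f2.values[1, 1] = 2.5
        decay(f1, 1.0, sp, prune=False)
        decay(f2, 0.5, sp, prune=False)
        decay(f2, 0.5, sp, prune=False)
        assert f1.values[1, 1] == pytest.approx(f2.values[1, 1], rel=1e-12)


def brute_sector_sums(field, head, e_h, p):
    """Independent oracle: accumulate every grid element of the whole
    field into sectors by its center's polar angle."""
    n = p.n_sectors
    sums = np.zeros(n)
    maxs = np.zeros(n)
    G = field.G
    w = field.width
    for i in range(G):
        for j in range(G):
            S = field.values[i, j]
            if S < p.S_thr:
                continue
            # minimum-image center offset
            rel = np.array([(i + 0.5) * w - head[0], (j + 0.5) * w - head[1]])
            rel -= field.L * np.round(rel / field.L)
            # exclude the head's own element
            if (i, j) == field.element_index(head):
                continue
            if rel @ rel > (p.L_c / 2) ** 2 or rel @ e_h <= 0:
                continue
            ang = math.atan2(e_h[0] * rel[1] - e_h[1] * rel[0], rel @ e_h)
            b = min(max(int((ang + math.pi / 2) / (math.pi / n)), 0), n - 1)
            sums[b] += S
            maxs[b] = max(maxs[b], S)
    return sums, maxs


class TestSenseTrail:
    def test_empty_field_returns_none(self, sp):
        f = SlimeField.empty(sp)
        assert sense_trail(f, np.array([20.0, 20.0]),
                           np.array([1.0, 0.0]), _U(0.5), sp) is None

    def test_straight_trail_ahead_selects_central_sector(self, sp):
        f = SlimeField.empty(sp)
        j = f.element_index(np.array([20.0, 20.25]))[1]
        for i in range(42, 48):
            f.values[i, j] = 1.0
        e_s, s_loc = sense_trail(f, np.array([20.0, 20.25]),
                                 np.array([1.0, 0.0]), _U(0.5), sp)
        assert np.allclose(e_s, [1.0, 0.0], atol=1e-12)
        assert s_loc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_selection_matches_brute_oracle(self, sp, seed):
        rng = np.random.default_rng(seed)
        f = SlimeField.empty(sp)
        idx = rng.integers(30, 55, size=(25, 2))
        f.values[idx[:, 0], idx[:, 1]] = rng.uniform(0.005, 2.0, 25)
        head = np.array([20.0, 20.0]) + rng.uniform(-1, 1, 2)
        e_h = rotate(np.array([1.0, 0.0]), rng.uniform(0, 2 * np.pi))
        res = sense_trail(f, head, e_h, _U(0.3), sp)
        sums, maxs = brute_sector_sums(f, head, e_h, sp)
        if sums.max() <= 0:
            assert res is None
            return
        # the chosen sector satisfies the acceptance + least-deviation rule
        n = sp.n_sectors
        centers = -math.pi / 2 + (np.arange(n) + 0.5) * math.pi / n
        e_s, s_loc = res
        ang = math.atan2(e_h[0] * e_s[1] - e_h[1] * e_s[0], e_h @ e_s)
        b = int(np.argmin(np.abs(centers - ang)))
        assert sums[b] >= sp.sector_accept_frac * sums.max() - 1e-9
        qual = sums >= sp.sector_accept_frac * sums.max() - 1e-12
        assert abs(centers[b]) <= np.abs(centers[qual]).min() + 1e-9
        assert s_loc == pytest.approx(maxs[b])

    def test_rotation_equivariance(self, sp):
        # rotating field and heading by 90° rotates the answer by 90°
        f = SlimeField.empty(sp)
        rng = np.random.default_rng(3)
        idx = rng.integers(38, 46, size=(12, 2))
        vals = rng.uniform(0.05, 1.0, 12)
        f.values[idx[:, 0], idx[:, 1]] = vals
        G = f.G
        f90 = SlimeField.empty(sp)
        c = np.array([20.0, 20.0])
        # rotate the field by 90° about the domain center (grid-exact)
        for (i, j), v in zip(idx, vals):
            f90.values[(G - 1 - j) % G, i] = v
        head = np.array([20.0, 18.5])
        e_h = np.array([0.0, 1.0])
        head90 = c + rotate(head - c, math.pi / 2)
        r1 = sense_trail(f, head, e_h, _U(0.2), sp)
        r2 = sense_trail(f90, head90, rotate(e_h, math.pi / 2), _U(0.2), sp)
        assert (r1 is None) == (r2 is None)
        if r1 is not None:
            assert np.allclose(rotate(r1[0], math.pi / 2), r2[0], atol=1e-9)
            assert r1[1] == pytest.approx(r2[1])

    def test_symmetric_tie_broken_by_rng(self, sp):
        f = SlimeField.empty(sp)
        head = np.array([20.25, 20.25])
        e_h = np.array([1.0, 0.0])
        # two mirror elements straight up-left / down-left of the heading
        i0, j0 = f.element_index(head)
        f.values[i0 + 2, j0 + 3] = 1.0
        f.values[i0 + 2, j0 - 3] = 1.0
        up, _ = sense_trail(f, head, e_h, _U(0.9), sp)
        dn, _ = sense_trail(f, head, e_h, _U(0.1), sp)
        assert up[1] * dn[1] < 0                # opposite-side sectors


class TestSteeringSplit:
    def test_zero_effectiveness(self, sp):
        import dataclasses
        p0 = dataclasses.replace(sp, eps_s=0.0, _validated=True)
        F_s, F_c = steering_split(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                                  p0.S0_ref, p0)
        assert np.allclose(F_s, 0.0)
        assert np.allclose(F_c, [p0.Fp_w, 0.0])

    def test_full_capture(self, sp):
        F_s, F_c = steering_split(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                                  sp.S0_ref, sp)
        assert np.linalg.norm(F_s) == pytest.approx(sp.Fp_w)
        assert np.allclose(F_c, 0.0)

    def test_stacked_deposits_clamped(self, sp):
        F_s, _ = steering_split(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                                10 * sp.S0_ref, sp)
        assert np.linalg.norm(F_s) == pytest.approx(sp.eps_s * sp.Fp_w)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(eps=st.floats(0.0, 1.0), s=st.floats(0.0, 5.0))
    def test_component_magnitudes_sum_to_head_propulsion(self, eps, s):
        import dataclasses
        p = validate_params(ModelParams(L_sim=40.0, L_s=None))
        p = dataclasses.replace(p, eps_s=eps, _validated=True)
        F_s, F_c = steering_split(np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                                  s * p.S0_ref, p)
        total = np.linalg.norm(F_s) + np.linalg.norm(F_c)
        assert total == pytest.approx(p.Fp_w, rel=1e-9)


class TestTrailLength:
    def test_boundary_is_zero_length(self):
        # S_tau1 == S_thr -> ln(1) = 0
        p = validate_params(ModelParams(L_sim=40.0, L_s=None, S_r=1.0, k_d=1.0))
        tau1 = p.W_c / p.v_c
        s_tau1 = (1 - math.exp(-p.k_d * tau1)) * p.S_r / p.k_d
        import dataclasses
        p_edge = dataclasses.replace(p, S_thr=s_tau1 * (1 + 1e-9),
                                     _validated=True)
        with pytest.raises(ValueError, match="trail"):
            trail_length(p_edge)

    def test_joint_rate_scaling_shortens_trails(self):
        import dataclasses
        p = validate_params(ModelParams(L_sim=40.0, L_s=None, S_r=1.0, k_d=1.0))
        base = trail_length(p)
        p2 = dataclasses.replace(p, S_r=2.0, k_d=2.0, _validated=True)
        assert trail_length(p2) < base
        # steady total volume S_r/k_d is invariant under the joint scaling
        assert p2.S_r / p2.k_d == p.S_r / p.k_d

    @pytest.mark.parametrize("target", [11.0, 0.16, 2.0])
    def test_rate_solver_round_trip(self, target):
        import dataclasses
        p = validate_params(ModelParams(L_sim=40.0, L_s=None, S_r=1.0, k_d=1.0))
        sr, kd = rate_for_trail_length(target, p)
        p2 = dataclasses.replace(p, S_r=sr, k_d=kd, _validated=True)
        assert trail_length(p2) == pytest.approx(target, abs=1e-3)

    def test_scale_factor_monotone_decreasing_in_target(self):
        p = validate_params(ModelParams(L_sim=40.0, L_s=None, S_r=1.0, k_d=1.0))
        fs = [rate_for_trail_length(t, p)[0] for t in (0.2, 1.0, 5.0, 11.0)]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_unreachable_target_raises(self):
        p = validate_params(ModelParams(L_sim=40.0, L_s=None, S_r=1.0, k_d=1.0))
        with pytest.raises(ValueError, match="unreachable"):
            rate_for_trail_length(1e4, p)

    def test_single_glider_wet_trail_matches_closed_form(self):
        from myxosim import engine
        from myxosim.io_cli import make_fixture

        p = validate_params(ModelParams(
            L_sim=60.0, t_end=8.0, reversals_enabled=False,
            turns_enabled=False, slime_enabled=True, L_s=11.0))
        w = make_fixture("single_glider", p)
        engine.run_world(w, t_final=8.0)
        wet = np.argwhere(w.slime.values >= p.S_thr)
        j = int(np.bincount(wet[:, 1]).argmax())
        row = wet[wet[:, 1] == j][:, 0]
        span = (row.max() - row.min() + 1) * w.slime.width
        assert span == pytest.approx(trail_length(p), abs=w.slime.width)
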