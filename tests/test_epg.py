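"""EPG engine: closed forms, unitarity, and the Bloch-ensemble equivalence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dscflair.epg import (
    EPGState,
    bloch_ensemble_oracle,
    epg_cost_and_grad,
    epg_evolve,
    epg_rf,
    epg_shift,
    forward_model,
    simulate_echo_train,
    target_signal,
)
from dscflair.sequence import build_base_train


def _norm(state):
    """Quadratic invariant of the per-order RF rotation."""
    return (np.abs(state.Fplus) ** 2 + np.abs(state.Fminus) ** 2
            + 2 * np.abs(state.Z) ** 2).sum()


class TestSingleOperators:
    def test_zero_flip_is_identity(self):
        s = EPGState.equilibrium(4)
        s.Fplus[2] = 0.3 + 0.1j
        out = epg_rf(s, 0.0, 37.0)
        assert np.allclose(out.Fplus, s.Fplus)
        assert np.allclose(out.Z, s.Z)

    def test_inversion_closed_form(self):
        s = EPGState.equilibrium(4)
        out = epg_rf(s, 180.0, 0.0)
        assert out.Z[0] == pytest.approx(-1.0)
        assert np.allclose(out.Fplus, 0.0, atol=1e-15)

    def test_excitation_closed_form(self):
        s = EPGState.equilibrium(4)
        out = epg_rf(s, 90.0, 90.0)
        assert abs(out.Fplus[0]) == pytest.approx(1.0)
        assert abs(out.Z[0]) == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(-360, 360), st.floats(-180, 180))
    def test_rf_rotation_preserves_quadratic_norm(self, alpha, phi):
        rng = np.random.default_rng(7)
        s = EPGState.equilibrium(5)
        s.Fplus = rng.normal(size=6) + 1j * rng.normal(size=6)
        s.Fminus = rng.normal(size=6) + 1j * rng.normal(size=6)
        s.Z = rng.normal(size=6) + 1j * rng.normal(size=6)
        out = epg_rf(s, alpha, phi)
        assert _norm(out) == pytest.approx(_norm(s), rel=1e-12)

    def test_evolve_identity_at_zero_dt(self):
        s = EPGState.equilibrium(3)
        s.Fplus[1] = 0.5
        out = epg_evolve(s, 0.0, 1.5, 0.05)
        assert np.allclose(out.Fplus, s.Fplus) and np.allclose(out.Z, s.Z)

    def test_evolve_t1_recovery_closed_form(self):
        s = EPGState.equilibrium(3, z0=0.0)
        out = epg_evolve(s, 1.5, 1.5, 0.05)
        assert out.Z[0] == pytest.approx(1 - np.exp(-1.0))

    def test_repeated_shift_moves_orders_up(self):
        s = EPGState.equilibrium(5, z0=0.0)
        s.Fplus[0] = 1.0
        s.Fminus[0] = 1.0  # conj consistency at order 0
        for n in range(1, 4):
            s = epg_shift(s)
            assert s.Fplus[n] == pytest.approx(1.0)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            epg_evolve(EPGState.equilibrium(2), -1e-3, 1.5, 0.05)


class TestEchoTrain:
    def test_ideal_cpmg_echoes_all_unity(self):
        tr = build_base_train(n_pulses=32, const_angle=180, ramp_length=0,
                              TR=8, TI=2.25, center_echo_index=16)
        e = simulate_echo_train(tr, 1.0, 1e12, 1e12)
        assert np.allclose(e, 1.0, atol=1e-9)

    def test_pure_t2_decay_closed_form(self):
        tr = build_base_train(n_pulses=32, const_angle=180, ramp_length=0,
                              TR=8, TI=2.25, center_echo_index=16)
        e = simulate_echo_train(tr, 1.0, 1e12, 0.05)
        j = np.arange(1, tr.n_echoes + 1)
        assert np.allclose(e, np.exp(-j * 3e-3 / 0.05), atol=1e-12)

    def test_echoes_bounded_and_monotone_for_ideal_train(self):
        tr = build_base_train(n_pulses=64, const_angle=180, ramp_length=0,
                              TR=8, TI=2.25, center_echo_index=32)
        e = simulate_echo_train(tr, 1.0, 1.5, 0.05)
        assert np.all(e >= 0) and np.all(e <= 1.0)
        assert np.all(np.diff(e) <= 1e-12)

    def test_scale_length_mismatch_rejected(self, paper_train):
        with pytest.raises(ValueError):
            simulate_echo_train(paper_train, np.ones(5), 1.5, 0.05)


class TestBlochEquivalence:
    def test_epg_matches_bloch_ensemble_over_random_draws(self, paper_train):
        """20 random shim/sensitivity draws agree to <= 1e-6 at 1024 spins."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            amp = rng.uniform(0.3, 1.3, paper_train.n_pulses)
            ph = rng.uniform(-np.pi, np.pi, paper_train.n_pulses)
            scale = amp * np.exp(1j * ph)
            e_epg = simulate_echo_train(paper_train, scale, 1.5, 0.05)
            e_bloch = bloch_ensemble_oracle(paper_train, scale, 1.5, 0.05,
                                            n_isochromats=1024)
            worst = max(worst, np.max(np.abs(e_epg - e_bloch)))
        assert worst <= 1e-6

    def test_single_isochromat_differs_from_epg(self, paper_train):
        """No configuration dephasing with one spin: the ensemble is needed."""
        scale = np.full(paper_train.n_pulses, 0.8 + 0.1j)
        e_epg = simulate_echo_train(paper_train, scale, 1.5, 0.05)
        e_one = bloch_ensemble_oracle(paper_train, scale, 1.5, 0.05,
                                      n_isochromats=1)
        assert np.max(np.abs(e_epg - e_one)) > 1e-3

    def test_ideal_cpmg_bloch_oracle(self):
        tr = build_base_train(n_pulses=16, const_angle=180, ramp_length=0,
                              TR=8, TI=2.25, center_echo_index=8)
        e = bloch_ensemble_oracle(tr, 1.0, 1e12, 1e12, n_isochromats=64)
        assert np.allclose(e, 1.0, atol=1e-9)


class TestForwardModel:
    def test_uniform_sensitivity_reproduces_target(self, paper_train):
        S = np.full((3, 8), 1 / 8, dtype=complex)
        pred = forward_model(np.ones((paper_train.n_pulses, 8)), S,
                             paper_train, 1.5, 0.05)
        assert np.allclose(pred.I, pred.T[None, :], atol=1e-12)

    def test_zero_sensitivity_voxel_gives_zero_signal(self, paper_train):
        S = np.zeros((1, 8), dtype=complex)
        pred = forward_model(np.ones((paper_train.n_pulses, 8)), S,
                             paper_train, 1.5, 0.05)
        assert np.allclose(pred.I, 0.0)

    def test_rows_match_per_voxel_simulation(self, paper_train):
        rng = np.random.default_rng(3)
        S = rng.normal(0.3, 0.2, (3, 8)) + 1j * rng.normal(0, 0.2, (3, 8))
        w = rng.normal(0.8, 0.2, (paper_train.n_pulses, 8)) + 1j * rng.normal(
            0, 0.2, (paper_train.n_pulses, 8))
        pred = forward_model(w, S, paper_train, 1.5, 0.05)
        for i in range(3):
            scale = S[i] @ w.T
            e = simulate_echo_train(paper_train, scale, 1.5, 0.05)
            assert np.allclose(pred.I[i], e, atol=1e-12)

    def test_global_phase_equivariance(self, paper_train):
        rng = np.random.default_rng(4)
        S = rng.normal(0.3, 0.2, (4, 8)) + 1j * rng.normal(0, 0.2, (4, 8))
        w = np.ones((paper_train.n_pulses, 8), dtype=complex)
        p0 = forward_model(w, S, paper_train, 1.5, 0.05)
        p1 = forward_model(w * np.exp(0.7j), S, paper_train, 1.5, 0.05)
        assert np.allclose(p0.I, p1.I, atol=1e-12)

    def test_channel_mismatch_rejected(self, paper_train):
        with pytest.raises(ValueError):
            forward_model(np.ones((paper_train.n_pulses, 8)),
                          np.ones((2, 4), dtype=complex),
                          paper_train, 1.5, 0.05)


class TestTargetSignal:
    def test_target_equals_unit_voxel_prediction(self, paper_train):
        T = target_signal(paper_train, 1.5, 0.05)
        S = np.full((1, 8), 1 / 8, dtype=complex)
        pred = forward_model(np.ones((paper_train.n_pulses, 8)), S,
                             paper_train, 1.5, 0.05)
        assert np.allclose(T, pred.I[0], atol=1e-12)

    def test_target_positive_and_bounded(self, paper_train):
        T = target_signal(paper_train, 1.5, 0.05)
        assert np.all(T > 0) and np.all(T <= 1.0)

    def test_target_ideal_train_closed_form_at_center(self):
        tr = build_base_train(n_pulses=192, const_angle=180, ramp_length=0)
        T = target_signal(tr, 1e12, 0.05)
        assert T[99] == pytest.approx(np.exp(-100 * 3e-3 / 0.05), rel=1e-9)


class TestAdjointGradient:
    def test_adjoint_matches_central_differences(self, short_train):
        """Exact gradient vs finite differences on a 2-voxel toy problem."""
        rng = np.random.default_rng(1)
        nc, V = 3, 2
        S = rng.normal(0.6, 0.3, (V, nc)) + 1j * rng.normal(0, 0.3, (V, nc))
        w = rng.normal(0.7, 0.2, (short_train.n_pulses, nc)) + 1j * rng.normal(
            0, 0.2, (short_train.n_pulses, nc))
        C = np.linspace(0.3, 1, short_train.n_echoes)
        _, g = epg_cost_and_grad(w, S, short_train, 1.5, 0.05, C)
        eps = 1e-6
        rng2 = np.random.default_rng(2)
        for _ in range(10):  # spot-check random entries
            j = rng2.integers(short_train.n_pulses)
            k = rng2.integers(nc)
            part = rng2.choice([1.0, 1j])
            wp, wm = w.copy(), w.copy()
            wp[j, k] += eps * part
            wm[j, k] -= eps * part
            cp, _ = epg_cost_and_grad(wp, S, short_train, 1.5, 0.05, C)
            cm, _ = epg_cost_and_grad(wm, S, short_train, 1.5, 0.05, C)
            fd = (cp - cm) / (2 * eps)
            an = g[j, k].real if part == 1.0 else g[j, k].imag
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-9)
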