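"""Shim parameterization, DSC cost/optimization, static MLS, universal."""

import numpy as np
import pytest

from dscflair.epg import forward_model, simulate_echo_train, target_signal
from dscflair.sequence import PowerModel, channel_powers
from dscflair.shim import (
    DSCConfig,
    ShimSchedule,
    build_echo_weighting,
    build_mapping,
    dsc_cost,
    dsc_optimize,
    quadrature_solution,
    static_mls_shim,
    universal_optimize,
)


class TestMapping:
    def test_protocol_mapping_covers_all_pulses(self):
        m = build_mapping(192, 13, (60, 60, 59))
        assert m.size == 192
        assert m.max() + 1 == 16
        # first 13 pulses individually shimmed
        assert np.array_equal(m[:13], np.arange(13))
        # each pulse assigned exactly one row, rows contiguous
        assert np.array_equal(np.unique(m), np.arange(16))

    def test_block_boundaries(self):
        m = build_mapping(192, 13, (60, 60, 59))
        # 1-based pulses 14 and 73 share a row; pulse 74 starts the next
        assert m[13] == m[72]
        assert m[73] == m[72] + 1
        assert np.sum(m == m[13]) == 60
        assert np.sum(m == m[191]) == 59

    def test_identity_mapping(self):
        m = build_mapping(10, 10, ())
        assert np.array_equal(m, np.arange(10))

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_mapping(192, 13, (60, 60, 60))


class TestEchoWeighting:
    def test_center_has_maximum_weight(self):
        C = build_echo_weighting(191, 100, 0.0).C
        assert C[99] == 1.0
        assert C.max() == 1.0

    def test_linear_ramp_structure(self):
        C = build_echo_weighting(191, 100, 0.0).C
        assert C[0] == pytest.approx(0.0)
        assert C[-1] == pytest.approx(0.0)
        assert np.all(np.diff(C[:100]) > 0)
        assert np.all(np.diff(C[99:]) < 0)

    def test_floor_raises_edges(self):
        C = build_echo_weighting(191, 100, 0.3).C
        assert C[0] == pytest.approx(0.3)

    def test_near_unity_floor_is_near_uniform(self):
        C = build_echo_weighting(51, 26, 0.999).C
        assert np.ptp(C) < 2e-3

    def test_unit_floor_disallowed(self):
        with pytest.raises(ValueError):
            build_echo_weighting(51, 26, 1.0)


class TestDSCCost:
    def test_uniform_fields_quadrature_zero_cost(self, paper_train):
        S = np.full((2, 8), 1 / 8, dtype=complex)
        C = build_echo_weighting(paper_train.n_echoes).C
        m = build_mapping(paper_train.n_pulses)
        c = dsc_cost(np.ones((16, 8)), S, paper_train, 1.5, 0.05, C, mapping=m)
        assert c == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_in_weighting(self, short_train):
        rng = np.random.default_rng(0)
        S = rng.normal(0.3, 0.2, (2, 4)) + 1j * rng.normal(0, 0.2, (2, 4))
        C = build_echo_weighting(short_train.n_echoes, 12, 0.2).C
        m = build_mapping(short_train.n_pulses, 4, (10, 10))
        w = rng.normal(0.8, 0.1, (6, 4)) + 0j
        c1 = dsc_cost(w, S, short_train, 1.5, 0.05, C, mapping=m)
        c2 = dsc_cost(w, S, short_train, 1.5, 0.05, 2 * C, mapping=m)
        assert c2 == pytest.approx(4 * c1, rel=1e-12)

    def test_matches_bruteforce_per_voxel_sum(self, short_train):
        """Hand-summed squared deviations over a 2-voxel toy problem."""
        rng = np.random.default_rng(5)
        S = rng.normal(0.4, 0.2, (2, 4)) + 1j * rng.normal(0, 0.2, (2, 4))
        C = build_echo_weighting(short_train.n_echoes, 12, 0.2).C
        m = build_mapping(short_train.n_pulses, 4, (10, 10))
        w = rng.normal(0.8, 0.2, (6, 4)) + 1j * rng.normal(0, 0.2, (6, 4))
        c = dsc_cost(w, S, short_train, 1.5, 0.05, C, mapping=m)
        T = target_signal(short_train, 1.5, 0.05)
        brute = 0.0
        for i in range(2):
            scale = S[i] @ w[m].T
            e = simulate_echo_train(short_train, scale, 1.5, 0.05)
            brute += np.sum((C * (e - T)) ** 2)
        assert c == pytest.approx(brute, rel=1e-12)


class TestQuadrature:
    def test_all_ones(self):
        q = quadrature_solution(192, 8)
        assert np.allclose(q.w, 1.0)
        assert q.w.shape == (192, 8)

    def test_quadrature_power_finite(self, paper_train, power_model):
        rep = channel_powers(quadrature_solution(192, 8).w, paper_train,
                             power_model)
        assert np.isfinite(rep.max_avg) and np.isfinite(rep.max_peak)

    def test_quadrature_on_uniform_fields_hits_target(self, paper_train):
        S = np.full((1, 8), 1 / 8, dtype=complex)
        pred = forward_model(quadrature_solution(192, 8).w, S, paper_train,
                             1.5, 0.05)
        assert np.allclose(pred.I[0], pred.T, atol=1e-12)


class TestDSCOptimize:
    def test_single_voxel_reaches_target(self, paper_train, power_model):
        """With uniform unit sensitivity and loose limits the exact target is
        reachable (w = 1 is feasible and zero-cost)."""
        S = np.full((1, 8), 1 / 8, dtype=complex)
        cfg = DSCConfig(maxiter=300, weight_floor=0.2)
        sol = dsc_optimize(S, paper_train, power_model, cfg)
        assert sol.final_cost <= 1e-6 * sol.initial_cost
        assert sol.power_report.feasible

    def test_solution_is_feasible_and_improves(self, small_subject,
                                               paper_train, power_model):
        cfg = DSCConfig(maxiter=30, max_opt_voxels=60, K_opt=32)
        sol = dsc_optimize(small_subject, paper_train, power_model, cfg)
        # independent re-evaluation of the constraint formulas
        rep = channel_powers(sol.w, paper_train, power_model)
        assert rep.max_avg <= power_model.P_avg * (1 + 1e-9)
        assert rep.max_peak <= power_model.P_peak * (1 + 1e-9)
        assert sol.final_cost <= sol.initial_cost

    def test_deterministic_given_fixed_inputs(self, short_train, power_model):
        rng = np.random.default_rng(11)
        S = rng.normal(0.3, 0.2, (5, 4)) + 1j * rng.normal(0, 0.2, (5, 4))
        cfg = DSCConfig(individual=4, blocks=(10, 10), maxiter=10, K_opt=16)
        s1 = dsc_optimize(S, short_train, power_model, cfg)
        s2 = dsc_optimize(S, short_train, power_model, cfg)
        assert np.array_equal(s1.schedule.w_reduced, s2.schedule.w_reduced)
        assert np.array_equal(s1.cost_history, s2.cost_history)

    def test_infeasible_start_rescaled_to_feasibility(self, short_train):
        """A start violating a tight average-power budget is rescaled and the
        returned solution still satisfies the limits."""
        pm = PowerModel(P_avg=0.36, mp_power_offset=0.34)  # 0.02 W budget
        S = np.full((1, 4), 0.25, dtype=complex)
        cfg = DSCConfig(individual=4, blocks=(10, 10), maxiter=10, K_opt=16)
        sol = dsc_optimize(S, short_train, pm, cfg)
        rep = channel_powers(sol.w, short_train, pm)
        assert rep.max_avg <= pm.P_avg * (1 + 1e-9)
        assert rep.max_peak <= pm.P_peak * (1 + 1e-9)


class TestUniversal:
    def test_single_subject_degenerates_to_individual(self, short_train,
                                                      power_model):
        rng = np.random.default_rng(2)
        S = rng.normal(0.3, 0.2, (6, 4)) + 1j * rng.normal(0, 0.2, (6, 4))
        cfg = DSCConfig(individual=4, blocks=(10, 10), maxiter=10, K_opt=16,
                        max_opt_voxels=0)
        s_ind = dsc_optimize(S, short_train, power_model, cfg)
        s_uni = universal_optimize([S], short_train, power_model, cfg)
        assert np.allclose(s_ind.schedule.w_reduced, s_uni.schedule.w_reduced)

    def test_duplicated_subject_doubles_cost(self, short_train, power_model):
        rng = np.random.default_rng(3)
        S = rng.normal(0.3, 0.2, (6, 4)) + 1j * rng.normal(0, 0.2, (6, 4))
        from dscflair.shim import build_echo_weighting, build_mapping, dsc_cost
        C = build_echo_weighting(short_train.n_echoes, 12, 0.0).C
        m = build_mapping(short_train.n_pulses, 4, (10, 10))
        w = np.full((6, 4), 0.6 + 0j)
        c1 = dsc_cost(w, S, short_train, 1.5, 0.05, C, mapping=m)
        c2 = dsc_cost(w, np.vstack([S, S]), short_train, 1.5, 0.05, C,
                      mapping=m)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_channel_mismatch_rejected(self, short_train, power_model):
        with pytest.raises(ValueError):
            universal_optimize(
                [np.ones((3, 4), dtype=complex), np.ones((3, 8), dtype=complex)],
                short_train, power_model,
            )


class TestStaticMLS:
    def test_two_channel_antiphase_voxel(self, paper_train, power_model):
        """Sensitivities (1, e^{i pi}) with an unreachable target: the
        optimum counter-phases the channels so the fields co-align and both
        amplitudes sit at the cap; brute force over a phase grid agrees."""
        S = np.array([[1.0, np.exp(1j * np.pi)]])
        target = 5.0  # far above what the power caps allow
        sched = static_mls_shim(S, paper_train, power_model, target=target)
        w = sched.w_reduced[0]
        dphi = np.angle(w[1]) - np.angle(w[0])
        assert np.cos(dphi - np.pi) == pytest.approx(1.0, abs=1e-3)
        # combined amplitude equals the co-aligned sum of amplitudes
        assert abs(S[0] @ w) == pytest.approx(abs(w[0]) + abs(w[1]), rel=1e-4)
        # brute-force oracle: both channels at the cap, relative phase swept
        r = np.abs(w).max()
        phis = np.linspace(0, 2 * np.pi, 1441)
        best = min(abs(abs(r - r * np.exp(1j * p)) - target) for p in phis)
        assert abs(abs(S[0] @ w) - target) <= best + 1e-4

    def test_objective_improves_and_exchange_is_monotone(self, paper_train,
                                                         power_model):
        """The variable-exchange iteration never increases the MLS
        objective: intermediate iterate objectives decrease."""
        rng = np.random.default_rng(8)
        S = rng.normal(0.4, 0.3, (30, 8)) + 1j * rng.normal(0, 0.3, (30, 8))
        t = float(np.mean(np.abs(S.sum(axis=1))))

        def obj(wc):
            return float(np.sum((np.abs(S @ wc) - t) ** 2))

        objs = [obj(static_mls_shim(S, paper_train, power_model,
                                    n_exchanges=n).w_reduced[0])
                for n in (1, 3, 10, 30)]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))
        # and the converged shim beats the uniform start
        start = obj(np.full(8, 1.0 + 0j))
        assert objs[-1] <= start + 1e-9

    def test_binding_average_power_drives_all_channels_to_cap(self,
                                                              paper_train):
        """Under a binding average-power limit only phases differ between
        channels: every amplitude sits at the cap."""
        pm = PowerModel(P_avg=0.2, P_peak=85.0, mp_power_offset=0.15)
        rng = np.random.default_rng(9)
        S = rng.normal(0.5, 0.3, (40, 8)) + 1j * rng.normal(0, 0.3, (40, 8))
        sched = static_mls_shim(S, paper_train, pm, target=5.0)
        amps = np.abs(sched.w_reduced[0])
        assert np.ptp(amps) / amps.mean() < 0.05
        rep = channel_powers(sched.w, paper_train, pm)
        assert rep.max_avg <= pm.P_avg * (1 + 1e-6)
        assert rep.max_avg >= 0.95 * pm.P_avg  # the limit is actually binding

    def test_all_zero_sensitivities_rejected(self, paper_train, power_model):
        with pytest.raises(ValueError):
            static_mls_shim(np.zeros((3, 8), dtype=complex), paper_train,
                            power_model)


class TestShimSchedule:
    def test_expansion_through_mapping(self):
        m = build_mapping(192, 13, (60, 60, 59))
        wr = np.arange(16 * 8, dtype=float).reshape(16, 8) + 0j
        sched = ShimSchedule(w_reduced=wr, mapping=m)
        assert sched.w.shape == (192, 8)
        assert np.array_equal(sched.w[13], sched.w[72])
        assert np.array_equal(sched.w[0], wr[0])

    def test_invalid_mapping_rejected(self):
        with pytest.raises(ValueError):
            ShimSchedule(w_reduced=np.ones((2, 4)), mapping=np.array([0, 5]))
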