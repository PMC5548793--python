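"""Origin-fixation chain: rates, steady state, dynamics, hitting times."""

import numpy as np
import pytest

from tfspec import chain, oracles, thermo
from tfspec.chain import (
    build_chain,
    dominant_macrostate_map,
    dwell_time,
    fixation_probability,
    hitting_time,
    propagate,
    steady_state,
)
from tfspec.params import ModelParams


class TestFixationProbability:
    def test_neutral_limit(self):
        assert fixation_probability(0.0, 1000) == pytest.approx(1e-3)
        assert fixation_probability(1e-14, 500) == pytest.approx(1 / 500, rel=1e-6)

    def test_strong_selection_limit(self):
        dF = 0.05
        assert fixation_probability(dF, 10_000) == \
            pytest.approx(1 - np.exp(-2 * dF), rel=1e-6)

    def test_ratio_identity(self):
        """Phi(dF)/Phi(-dF) = exp(2(N-1) dF) -- the identity behind the
        closed-form steady state."""
        N = 200
        for dF in (1e-4, 1e-3, 0.01, 0.05):
            ratio = fixation_probability(dF, N) / fixation_probability(-dF, N)
            assert ratio == pytest.approx(np.exp(2 * (N - 1) * dF), rel=1e-8)

    def test_monotone_and_safe_at_extremes(self):
        dF = np.array([-50.0, -1.0, -1e-3, 0.0, 1e-3, 1.0, 50.0])
        phi = fixation_probability(dF, 1000)
        assert np.all(np.diff(phi) >= 0)
        assert np.isfinite(phi).all()
        assert phi[0] < 1e-300  # hopeless mutant underflows cleanly
        assert phi[-1] == pytest.approx(1.0, abs=1e-6)


class TestChainConstruction:
    def test_generator_row_sums_zero(self, small_chain):
        rows = np.asarray(small_chain.Q.sum(axis=1)).ravel()
        assert np.abs(rows).max() < 1e-18
        off = small_chain.Q.copy()
        off.setdiag(0.0)
        assert off.data.min() >= 0.0

    def test_exit_rate_bound(self, small_chain):
        """Total exit rate <= 2 N mu (n_G L + r_TF n_TF L + 2 r_S n_TF) max Phi."""
        p = small_chain.params
        bound = 2 * p.N * p.mu * (p.n_G * p.L + p.r_TF * 2 * p.L + p.r_S * 4)
        exit_rates = -small_chain.Q.diagonal()
        assert exit_rates.max() <= bound * 1.0000001

    def test_lumped_rates_match_full_chain_oracle(self, tiny, tiny_space):
        """The analytic class-averaged mutation rates equal the explicit-
        sequence chain marginalised over classes (exactly, L=2, n_G=1)."""
        cm = build_chain(tiny, tiny_space)
        oracle = oracles.lumped_mutation_oracle(tiny, tiny_space)
        diff = np.abs((cm.mu_matrix - oracle).toarray()).max()
        assert diff < 1e-12 * tiny.mu

    def test_neutral_detailed_balance(self, tiny_space):
        p = ModelParams(L=2, n_G=1, s=0.0)
        cm = build_chain(p, tiny_space)
        P0 = tiny_space.neutral_distribution()
        flow = cm.Q.multiply(P0[:, None])
        resid = np.abs((flow - flow.T).toarray()).max() / np.abs(cm.Q.data).max()
        assert resid < 1e-8

    def test_transition_matrix_stochastic(self, tiny_chain):
        A = tiny_chain.transition_matrix()
        rows = np.asarray(A.sum(axis=1)).ravel()
        np.testing.assert_allclose(rows, 1.0, atol=1e-12)
        assert A.data.min() >= 0.0 and A.data.max() <= 1.0


class TestSteadyState:
    def test_neutral_equals_P0(self, tiny_space):
        p = ModelParams(L=2, n_G=1, s=0.0)
        cm = build_chain(p, tiny_space)
        P0 = tiny_space.neutral_distribution()
        for method in ("closed_form", "null_space"):
            pi = steady_state(cm, method)
            assert 0.5 * np.abs(pi - P0).sum() < 1e-10

    def test_closed_vs_null_space_small(self, small_chain):
        cf = steady_state(small_chain, "closed_form")
        ns = steady_state(small_chain, "null_space")
        assert cf.sum() == pytest.approx(1.0, abs=1e-12)
        # 2N vs 2(N-1) exponent: O(s) discrepancy only
        assert 0.5 * np.abs(cf - ns).sum() < 0.02

    def test_invariance_under_rate_rescaling(self, small, small_space):
        ref = steady_state(build_chain(small, small_space), "null_space")
        for kw in (dict(mu=5e-5), dict(r_S=3.0), dict(r_TF=0.25)):
            pi = steady_state(build_chain(small.replace(**kw), small_space),
                              "null_space")
            assert 0.5 * np.abs(pi - ref).sum() < 1e-9

    def test_closed_form_ignores_mutation_scale_exactly(self, small, small_space):
        a = steady_state(build_chain(small, small_space), "closed_form")
        b = steady_state(build_chain(small.replace(mu=1e-3, r_S=9.0, r_TF=0.1),
                                     small_space), "closed_form")
        np.testing.assert_array_equal(a, b)

    def test_reducible_chain_raises(self, small, small_space):
        frozen = small.replace(r_S=0.0)  # sensing sectors disconnect
        cm = build_chain(frozen, small_space)
        with pytest.raises(ValueError, match="reducible"):
            steady_state(cm, "null_space")

    def test_lumped_matches_full_chain_under_selection(self, tiny, tiny_space):
        """Occupancy statistics of the reduced chain match the fully
        enumerated explicit-sequence chain (L=2, n_G=1)."""
        cm = build_chain(tiny, tiny_space)
        pi = steady_state(cm, "null_space")
        full = oracles.enumerate_full_chain(tiny)
        proj = np.bincount(full.reduced_index(tiny_space),
                           weights=full.steady_state(), minlength=len(tiny_space))
        assert 0.5 * np.abs(pi - proj).sum() < 0.01


class TestPropagate:
    def test_zero_time_is_identity(self, tiny_chain):
        P0 = tiny_chain.initial_distribution()
        assert np.array_equal(propagate(tiny_chain, P0, 0.0), P0)

    def test_mass_conserved(self, tiny_chain):
        P0 = tiny_chain.initial_distribution()
        times = np.linspace(0, 2e5, 9)
        for method in ("euler", "uniformization"):
            traj = propagate(tiny_chain, P0, times[-1], method=method,
                             times=times)
            np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-10)
            assert traj.min() > -1e-12

    def test_converges_to_steady_state(self, tiny_chain):
        pi = steady_state(tiny_chain, "null_space")
        P = propagate(tiny_chain, tiny_chain.initial_distribution(),
                      T=300 / tiny_chain.params.mu)
        assert 0.5 * np.abs(P - pi).sum() < 1e-6

    def test_euler_agrees_with_uniformization(self, tiny_chain):
        P0 = tiny_chain.initial_distribution()
        T = 0.3 / tiny_chain.params.mu
        Pe = propagate(tiny_chain, P0, T, method="euler")
        Pu = propagate(tiny_chain, P0, T, method="uniformization")
        assert 0.5 * np.abs(Pe - Pu).sum() < 1e-4

    def test_unnormalised_input_raises(self, tiny_chain):
        with pytest.raises(ValueError):
            propagate(tiny_chain, np.ones(tiny_chain.n_states), 1.0)


class TestHittingTimes:
    def test_zero_on_target(self, small_chain):
        target = small_chain.labels == "SpecializeBoth"
        res = hitting_time(small_chain, target)
        assert np.all(res.times[target] == 0.0)
        assert np.all(res.times[~target] > 0.0)

    def test_single_state_complement_is_inverse_exit_rate(self, tiny_chain):
        """From state x to 'anywhere else' the mean time is exactly the mean
        sojourn 1/exit-rate (geometric/exponential holding time)."""
        x = 7
        target = np.ones(tiny_chain.n_states, dtype=bool)
        target[x] = False
        res = hitting_time(tiny_chain, target)
        exit_rate = -tiny_chain.Q.diagonal()[x]
        assert res.times[x] == pytest.approx(1.0 / exit_rate, rel=1e-10)

    def test_consistent_with_one_step_recursion(self, tiny_chain):
        """T = t_g + A^T T on non-target states, with A = I + Q t_g."""
        target = tiny_chain.labels == "NoRegulation"
        res = hitting_time(tiny_chain, target)
        A = tiny_chain.transition_matrix()
        rhs = tiny_chain.params.t_g + A @ res.times
        np.testing.assert_allclose(res.times[~target], rhs[~target], rtol=1e-8)

    def test_unreachable_target_raises(self, small, small_space):
        frozen = small.replace(r_S=0.0)
        cm = build_chain(frozen, small_space)
        with pytest.raises(ValueError, match="unreachable"):
            hitting_time(cm, cm.labels == "SpecializeBoth")

    def test_gillespie_agreement(self, small_chain):
        """Mean simulated arrival time within 3 SE of the analytic value."""
        from tfspec import gillespie

        p = small_chain.params
        target = small_chain.labels == "SpecializeBoth"
        analytic = float(hitting_time(small_chain, target).times
                         @ small_chain.initial_distribution())
        trajs = gillespie.simulate_ensemble(
            small_chain, n_replicates=400, horizon=500 / p.mu, seed=7,
            stop_at="SpecializeBoth")
        st = gillespie.trajectory_statistics(trajs)
        assert st.n_unresolved == 0
        assert abs(st.tau_mean - analytic) < 3 * st.tau_se


class TestDwellTimes:
    def test_whole_space_is_infinite(self, tiny_chain):
        import copy

        cm = copy.copy(tiny_chain)
        cm.labels = np.full(cm.n_states, "Everything", dtype=object)
        assert dwell_time(cm, "Everything") == float("inf")

    def test_empty_macrostate_raises(self, tiny_chain):
        with pytest.raises(ValueError, match="empty"):
            dwell_time(tiny_chain, "NotAState")

    def test_positive_and_weighting_modes(self, small_chain):
        pss = steady_state(small_chain)
        t_ss = dwell_time(small_chain, "OneTFLost", P_ss=pss)
        t_u = dwell_time(small_chain, "OneTFLost", weighting="uniform")
        assert t_ss > 0 and t_u > 0

    def test_matches_simulated_sojourns(self, small_chain):
        """Dwell time in a macrostate agrees with simulated sojourn
        durations (entry-weighted) within sampling error."""
        from tfspec import gillespie

        p = small_chain.params
        z = "OneTFLost"
        durations = []
        for rep in range(120):
            tr = gillespie.simulate_reduced(
                small_chain, horizon=100 / p.mu,
                rng=np.random.default_rng([99, rep]))
            spans = np.diff(np.append(tr.times, tr.horizon))
            in_z = tr.labels == z
            # merge consecutive in-state segments into sojourns
            run = 0.0
            for flag, dt in zip(in_z, spans):
                if flag:
                    run += dt
                elif run > 0:
                    durations.append(run)
                    run = 0.0
        durations = np.array(durations)
        assert len(durations) > 40
        # analytic counterpart of entry-weighted sojourns: weight in-state
        # hitting times by the steady-state probability flow into the state
        pss = steady_state(small_chain)
        in_z = small_chain.labels == z
        res = hitting_time(small_chain, target_mask=~in_z)
        Qio = small_chain.Q[~in_z][:, in_z]
        entry = np.asarray(Qio.multiply(pss[~in_z][:, None]).sum(axis=0)).ravel()
        entry /= entry.sum()
        analytic = float(entry @ res.times[in_z])
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert abs(durations.mean() - analytic) < 3 * se
        # and the macrostate dwell time itself is of the same order
        t_ss = dwell_time(small_chain, z, P_ss=pss)
        assert 0.2 * t_ss < durations.mean() < 5 * t_ss


class TestPhaseMaps:
    def test_weak_selection_gives_no_regulation(self, small, small_space):
        grid = dominant_macrostate_map(small, np.array([1e-4]),
                                       np.linspace(-0.8, 0.8, 5),
                                       space=small_space)
        assert set(grid.ravel()) == {"NoRegulation"}

    def test_infeasible_cells_labelled(self, small, small_space):
        grid = dominant_macrostate_map(small, np.array([25.0]),
                                       np.array([-0.9, 0.0]),
                                       f_values=np.array([0.9]),
                                       space=small_space)
        assert grid[0, 0] == "Impossible"
        assert grid[0, 1] != "Impossible"
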