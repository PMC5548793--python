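"""Occupancy, fitness, strong/weak phenotypes, macrostates, free fitness."""

import math

import numpy as np
import pytest

from tfspec import thermo
from tfspec.params import ModelParams
from tfspec.thermo import (
    MACROSTATES,
    ReducedGenotype,
    binding_phenotypes,
    binding_probability,
    classify_macrostate,
    classify_states,
    expression_profile,
    fitness,
    initial_genotype,
    macrostate_free_fitness,
)


class TestOccupancy:
    def test_no_active_tf(self):
        assert binding_probability([0, 0], [0.0, 0.0], 3.0) == 0.0

    def test_half_occupancy_point(self):
        # C * exp(-eps*k) = 1  =>  p = 1/2
        eps, k = 3.0, 2
        assert binding_probability([k], [math.exp(eps * k)], eps) == \
            pytest.approx(0.5, abs=1e-14)

    def test_two_tf_value(self):
        # both TFs on consensus at C0 = e^7.5: p = 2C0/(1+2C0)
        C0 = math.exp(7.5)
        p = binding_probability([0, 0], [C0, C0], 3.0)
        assert p == pytest.approx(2 * C0 / (1 + 2 * C0), rel=1e-12)
        assert p == pytest.approx(0.999723, abs=1e-6)

    def test_monotonicity(self, rng):
        eps = 3.0
        for _ in range(50):
            k = rng.integers(0, 6, size=2)
            C = rng.uniform(0, 100, size=2)
            p = binding_probability(k, C, eps)
            assert 0.0 <= p <= 1.0
            if C[0] > 0:
                worse = binding_probability(k + np.array([1, 0]), C, eps)
                assert worse < p or (p == 0.0)
            more = binding_probability(k, C * 1.5, eps)
            assert more >= p


class TestExpression:
    def test_unresponsive_activator_silent(self):
        p = ModelParams()
        g = ReducedGenotype(p.L, ((0, 0), (0, 0)), (0, 0))
        assert np.all(expression_profile(g, p) == 0.0)

    def test_unresponsive_repressor_full(self):
        p = ModelParams(mode="repressor")
        g = ReducedGenotype(p.L, ((0, 0), (0, 0)), (0, 0))
        assert np.all(expression_profile(g, p) == 1.0)

    def test_initial_genotype_fully_induced_when_signalled(self):
        p = ModelParams()
        prof = expression_profile(initial_genotype(p), p)
        # any signal present -> both genes essentially on; no signal -> off
        for m in (0b01, 0b10, 0b11):
            assert np.all(prof[:, m] > 0.98)
        assert np.all(prof[:, 0b00] == 0.0)

    def test_repressor_complements_activator(self):
        pa = ModelParams()
        pr = ModelParams(mode="repressor")
        g = ReducedGenotype(2, ((1, 3), (2, 0)), (0b10, 0b11))
        np.testing.assert_allclose(
            expression_profile(g, pr), 1.0 - expression_profile(g, pa), atol=1e-15)


class TestFitness:
    def test_zero_iff_ideal(self):
        p = ModelParams()
        g = initial_genotype(p)
        # initial genotype has crosstalk: fitness strictly negative
        assert fitness(g, p) < 0.0
        assert fitness(g, p.replace(s=0.0)) == 0.0

    def test_initial_genotype_hand_value(self):
        """Hand evaluation of the quadratic penalty for the post-duplication
        genotype at rho=0, f=1/2 (alpha = 1/4 each): both genes sit at
        p2 = 2 C0 / (1 + 2 C0) whenever any signal is present, so each gene
        pays 1/4 * beta_off * p2^2 in its wrong-signal environment and
        (1 - p2)^2 terms in its two on-environments."""
        p = ModelParams()
        p2 = 2 * p.C0 / (1 + 2 * p.C0)
        expected_loss = 2 * (0.25 * 0.5 * p2 ** 2 + 2 * 0.25 * (1 - p2) ** 2)
        assert fitness(initial_genotype(p), p) == \
            pytest.approx(-p.s * expected_loss, rel=1e-12)

    def test_bounds(self, small, small_space):
        F = thermo.fitness_array(small_space, small)
        alpha = small.env.as_array
        beta = small.weight_profile()
        lower = -small.s * float((alpha[None, :] * beta).sum())
        assert np.all(F <= 0.0) and np.all(F >= lower - 1e-12)

    def test_scalar_matches_vectorised(self, small, small_space):
        F = thermo.fitness_array(small_space, small)
        for i in (0, 100, 2000):
            g = ReducedGenotype(int(small_space.M[i]),
                                tuple(map(tuple, small_space.k[i].tolist())),
                                tuple(int(s) for s in small_space.sigma[i]))
            assert fitness(g, small) == pytest.approx(F[i], rel=1e-12)


class TestPhenotypes:
    def test_default_threshold(self):
        p = ModelParams()  # C0 = e^{1.5 eps}: strong iff k <= 1
        g = ReducedGenotype(3, ((0, 1), (2, 5)), (3, 3))
        np.testing.assert_array_equal(
            binding_phenotypes(g, p), [[True, True], [False, False]])

    def test_saturating_concentration_threshold(self):
        # C0 = e^{2.5 eps} moves the strong/weak cut between k=2 and k=3
        p = ModelParams(C0=math.exp(2.5 * 3.0))
        g = ReducedGenotype(3, ((2, 3), (0, 5)), (3, 3))
        np.testing.assert_array_equal(
            binding_phenotypes(g, p), [[True, False], [True, False]])


class TestMacrostates:
    def test_examples(self):
        p = ModelParams()
        L = p.L
        cases = [
            (ReducedGenotype(L, ((0, 0), (0, 0)), (3, 3)), "Initial"),
            (ReducedGenotype(0, ((0, 5), (5, 0)), (0b10, 0b01)), "SpecializeBoth"),
            (ReducedGenotype(0, ((5, 0), (0, 5)), (0b01, 0b10)), "SpecializeBoth"),
            (ReducedGenotype(0, ((0, 5), (5, 0)), (0b11, 0b01)), "SpecializeBinding"),
            (ReducedGenotype(0, ((5, 5), (5, 5)), (3, 1)), "NoRegulation"),
            (ReducedGenotype(0, ((0, 0), (5, 5)), (0b10, 0b01)), "OneTFLost"),
            # strong bonds only from a sensing-dead TF: nothing transduced
            (ReducedGenotype(0, ((0, 0), (5, 5)), (0b00, 0b01)), "NoRegulation"),
            # everything strong but sensing not complete -> Partial
            (ReducedGenotype(L, ((0, 0), (0, 0)), (3, 1)), "Partial"),
            (ReducedGenotype(2, ((0, 0), (3, 0)), (3, 3)), "Partial"),
        ]
        for g, expected in cases:
            assert classify_macrostate(g, p) == expected, g

    def test_classification_total_and_unique(self, baseline, baseline_space):
        labels = classify_states(baseline_space, baseline)
        assert set(labels) <= set(MACROSTATES)
        # every label actually occurs at L=5
        assert set(labels) == set(MACROSTATES)

    def test_scalar_agrees_with_vectorised(self, baseline, baseline_space):
        labels = classify_states(baseline_space, baseline)
        rng = np.random.default_rng(0)
        for i in rng.integers(0, len(baseline_space), size=200):
            g = ReducedGenotype(int(baseline_space.M[i]),
                                tuple(map(tuple, baseline_space.k[i].tolist())),
                                tuple(int(s) for s in baseline_space.sigma[i]))
            assert classify_macrostate(g, baseline) == labels[i]


class TestFreeFitness:
    def test_neutral_limit_ranks_by_counts(self, small, small_space):
        p0 = small.replace(s=1e-12)
        fhat = macrostate_free_fitness(small_space, p0)
        counts = thermo.macrostate_counts(small_space, params=p0)
        order_f = sorted(MACROSTATES, key=lambda z: fhat[z])
        order_c = sorted(MACROSTATES, key=lambda z: math.log(max(counts[z], 1)))
        assert order_f == order_c

    def test_rho_sensitivity_pattern(self, baseline, baseline_space):
        """Signal correlation barely moves the free fitness of macrostates
        without signal-dependent crosstalk: Specialize-Both (correct
        expression at any rho) is the most rho-robust, No-Regulation (only
        residual weak-binding expression) several-fold more robust than the
        crosstalk-prone Initial and One-TF-Lost states."""
        vals = {z: [] for z in MACROSTATES}
        for rho in (-0.9, -0.5, 0.0, 0.5, 0.9):
            fhat = macrostate_free_fitness(baseline_space, baseline.replace(rho=rho))
            for z in vals:
                vals[z].append(fhat[z])
        spread = {z: np.ptp(v) for z, v in vals.items()}
        assert spread["SpecializeBoth"] == min(spread.values())
        for z in ("Initial", "OneTFLost"):
            assert spread["NoRegulation"] < spread[z] / 3.0

    def test_argmax_matches_steady_state_dominance(self, baseline, baseline_space):
        """P_SS(z) proportional to exp(2N Fhat(z)): the free-fitness argmax is
        the dominant steady-state macrostate; at Ns=25, rho=0 that is
        SpecializeBoth."""
        from tfspec import chain

        fhat = macrostate_free_fitness(baseline_space, baseline)
        best = max(fhat, key=fhat.get)
        assert best == "SpecializeBoth"
        cm = chain.build_chain(baseline, baseline_space)
        P = chain.steady_state(cm)
        probs = chain.macrostate_probabilities(baseline_space, baseline, P, cm.labels)
        assert max(probs, key=probs.get) == best
        # quantitative consistency of the soft-max identity
        logp = {z: 2 * baseline.N * fhat[z] for z in MACROSTATES}
        ref = max(logp.values())
        expect = {z: math.exp(v - ref) for z, v in logp.items()}
        norm = sum(expect.values())
        for z in MACROSTATES:
            assert probs[z] == pytest.approx(expect[z] / norm, abs=1e-9)

    def test_empty_macrostate_is_minus_inf(self, tiny, tiny_space):
        labels = classify_states(tiny_space, tiny)
        fhat = macrostate_free_fitness(tiny_space, tiny, labels=labels)
        for z in MACROSTATES:
            if not (labels == z).any():
                assert fhat[z] == float("-inf")
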