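"""Mark-recapture likelihood: quadrature vs enumeration oracle, closed
forms, invariances, and the two implementation routes."""

import numpy as np
import pytest

from aukipm import (DetectionParams, EncounterData, VitalRates, brute_force_loglik,
                    dataset_loglik, gamma_poisson_zero_mass, gamma_quadrature,
                    individual_loglik)
from aukipm.cmr import _params_to_arrays, forward_logliks, forward_logliks_fast

from conftest import random_detection, random_history, random_rates


class TestGammaQuadrature:
    @pytest.mark.parametrize("theta", [0.5, 2.0, 16.2, 39.0, 1e6, 1e8])
    def test_moments(self, theta):
        """Nodes/weights integrate low-order moments of Gamma(theta, theta)
        exactly: mean 1, variance 1/theta, third central moment 2/theta^2."""
        h, w = gamma_quadrature(theta, 32)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w @ h == pytest.approx(1.0, rel=1e-10)
        assert w @ (h - 1.0) ** 2 == pytest.approx(1.0 / theta, rel=1e-6)
        assert w @ (h - 1.0) ** 3 == pytest.approx(2.0 / theta ** 2, rel=1e-4)

    def test_zero_mass_identity(self):
        """Quadrature of exp(-eps*h) reproduces the closed-form gamma-Poisson
        zero mass."""
        for theta in (0.7, 11.0, 150.0):
            h, w = gamma_quadrature(theta, 32)
            for eps in (0.3, 1.0, 2.5):
                assert w @ np.exp(-eps * h) == pytest.approx(
                    gamma_poisson_zero_mass(theta, eps), rel=1e-9)


class TestOracleEquivalence:
    def test_small_histories(self):
        """Forward-plus-quadrature equals exhaustive latent-path enumeration
        with the analytic gamma integral, across extreme heterogeneity."""
        rng = np.random.default_rng(10)
        checked = 0
        for T in (2, 4, 6):
            for _ in range(25):
                theta = rng.choice([0.5, 16.2, 39.0, 1e6])
                rates = random_rates(rng, T)
                det = random_detection(rng, T, theta=theta)
                c, m, age = random_history(rng, T)
                l_quad = individual_loglik(c, m, age, rates, det)
                l_enum = brute_force_loglik(c, m, age, rates, det)
                assert abs(l_quad - l_enum) <= 1e-6, (T, theta, c, m, age)
                checked += 1
        assert checked == 75

    def test_node_doubling(self):
        """32- and 64-node quadrature agree to 1e-8 (resolution check)."""
        rng = np.random.default_rng(3)
        T = 8
        for _ in range(30):
            rates = random_rates(rng, T)
            det = random_detection(rng, T, theta=rng.choice([0.5, 5.0, 39.0]))
            c, m, age = random_history(rng, T)
            l32 = individual_loglik(c, m, age, rates, det, n_quadrature=32)
            l64 = individual_loglik(c, m, age, rates, det, n_quadrature=64)
            assert abs(l32 - l64) <= 1e-8

    def test_degenerate_gamma_limit(self):
        """At huge theta the gamma collapses on h = 1 and the enumeration
        must agree with a homogeneous Poisson hidden-Markov enumeration."""
        import itertools

        from aukipm.cmr import (ALIVE_AVAILABLE, ALIVE_UNAVAILABLE, DEAD,
                                LatentStateSpace, _poisson_pmf)

        rng = np.random.default_rng(4)
        T = 5
        for _ in range(10):
            rates = random_rates(rng, T)
            det = random_detection(rng, T, theta=1e8)
            c, m, age = random_history(rng, T)
            chick = age == 1
            ages = np.where(chick, np.clip(np.arange(T) - m, 0, 4), 4)
            grp = (ages >= 4).astype(int)
            eps_t = det.epsilon[grp, np.arange(T)]
            mats = []
            for t in range(m, T - 1):
                phi = rates.alpha1[t] if (chick and t == m) else rates.alpha2[t]
                a = int(np.clip(ages[t], 1, 4))
                mats.append(LatentStateSpace.transition_matrix(
                    phi, det.gamma1[a - 1], det.gamma2[a - 1],
                    force_unavailable=bool(chick and t == m)))
            total = 0.0
            for path in itertools.product((DEAD, ALIVE_UNAVAILABLE, ALIVE_AVAILABLE),
                                          repeat=T - 1 - m):
                states = (ALIVE_AVAILABLE,) + path
                pr = 1.0
                for s, (a, b) in enumerate(zip(states[:-1], states[1:])):
                    pr *= mats[s][a, b]
                for j, s in enumerate(states):
                    t = m + j
                    if s == ALIVE_AVAILABLE:
                        pr *= float(_poisson_pmf(np.array([c[t]]),
                                                 np.array([eps_t[t]]))[0])
                    elif c[t] != 0:
                        pr = 0.0
                total += pr
            total /= 1.0 - np.exp(-eps_t[m])
            l_enum = brute_force_loglik(c, m, age, rates, det)
            assert abs(l_enum - np.log(total)) < 1e-6

    def test_enumeration_span_guard(self):
        rng = np.random.default_rng(5)
        T = 12
        rates = random_rates(rng, T)
        det = random_detection(rng, T)
        c = np.zeros(T, dtype=int)
        c[0] = 1
        with pytest.raises(ValueError, match="paths refused"):
            brute_force_loglik(c, 0, 4, rates, det)


class TestClosedForms:
    def test_certain_event(self):
        """Adult marked with certain survival/availability and zero encounter
        rate: the only possible history has probability one."""
        rates = VitalRates(alpha1=[0.3], alpha2=[1 - 1e-15], f=[0.5, 0.5], omega=0.0)
        det = DetectionParams(gamma1=[0.2] * 4, gamma2=[1 - 1e-15] * 4,
                              epsilon=np.zeros((2, 2)), theta=5.0)
        assert individual_loglik(np.array([1, 0]), 0, 4, rates, det) == pytest.approx(0.0)

    @pytest.mark.parametrize("theta,eps", [(7.0, 1.5), (39.0, 2.0), (16.2, 1.0)])
    def test_single_occasion_zero_mass(self, theta, eps):
        """With certain survival and availability, P(no encounters on the one
        post-marking occasion) is the gamma-Poisson zero mass; the marking
        occasion is made uninformative by a zero marking-season rate."""
        rates = VitalRates(alpha1=[0.3], alpha2=[1 - 1e-15], f=[0.5, 0.5], omega=0.0)
        det = DetectionParams(gamma1=[0.2] * 4, gamma2=[1 - 1e-15] * 4,
                              epsilon=np.array([[0.0, 1.0], [0.0, eps]]), theta=theta)
        ll = individual_loglik(np.array([1, 0]), 0, 4, rates, det)
        assert ll == pytest.approx(np.log(gamma_poisson_zero_mass(theta, eps)),
                                   abs=1e-10)

    def test_zero_history_monotone_in_eps(self):
        """P(never seen again) decreases as the post-marking encounter rate
        rises (the marking-season rate is held fixed: it sits inside the
        conditioning on the marking event)."""
        rates = VitalRates(alpha1=[0.3] * 3, alpha2=[0.85] * 3, f=[0.5] * 4, omega=0.0)
        c = np.array([2, 0, 0, 0])
        prev = 0.0
        for eps in (0.5, 1.0, 2.0, 4.0):
            eps_mat = np.full((2, 4), eps)
            eps_mat[:, 0] = 1.0
            det = DetectionParams(gamma1=[0.3] * 4, gamma2=[0.8] * 4,
                                  epsilon=eps_mat, theta=10.0)
            ll = brute_force_loglik(c, 0, 4, rates, det)
            if prev:
                assert ll < prev
            prev = ll


class TestDatasetLoglik:
    def test_two_identical_individuals(self):
        rng = np.random.default_rng(6)
        T = 6
        rates = random_rates(rng, T)
        det = random_detection(rng, T)
        c, m, age = random_history(rng, T)
        enc1 = EncounterData(counts=c[None, :], mark_idx=[m], age_at_mark=[age])
        enc2 = EncounterData(counts=np.vstack([c, c]), mark_idx=[m, m],
                             age_at_mark=[age, age])
        assert dataset_loglik(enc2, rates, det) == pytest.approx(
            2.0 * dataset_loglik(enc1, rates, det), rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        T = 6
        rates = random_rates(rng, T)
        det = random_detection(rng, T)
        hists = [random_history(rng, T) for _ in range(50)]
        counts = np.array([h[0] for h in hists])
        mark = np.array([h[1] for h in hists])
        age = np.array([h[2] for h in hists])
        enc = EncounterData(counts=counts, mark_idx=mark, age_at_mark=age)
        perm = rng.permutation(50)
        enc_p = EncounterData(counts=counts[perm], mark_idx=mark[perm],
                              age_at_mark=age[perm])
        assert dataset_loglik(enc, rates, det) == pytest.approx(
            dataset_loglik(enc_p, rates, det), rel=1e-12)

    def test_matches_oracle_sum(self):
        rng = np.random.default_rng(8)
        T = 5
        rates = random_rates(rng, T)
        det = random_detection(rng, T)
        hists = [random_history(rng, T) for _ in range(20)]
        enc = EncounterData(counts=np.array([h[0] for h in hists]),
                            mark_idx=[h[1] for h in hists],
                            age_at_mark=[h[2] for h in hists])
        expected = sum(brute_force_loglik(c, m, a, rates, det) for c, m, a in hists)
        assert dataset_loglik(enc, rates, det) == pytest.approx(expected, abs=1e-6)

    def test_empty_dataset_warns(self):
        rng = np.random.default_rng(9)
        enc = EncounterData(counts=np.zeros((0, 4), dtype=int), mark_idx=[],
                            age_at_mark=[])
        with pytest.warns(RuntimeWarning):
            assert dataset_loglik(enc, random_rates(rng, 4),
                                  random_detection(rng, 4)) == 0.0

    def test_nonfinite_parameter_rejected(self):
        rng = np.random.default_rng(12)
        T = 4
        rates = random_rates(rng, T)
        det = random_detection(rng, T)
        c, m, age = random_history(rng, T)
        bad = _params_to_arrays(rates, det, T)
        a1 = bad[0].copy()
        a1[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            forward_logliks(c[None, :], np.array([m]), np.array([age == 1]),
                            a1, *bad[1:])


def test_compiled_route_matches_reference():
    """The compiled scalar-loop kernel and the vectorized numpy forward
    recursion give identical log-likelihoods."""
    rng = np.random.default_rng(11)
    T = 9
    hists = [random_history(rng, T) for _ in range(60)]
    counts = np.array([h[0] for h in hists])
    mark = np.array([h[1] for h in hists])
    chick = np.array([h[2] == 1 for h in hists])
    for theta in (0.8, 39.0):
        rates = random_rates(rng, T)
        det = random_detection(rng, T, theta=theta)
        args = _params_to_arrays(rates, det, T)
        ll_np = forward_logliks(counts, mark, chick, *args)
        ll_nb = forward_logliks_fast(counts, mark, chick, *args)
        np.testing.assert_allclose(ll_nb, ll_np, rtol=1e-10, atol=1e-10)
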