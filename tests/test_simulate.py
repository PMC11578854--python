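"""Synthetic-data generator: exact limiting cases, stochastic moment checks,
type invariants and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from aukipm import DetectionParams, VitalRates
from aukipm.cmr import gamma_poisson_zero_mass
from aukipm.simulate import (ScenarioConfig, calibration_scenario, one_step_transition,
                             reduced_scenario, simulate_bundle, simulate_counts,
                             simulate_encounters, simulate_population,
                             simulate_productivity)


class TestPopulationProcess:
    def test_certain_survival_recruits_everything(self):
        """With survival 1 and two chicks per pair (times 1/2 for the
        female-based model), next year's first-year class equals this year's
        breeding population exactly."""
        rng = np.random.default_rng(0)
        n = np.array([10, 20, 30, 500, 40], dtype=np.int64)
        for _ in range(20):
            out = one_step_transition(n, alpha1=1.0, alpha2=1.0, f=2.0,
                                      omega=0.0, rng=rng)
            assert out[0] == n[3] + n[4]

    def test_zero_survival_extinguishes(self):
        cfg = calibration_scenario(0)
        rates = VitalRates(alpha1=np.full(9, 1e-12), alpha2=np.full(9, 1e-12),
                           f=np.full(10, 0.5), omega=0.0, n_years=10)
        cfg2 = ScenarioConfig(design=cfg.design, rates=rates,
                              detection=cfg.detection, initial_total_pairs=100,
                              chicks_marked_per_year=0, adults_marked_per_year=0,
                              burrows_per_year=10, rng_seed=1,
                              initial_immigrant_lambda=5)
        with pytest.warns(RuntimeWarning, match="hit zero"):
            states = simulate_population(cfg2)
        assert states.extinct
        assert np.all(states.Ntot[2:] == 0)

    def test_binomial_moment_adult_survival(self):
        """Across replicates, N2[t+1]/N1[t] concentrates on adult survival."""
        rng = np.random.default_rng(2)
        n1 = 500
        reps = 1000
        draws = rng.binomial(n1, 0.85, size=reps)  # oracle distribution
        sim = np.array([one_step_transition(
            np.array([n1, 0, 0, 800, 50]), 0.30, 0.85, 0.55, 0.08, rng)[1]
            for _ in range(reps)])
        se = np.sqrt(0.85 * 0.15 / n1 / reps)
        assert abs(sim.mean() / n1 - 0.85) <= 3 * se + 3 * draws.std() / n1 / np.sqrt(reps)


class TestObservationStreams:
    def test_poisson_counts_moments(self):
        rng = np.random.default_rng(3)
        ntot = 8000
        draws = rng.poisson(ntot, size=10_000)
        assert abs(draws.mean() - ntot) <= 3.0 * np.sqrt(ntot / 10_000)

    def test_counts_only_survey_years(self):
        cfg = calibration_scenario(4)
        states = simulate_population(cfg)
        sc = simulate_counts(states, cfg.design, 5)
        assert set(sc.counts) == set(cfg.design.survey_indices.tolist())

    def test_zero_population_zero_count(self):
        rng = np.random.default_rng(0)
        assert rng.poisson(0) == 0  # observation law at Ntot = 0

    def test_productivity_limits_and_moments(self):
        rng = np.random.default_rng(5)
        ones = simulate_productivity(np.full(4, 1.0 - 1e-15), 100, rng)
        np.testing.assert_array_equal(ones.fledged, ones.burrows)
        zeros = simulate_productivity(np.full(4, 1e-15), 100, rng)
        assert zeros.fledged.sum() == 0
        reps = np.array([simulate_productivity([0.55], 100, rng).fledged[0]
                         for _ in range(10_000)])
        se = np.sqrt(100 * 0.55 * 0.45 / 10_000)
        assert abs(reps.mean() - 55.0) <= 3.0 * se


class TestEncounterGeneration:
    def _mini_config(self, theta, eps, T=4, chicks=0, adults=400, seed=0):
        cfg = calibration_scenario(seed)
        rates = VitalRates(alpha1=np.full(T - 1, 1 - 1e-12),
                           alpha2=np.full(T - 1, 1 - 1e-12),
                           f=np.full(T, 0.5), omega=0.0, n_years=T)
        design_years = tuple(range(2000, 2000 + T))
        from aukipm import StudyDesign
        design = StudyDesign(years=design_years, survey_years=design_years[:1])
        det = DetectionParams(gamma1=[1 - 1e-12] * 4, gamma2=[1 - 1e-12] * 4,
                              epsilon=np.full((2, T), eps), theta=theta)
        return ScenarioConfig(design=design, rates=rates, detection=det,
                              initial_total_pairs=6000, chicks_marked_per_year=chicks,
                              adults_marked_per_year=adults, burrows_per_year=10,
                              rng_seed=seed, initial_immigrant_lambda=5)

    def test_zero_rate_zero_counts(self):
        """Certain survival/availability but zero encounter rate: nothing is
        ever seen after marking (and the marking count is 1 in the limit)."""
        cfg = self._mini_config(theta=5.0, eps=0.0, adults=50)
        states = simulate_population(cfg, 0)
        enc = simulate_encounters(cfg, states, 1)
        post = enc.counts.copy()
        post[np.arange(enc.n_individuals), enc.mark_idx] = 0
        assert post.sum() == 0

    def test_gamma_poisson_marginal_pmf(self):
        """One-occasion counts from always-available adults follow the
        negative-binomial (gamma-Poisson) marginal; chi-square check at the
        reported razorbill-like overdispersion."""
        theta, eps = 16.2, 1.0
        cfg = self._mini_config(theta=theta, eps=eps, T=4, adults=2500, seed=7)
        states = simulate_population(cfg, 0)
        enc = simulate_encounters(cfg, states, 2)
        first_cohort = enc.mark_idx == 0
        c = enc.counts[first_cohort, 1]      # first post-marking occasion
        n = c.size
        assert n >= 2400
        kmax = 8
        obs = np.bincount(np.minimum(c, kmax), minlength=kmax + 1)
        from scipy.special import gammaln
        ks = np.arange(kmax)
        logpmf = (gammaln(ks + theta) - gammaln(theta) - gammaln(ks + 1)
                  + theta * np.log(theta / (theta + eps))
                  + ks * np.log(eps / (theta + eps)))
        p = np.exp(logpmf)
        p = np.append(p, 1.0 - p.sum())
        chi2 = ((obs - n * p) ** 2 / (n * p)).sum()
        # 99.9% quantile of chi-square with kmax dof
        assert chi2 < stats.chi2.ppf(0.999, kmax)

    def test_large_theta_approaches_poisson_variance(self):
        """Heterogeneity vanishes as theta grows: the count variance among
        available adults approaches the Poisson variance (= eps), while a
        small theta leaves clear overdispersion."""
        out = {}
        for theta in (1.0, 1e8):
            cfg = self._mini_config(theta=theta, eps=2.0, T=3, adults=5000, seed=3)
            states = simulate_population(cfg, 0)
            enc = simulate_encounters(cfg, states, 4)
            c = enc.counts[enc.mark_idx == 0, 1]
            out[theta] = c.var(ddof=1)
        assert abs(out[1e8] - 2.0) < 0.15
        assert out[1.0] > 4.0                 # eps + eps^2/theta = 6

    def test_marking_counts_positive(self):
        cfg = reduced_scenario(3)
        bundle, _ = simulate_bundle(cfg)
        enc = bundle.encounters
        assert np.all(enc.counts[np.arange(enc.n_individuals), enc.mark_idx] >= 1)

    def test_truncation_warns(self):
        cfg = self._mini_config(theta=5.0, eps=1.0, adults=10_000)
        states = simulate_population(cfg, 0)
        with pytest.warns(RuntimeWarning, match="truncated"):
            simulate_encounters(cfg, states, 1)


class TestReproducibility:
    def test_same_seed_same_bundle(self):
        b1, s1 = simulate_bundle(calibration_scenario(9))
        b2, s2 = simulate_bundle(calibration_scenario(9))
        np.testing.assert_array_equal(b1.encounters.counts, b2.encounters.counts)
        assert b1.surveys.counts == b2.surveys.counts
        np.testing.assert_array_equal(s1.as_matrix(), s2.as_matrix())

    def test_invariants_across_seeds(self):
        for seed in range(4):
            bundle, states = simulate_bundle(calibration_scenario(seed))
            enc = bundle.encounters
            assert np.all(enc.counts >= 0)
            assert np.all(states.Ntot == states.N4 + states.Nimm)
            assert np.all(bundle.productivity.fledged <= bundle.productivity.burrows)
            bundle.surveys.validate_against(bundle.design)
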