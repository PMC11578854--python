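"""Transient LTRE: exact growth algebra, sensitivities, decomposition
identities and qualitative attribution."""

import numpy as np
import pytest

from aukipm import build_projection_matrix, stable_stage_distribution
from aukipm.ltre import (LtreInput, PARAM_NAMES, annual_contributions,
                         growth_function, process_correlations, sensitivities,
                         variance_contributions)


def theta_vec(a1, a2, f, om, props):
    return np.array([a1, a2, f, om, *props])


def make_input(rng, T=12, sd=0.03, vary=("alpha1", "alpha2", "f"),
               base=(0.3, 0.85, 0.55, 0.08)):
    names = ("alpha1", "alpha2", "f", "omega")
    cols = {}
    for name, mean in zip(names, base):
        noise = sd * rng.standard_normal(T) if name in vary else np.zeros(T)
        cols[name] = np.clip(mean + noise, 0.01, 0.99)
    props = np.abs(rng.normal([0.1, 0.08, 0.07, 0.6, 0.15], 0.01, size=(T, 5)))
    props /= props.sum(axis=1, keepdims=True)
    return LtreInput(alpha1=cols["alpha1"], alpha2=cols["alpha2"], f=cols["f"],
                     omega=cols["omega"], proportions=props)


class TestGrowthFunction:
    def test_pure_survival(self):
        th = theta_vec(0.0, 1.0, 0.0, 0.0, [0.2, 0.2, 0.2, 0.2, 0.2])
        assert growth_function(th) == pytest.approx(1.0)

    def test_all_rates_zero(self):
        th = theta_vec(0.0, 0.0, 0.0, 0.0, [0.2, 0.2, 0.2, 0.2, 0.2])
        assert growth_function(th) == pytest.approx(0.0)

    def test_equals_leading_eigenvalue_at_stable_stage(self):
        """At the stable stage structure the one-step total growth is the
        asymptotic growth rate (eigen oracle from the projection matrix)."""
        A = build_projection_matrix(0.30, 0.85, 0.55, 0.08)
        v, lam = stable_stage_distribution(A)
        th = theta_vec(0.30, 0.85, 0.55, 0.08, v)
        assert growth_function(th) == pytest.approx(lam, abs=1e-10)

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            growth_function(theta_vec(0.3, 0.8, 0.5, 0.1, [0.5, 0.2, 0.2, 0.2, 0.2]))


class TestSensitivities:
    def test_adult_survival_partial_is_one(self):
        th = theta_vec(0.3, 0.85, 0.55, 0.08, [0.1, 0.1, 0.1, 0.55, 0.15])
        s = sensitivities(th)
        assert s[PARAM_NAMES.index("alpha2")] == pytest.approx(1.0)

    def test_productivity_partial(self):
        props = [0.1, 0.1, 0.1, 0.55, 0.15]
        th = theta_vec(0.3, 0.85, 0.55, 0.08, props)
        s = sensitivities(th)
        assert s[PARAM_NAMES.index("f")] == pytest.approx(0.3 / 2 * (0.55 + 0.15))

    def test_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            props = rng.dirichlet(np.ones(5))
            th = theta_vec(*rng.uniform(0.05, 0.9, 4), props)
            np.testing.assert_allclose(sensitivities(th),
                                       sensitivities(th, numeric=True),
                                       atol=1e-8)


class TestVarianceContributions:
    def test_constant_series_zero(self):
        rng = np.random.default_rng(1)
        inp = make_input(rng, vary=())
        props = np.repeat(inp.proportions[:1], inp.n_intervals, axis=0)
        inp = LtreInput(alpha1=inp.alpha1, alpha2=inp.alpha2, f=inp.f,
                        omega=inp.omega, proportions=props)
        res = variance_contributions(inp)
        assert res.total_variance == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(res.contributions, 0.0, atol=1e-18)

    def test_single_source_gets_full_attribution(self):
        rng = np.random.default_rng(2)
        inp = make_input(rng, vary=("alpha2",))
        props = np.repeat(inp.proportions[:1], inp.n_intervals, axis=0)
        inp = LtreInput(alpha1=inp.alpha1, alpha2=inp.alpha2, f=inp.f,
                        omega=inp.omega, proportions=props)
        res = variance_contributions(inp)
        i = PARAM_NAMES.index("alpha2")
        assert res.percent[i] == pytest.approx(100.0, abs=1e-8)
        assert res.own_variance[i] == pytest.approx(res.total_variance, rel=1e-10)

    def test_first_order_matches_direct_variance(self):
        """Under small perturbations the summed contributions reproduce the
        directly computed Var(lambda(theta_t)) within 10%."""
        rng = np.random.default_rng(3)
        inp = make_input(rng, T=400, sd=0.01)
        res = variance_contributions(inp)
        lam_t = growth_function(inp.matrix())
        direct = np.var(lam_t, ddof=1)
        assert res.total_variance == pytest.approx(direct, rel=0.10)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(4)
        res = variance_contributions(make_input(rng))
        assert res.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_scale_equivariance(self):
        """Multiplying all abundances by a constant leaves proportions, hence
        lambda and all contributions, unchanged (proportions are scale-free
        by construction: recompute from scaled abundances)."""
        rng = np.random.default_rng(5)
        N = rng.integers(50, 5000, size=(10, 5)).astype(float)
        a1 = np.full(10, 0.3) + 0.02 * rng.standard_normal(10)
        for scale in (1.0, 7.0, 123.0):
            P = (N * scale) / (N * scale).sum(axis=1, keepdims=True)
            inp = LtreInput(alpha1=a1, alpha2=0.85, f=0.55, omega=0.08,
                            proportions=P)
            res = variance_contributions(inp)
            if scale == 1.0:
                ref = res.contributions.copy()
            else:
                np.testing.assert_allclose(res.contributions, ref, rtol=1e-12)

    def test_too_short_series_error(self):
        rng = np.random.default_rng(6)
        inp = make_input(rng, T=2)
        with pytest.raises(ValueError):
            variance_contributions(inp)


class TestAnnualContributions:
    def test_identical_years_zero_row(self):
        rng = np.random.default_rng(7)
        inp = make_input(rng, T=6, vary=())
        props = np.repeat(inp.proportions[:1], 6, axis=0)
        inp = LtreInput(alpha1=inp.alpha1, alpha2=inp.alpha2, f=inp.f,
                        omega=inp.omega, proportions=props)
        np.testing.assert_allclose(annual_contributions(inp), 0.0, atol=1e-15)

    def test_only_changing_parameter_contributes(self):
        T = 6
        f = np.linspace(0.4, 0.7, T)
        props = np.repeat([[0.1, 0.1, 0.1, 0.55, 0.15]], T, axis=0)
        inp = LtreInput(alpha1=0.3, alpha2=0.85, f=f, omega=0.08, proportions=props)
        ann = annual_contributions(inp)
        i_f = PARAM_NAMES.index("f")
        assert np.all(ann[:, i_f] != 0.0)
        mask = np.ones(9, dtype=bool)
        mask[i_f] = False
        np.testing.assert_allclose(ann[:, mask], 0.0, atol=1e-15)

    def test_row_sums_track_delta_lambda(self):
        rng = np.random.default_rng(8)
        inp = make_input(rng, T=30, sd=0.01)
        ann = annual_contributions(inp)
        lam_t = growth_function(inp.matrix())
        dlam = np.diff(lam_t)
        scale = np.maximum(np.abs(dlam), 1e-6)
        assert np.all(np.abs(ann.sum(axis=1) - dlam) / scale <= 0.05)


class TestProcessCorrelations:
    def test_duplicated_series_correlation_one(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal((50, 12))
        out = process_correlations({"alpha2": s, "f": s}, pairs=(("alpha2", "f"),))
        assert out["mean"][0] == pytest.approx(1.0)

    def test_antiphase_minus_one(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal((50, 12))
        out = process_correlations({"alpha2": s, "f": -s}, pairs=(("alpha2", "f"),))
        assert out["mean"][0] == pytest.approx(-1.0)

    def test_independent_series_interval_covers_zero(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((400, 15))
        b = rng.standard_normal((400, 15))
        out = process_correlations({"alpha2": a, "f": b}, pairs=(("alpha2", "f"),))
        assert out["lo"][0] < 0.0 < out["hi"][0]


def test_dominant_adult_survival_ranks_first():
    """When adult survival carries most temporal variance, it ranks first in
    the decomposition in nearly every replicate."""
    rng = np.random.default_rng(12)
    wins = 0
    for _ in range(20):
        inp = make_input(rng, T=15, sd=0.0, vary=())
        a2 = np.clip(0.85 + 0.06 * rng.standard_normal(15), 0.01, 0.99)
        a1 = np.clip(0.30 + 0.015 * rng.standard_normal(15), 0.01, 0.99)
        f = np.clip(0.55 + 0.015 * rng.standard_normal(15), 0.01, 0.99)
        inp = LtreInput(alpha1=a1, alpha2=a2, f=f, omega=0.08,
                        proportions=inp.proportions)
        res = variance_contributions(inp)
        if np.argmax(res.totals) == PARAM_NAMES.index("alpha2"):
            wins += 1
    assert wins >= 18
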