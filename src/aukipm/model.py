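"""Joint log-posterior of the integrated population model.

The IPM has three sub-models sharing parameters:

* a state-space matrix population model for the breeding-pair counts —
  binomial survival/recruitment transitions and a Poisson immigration draw
  propagate five latent abundance classes, and surveys observe the breeding
  population ``Ntot = N4 + Nimm`` with Poisson error;
* the zero-inflated gamma-Poisson mark-recapture submodel
  (:mod:`aukipm.cmr`) sharing the survival rates;
* a binomial model for annual fledging successes sharing productivity.

Temporal variation enters through logit-scale random year effects: survival
effects have fixed standard deviation 1 (a deliberately literal reading of a
unit-variance specification), productivity effects have an estimated standard
deviation ``sigma_f``, and (optionally) encounter rates get a shared
log-scale year-effect series with estimated standard deviation.

Two routes to the count-likelihood are provided: the *exact discrete* route
(:func:`state_process_logprob` + :func:`count_loglik` with integer latent
trajectories, sampled by the discrete engine in :mod:`aukipm.fit`) and the
*marginal* route (:func:`marginal_count_loglik`), which moment-matches the
binomial/Poisson transition kernels with Gaussians and integrates the latent
abundances out with a Kalman filter.  At colony scale (hundreds to thousands
of pairs) the Gaussian approximation is excellent, and it is what makes the
default fitting engine fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, log_expit

from .data import DataBundle, ProductivityData, SurveyCounts
from .demography import (DetectionParams, PopulationState, StudyDesign, VitalRates,
                         build_projection_matrix)

__all__ = [
    "PriorConfig", "ModelSpec", "ParameterVector", "ParamLayout",
    "state_process_logprob", "count_loglik", "productivity_loglik",
    "log_prior", "joint_log_posterior", "marginal_count_loglik",
    "kalman_smoother_sample", "initial_state_allocation",
]


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative defaults for parameters with no stated prior.

    Probability-scale means (survival, productivity, availability) get
    Uniform(0, 1); ``omega ~ Uniform(0, omega_max)``; ``sigma_f`` and the
    optional encounter-rate effect SD get Half-Normal(scale); ``theta`` gets
    Gamma(shape, rate) (default mean 20, SD 20 — wide on both sides of
    literature-scale heterogeneity); log encounter-rate means get
    Normal(0, log_eps_sd^2).  All overridable.
    """

    omega_max: float = 0.5
    sigma_f_scale: float = 1.0
    sigma_eps_scale: float = 1.0
    theta_shape: float = 1.0
    theta_rate: float = 0.05
    log_eps_sd: float = 1.5


@dataclass(frozen=True)
class ModelSpec:
    """Structural options of the IPM: study frame, effect toggles, priors."""

    design: StudyDesign
    initial_total_pairs: int
    initial_immigrant_lambda: float = 50.0
    survival_effect_sd: float = 1.0      # SD of logit-scale survival year effects
    survival_year_effects: bool = True
    f_year_effects: bool = True
    eps_year_effects: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)

    @property
    def n_years(self) -> int:
        return self.design.n_years


class ParamLayout:
    """Flat unconstrained parameterization of every model symbol.

    Order: logit means (alpha1, alpha2, f); survival year effects (2 x T-1,
    centered, fixed SD); productivity year effects (T, centered, estimated
    SD); log sigma_f; scaled-logit omega; logit gamma1 (4); logit gamma2
    (4); log epsilon group means (2); log theta; then, when enabled, shared
    epsilon year effects (T, raw scores) and log sigma_eps.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        T = spec.n_years
        names: list[tuple[str, int]] = [("mu_a1", 1), ("mu_a2", 1), ("mu_f", 1)]
        if spec.survival_year_effects:
            names += [("eta_a1", T - 1), ("eta_a2", T - 1)]
        if spec.f_year_effects:
            names += [("eta_f", T)]
        names += [("log_sigma_f", 1), ("omega_u", 1),
                  ("logit_g1", 4), ("logit_g2", 4), ("log_eps", 2), ("log_theta", 1)]
        if spec.eps_year_effects:
            names += [("eta_eps_raw", T), ("log_sigma_eps", 1)]
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in names:
            self.slices[name] = slice(off, off + size)
            off += size
        self.size = off

    def get(self, X: np.ndarray, name: str) -> np.ndarray:
        if name not in self.slices:
            return np.zeros(X.shape[:-1] + (0,))
        return X[..., self.slices[name]]

    # ------------------------------------------------------------------
    def natural(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Map a (P, d) batch of unconstrained vectors to natural-scale
        parameter arrays (each with leading axis P)."""
        X = np.atleast_2d(X)
        spec = self.spec
        T = spec.n_years
        P = X.shape[0]
        g = self.get
        eta_a1 = (g(X, "eta_a1") * spec.survival_effect_sd
                  if spec.survival_year_effects else np.zeros((P, T - 1)))
        eta_a2 = (g(X, "eta_a2") * spec.survival_effect_sd
                  if spec.survival_year_effects else np.zeros((P, T - 1)))
        sigma_f = np.exp(g(X, "log_sigma_f")[:, 0])
        eta_f = g(X, "eta_f") if spec.f_year_effects else np.zeros((P, T))
        out = {
            "alpha1": expit(g(X, "mu_a1") + eta_a1),
            "alpha2": expit(g(X, "mu_a2") + eta_a2),
            "f": expit(g(X, "mu_f") + eta_f),
            "mean_alpha1": expit(g(X, "mu_a1")[:, 0]),
            "mean_alpha2": expit(g(X, "mu_a2")[:, 0]),
            "mean_f": expit(g(X, "mu_f")[:, 0]),
            "sigma_f": sigma_f,
            "omega": spec.priors.omega_max * expit(g(X, "omega_u")[:, 0]),
            "gamma1": expit(g(X, "logit_g1")),
            "gamma2": expit(g(X, "logit_g2")),
            "theta": np.exp(g(X, "log_theta")[:, 0]),
        }
        log_eps = g(X, "log_eps")
        if spec.eps_year_effects:
            sigma_eps = np.exp(g(X, "log_sigma_eps")[:, 0])
            eta_eps = g(X, "eta_eps_raw") * sigma_eps[:, None]
            out["sigma_eps"] = sigma_eps
            out["epsilon"] = np.exp(log_eps[:, :, None] + eta_eps[:, None, :])
        else:
            out["epsilon"] = np.repeat(np.exp(log_eps)[:, :, None], T, axis=2)
        return out

    def vital_rates(self, nat: dict[str, np.ndarray], p: int) -> VitalRates:
        return VitalRates(alpha1=nat["alpha1"][p], alpha2=nat["alpha2"][p],
                          f=nat["f"][p], omega=float(nat["omega"][p]),
                          n_years=self.spec.n_years)

    def detection(self, nat: dict[str, np.ndarray], p: int) -> DetectionParams:
        return DetectionParams(gamma1=nat["gamma1"][p], gamma2=nat["gamma2"][p],
                               epsilon=nat["epsilon"][p], theta=float(nat["theta"][p]))


@dataclass
class ParameterVector:
    """One point in parameter space: an unconstrained vector plus (for the
    discrete engine) explicit integer latent abundances.

    The unconstrained coordinates map one-to-one onto every model symbol via
    :class:`ParamLayout`; the latent :class:`PopulationState` is carried
    alongside because the discrete engine samples it rather than integrating
    it out.
    """

    x: np.ndarray
    layout: ParamLayout
    states: PopulationState | None = None

    def natural(self) -> dict[str, np.ndarray]:
        return self.layout.natural(self.x[None, :])

    def rates(self) -> VitalRates:
        return self.layout.vital_rates(self.natural(), 0)

    def detection(self) -> DetectionParams:
        return self.layout.detection(self.natural(), 0)


# ---------------------------------------------------------------------------
# exact discrete-state submodel terms
# ---------------------------------------------------------------------------

def state_process_logprob(states: PopulationState, rates: VitalRates) -> float:
    """Exact log-probability of an integer latent trajectory.

    Sums the binomial masses of the four survival/recruitment transitions and
    the Poisson mass of the immigration draw over every interval; impossible
    transitions (e.g. more survivors than candidates) give ``-inf``.
    """
    T = states.n_years
    if rates.n_years != T:
        raise ValueError(f"rates cover {rates.n_years} years, states {T}")
    N1, N2, N3, N4, Ni = (states.N1, states.N2, states.N3, states.N4, states.Nimm)
    ntot = states.Ntot
    p_recruit = rates.f[:-1] / 2.0 * rates.alpha1
    ll = stats.binom.logpmf(N1[1:], ntot[:-1], p_recruit).sum()
    ll += stats.binom.logpmf(N2[1:], N1[:-1], rates.alpha2).sum()
    ll += stats.binom.logpmf(N3[1:], N2[:-1], rates.alpha2).sum()
    ll += stats.binom.logpmf(N4[1:], N3[:-1] + ntot[:-1], rates.alpha2).sum()
    resident = N1[:-1] + N2[:-1] + N3[:-1] + N4[:-1]
    ll += stats.poisson.logpmf(Ni[1:], rates.omega * resident).sum()
    return float(ll)


def count_loglik(surveys: SurveyCounts, states: PopulationState) -> float:
    """Poisson survey likelihood: ``y_t ~ Poisson(Ntot_t)`` over survey years.

    Years without a survey contribute nothing (missing at random)."""
    if not surveys.counts:
        return 0.0
    idx = surveys.year_indices
    if idx.max() >= states.n_years:
        raise ValueError("survey count for a year with no latent state")
    ntot = states.Ntot[idx]
    return float(stats.poisson.logpmf(surveys.values, ntot).sum())


def productivity_loglik(prod: ProductivityData, f_series: np.ndarray) -> float:
    """Binomial fledging likelihood: ``J_t ~ Binomial(B_t, f_t)``."""
    f_series = np.asarray(f_series, dtype=float)
    if f_series.shape != (prod.n_years,):
        raise ValueError("productivity series length mismatch")
    return float(stats.binom.logpmf(prod.fledged, prod.burrows, f_series).sum())


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _logistic_logpdf(x: np.ndarray) -> np.ndarray:
    # density of logit(U), U ~ Uniform(0,1)
    return log_expit(x) + log_expit(-x)


def log_prior_batch(X: np.ndarray, layout: ParamLayout) -> np.ndarray:
    """Log prior density in unconstrained coordinates for a (P, d) batch.

    Uniform probability-scale priors become logistic densities; log-scale
    parameters carry their Jacobians.  Includes every random-effect score.
    """
    X = np.atleast_2d(X)
    spec = layout.spec
    pr = spec.priors
    g = layout.get
    _LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

    def norm_logpdf(v, sd=1.0):
        return -0.5 * (v / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI

    lp = _logistic_logpdf(g(X, "mu_a1")).sum(axis=1)
    lp += _logistic_logpdf(g(X, "mu_a2")).sum(axis=1)
    lp += _logistic_logpdf(g(X, "mu_f")).sum(axis=1)
    lp += _logistic_logpdf(g(X, "omega_u")).sum(axis=1)
    lp += _logistic_logpdf(g(X, "logit_g1")).sum(axis=1)
    lp += _logistic_logpdf(g(X, "logit_g2")).sum(axis=1)
    if spec.survival_year_effects:
        lp += norm_logpdf(g(X, "eta_a1")).sum(axis=1)
        lp += norm_logpdf(g(X, "eta_a2")).sum(axis=1)
    # sigma_f ~ Half-Normal(scale); sampled as log sigma (Jacobian +log sigma)
    ls = g(X, "log_sigma_f")[:, 0]
    sigma_f = np.exp(ls)
    if spec.f_year_effects:
        # centered year effects: eta_f ~ Normal(0, sigma_f)
        lp += norm_logpdf(g(X, "eta_f"), sd=sigma_f[:, None]).sum(axis=1)
    lp += -0.5 * (sigma_f / pr.sigma_f_scale) ** 2 + ls
    lp += norm_logpdf(g(X, "log_eps"), sd=pr.log_eps_sd).sum(axis=1)
    lt = g(X, "log_theta")[:, 0]
    theta = np.exp(lt)
    lp += (pr.theta_shape - 1.0) * lt - pr.theta_rate * theta + lt
    if spec.eps_year_effects:
        lp += norm_logpdf(g(X, "eta_eps_raw")).sum(axis=1)
        le = g(X, "log_sigma_eps")[:, 0]
        sig = np.exp(le)
        lp += -0.5 * (sig / pr.sigma_eps_scale) ** 2 + le
    return lp


def log_prior(pv: ParameterVector) -> float:
    """Log prior of one parameter vector (plus the initial-immigrant Poisson
    mass when explicit latent states are attached)."""
    lp = float(log_prior_batch(pv.x[None, :], pv.layout)[0])
    if pv.states is not None:
        lam = pv.layout.spec.initial_immigrant_lambda
        lp += float(stats.poisson.logpmf(pv.states.Nimm[0], lam))
    return lp


# ---------------------------------------------------------------------------
# initial state allocation
# ---------------------------------------------------------------------------

def _power_stable_stage(A: np.ndarray, n_squarings: int = 7) -> np.ndarray:
    """Batched leading right eigenvector by repeated squaring: ``A^(2^k) u``
    converges like a ``2^k``-step power iteration.  A is (P, 5, 5); returns
    (P, 5) proportions."""
    M = A.copy()
    for _ in range(n_squarings):
        M = M @ M
        M /= np.abs(M).sum(axis=(1, 2), keepdims=True) + 1e-300
    v = M @ np.full((A.shape[0], 5, 1), 0.2)
    v = np.clip(v[:, :, 0], 0.0, None)
    return v / v.sum(axis=1, keepdims=True)


def initial_state_allocation(spec: ModelSpec, rates: VitalRates) -> np.ndarray:
    """Year-1 mean abundances: immigrants at their prior mean, breeders making
    up the initial pair count, pre-breeders from the stable stage structure
    implied by the first-year rates."""
    A = build_projection_matrix(rates.alpha1[0], rates.alpha2[0], rates.f[0],
                                rates.omega)
    v = _power_stable_stage(A[None, :, :])[0]
    n_imm = min(spec.initial_immigrant_lambda, 0.5 * spec.initial_total_pairs)
    n4 = spec.initial_total_pairs - n_imm
    m = np.array([v[0] / v[3] * n4, v[1] / v[3] * n4, v[2] / v[3] * n4, n4, n_imm])
    return m


# ---------------------------------------------------------------------------
# marginal (Kalman) count likelihood
# ---------------------------------------------------------------------------

def _transition_matrices(nat: dict[str, np.ndarray], T: int) -> np.ndarray:
    """(P, T-1, 5, 5) expected-value projection matrices per interval."""
    P = nat["alpha1"].shape[0]
    A = np.zeros((P, T - 1, 5, 5))
    rec = nat["f"][:, :-1] / 2.0 * nat["alpha1"]
    a2 = nat["alpha2"]
    om = nat["omega"][:, None]
    A[:, :, 0, 3] = A[:, :, 0, 4] = rec
    A[:, :, 1, 0] = a2
    A[:, :, 2, 1] = a2
    A[:, :, 3, 2] = A[:, :, 3, 3] = A[:, :, 3, 4] = a2
    A[:, :, 4, 0] = A[:, :, 4, 1] = A[:, :, 4, 2] = A[:, :, 4, 3] = om
    return A


def _process_cov(nat: dict[str, np.ndarray], m: np.ndarray, t: int) -> np.ndarray:
    """Diagonal covariance of the stochastic transition at interval ``t``
    evaluated at predicted means ``m`` (P, 5): binomial variances for the four
    survival/recruitment draws, Poisson variance for immigration."""
    mc = np.clip(m, 0.0, None)
    ntot = mc[:, 3] + mc[:, 4]
    resident = mc[:, :4].sum(axis=1)
    p_rec = nat["f"][:, t] / 2.0 * nat["alpha1"][:, t]
    a2 = nat["alpha2"][:, t]
    P = m.shape[0]
    Q = np.zeros((P, 5, 5))
    Q[:, 0, 0] = ntot * p_rec * (1.0 - p_rec)
    Q[:, 1, 1] = mc[:, 0] * a2 * (1.0 - a2)
    Q[:, 2, 2] = mc[:, 1] * a2 * (1.0 - a2)
    Q[:, 3, 3] = (mc[:, 2] + ntot) * a2 * (1.0 - a2)
    Q[:, 4, 4] = nat["omega"] * resident
    return Q


_H = np.array([0.0, 0.0, 0.0, 1.0, 1.0])  # observation picks Ntot = N4 + Nimm


def _initial_moments(spec: ModelSpec, nat: dict[str, np.ndarray]):
    """Batched year-1 mean and covariance.

    Pre-breeder classes follow the stable stage structure of each draw's
    first-interval matrix; spread is Poisson-scale (variance = mean) per
    class, with the immigrant class at its prior Poisson variance.
    """
    P = nat["alpha1"].shape[0]
    A1 = np.zeros((P, 5, 5))
    rec = nat["f"][:, 0] / 2.0 * nat["alpha1"][:, 0]
    a2 = nat["alpha2"][:, 0]
    om = nat["omega"]
    A1[:, 0, 3] = A1[:, 0, 4] = rec
    A1[:, 1, 0] = a2
    A1[:, 2, 1] = a2
    A1[:, 3, 2] = A1[:, 3, 3] = A1[:, 3, 4] = a2
    A1[:, 4, 0] = A1[:, 4, 1] = A1[:, 4, 2] = A1[:, 4, 3] = om
    v = _power_stable_stage(A1)
    n_imm = min(spec.initial_immigrant_lambda, 0.5 * spec.initial_total_pairs)
    n4 = spec.initial_total_pairs - n_imm
    P = v.shape[0]
    m = np.empty((P, 5))
    m[:, :3] = v[:, :3] / v[:, 3:4] * n4
    m[:, 3] = n4
    m[:, 4] = n_imm
    C = np.zeros((P, 5, 5))
    C[:, np.arange(5), np.arange(5)] = np.clip(m, 1.0, None)
    return m, C


def marginal_count_loglik(X: np.ndarray, layout: ParamLayout,
                          surveys: SurveyCounts) -> np.ndarray:
    """Survey log-likelihood with latent abundances integrated out.

    Moment-matched Gaussian approximation of the binomial/Poisson state
    process (conditional mean ``A_t m``, conditional covariance from the
    kernel variances) run through a Kalman filter; Poisson observation error
    approximated as Gaussian with variance equal to the predicted breeding
    population.  Returns (P,) log-likelihoods for a (P, d) parameter batch.
    """
    X = np.atleast_2d(X)
    spec = layout.spec
    T = spec.n_years
    nat = layout.natural(X)
    A = _transition_matrices(nat, T)
    m, C = _initial_moments(spec, nat)
    Pn = X.shape[0]
    ll = np.zeros(Pn)
    obs = dict(zip(surveys.year_indices.tolist(), surveys.values.tolist()))
    for t in range(T):
        if t in obs:
            y = obs[t]
            yhat = m @ _H
            PH = C @ _H
            S = PH @ _H + np.clip(yhat, 1.0, None)
            ll += -0.5 * (np.log(2.0 * np.pi * S) + (y - yhat) ** 2 / S)
            K = PH / S[:, None]
            m = m + K * (y - yhat)[:, None]
            C = C - K[:, :, None] * PH[:, None, :]
        if t < T - 1:
            At = A[:, t]
            m_new = (At @ m[:, :, None])[:, :, 0]
            C = At @ C @ At.transpose(0, 2, 1) + _process_cov(nat, m, t)
            m = m_new
    return ll


def kalman_filter_moments(x: np.ndarray, layout: ParamLayout, surveys: SurveyCounts):
    """Filtered means/covariances per year for one parameter vector (used by
    the backward sampler).  Returns (means (T,5), covs (T,5,5), A (T-1,5,5),
    Q (T-1,5,5))."""
    X = x[None, :]
    spec = layout.spec
    T = spec.n_years
    nat = layout.natural(X)
    A = _transition_matrices(nat, T)[0]
    m, C = _initial_moments(spec, nat)
    m, C = m[0], C[0]
    obs = dict(zip(surveys.year_indices.tolist(), surveys.values.tolist())) if surveys else {}
    means = np.empty((T, 5))
    covs = np.empty((T, 5, 5))
    Qs = np.empty((T - 1, 5, 5))
    for t in range(T):
        if t in obs:
            y = obs[t]
            yhat = m @ _H
            PH = C @ _H
            S = PH @ _H + max(yhat, 1.0)
            K = PH / S
            m = m + K * (y - yhat)
            C = C - np.outer(K, PH)
        means[t] = m
        covs[t] = C
        if t < T - 1:
            Q = _process_cov(nat, m[None, :], t)[0]
            Qs[t] = Q
            m_new = A[t] @ m
            C = A[t] @ C @ A[t].T + Q
            m = m_new
    return means, covs, A, Qs


def kalman_smoother_sample(x: np.ndarray, layout: ParamLayout,
                           surveys: SurveyCounts,
                           rng: np.random.Generator) -> np.ndarray:
    """One posterior draw of the latent abundance trajectory (T, 5) by
    forward-filter backward-sampling under the Gaussian approximation.
    Values are continuous; clip/round for integer reporting."""
    means, covs, A, Qs = kalman_filter_moments(x, layout, surveys)
    T = means.shape[0]
    out = np.empty((T, 5))
    jitter = 1e-6 * np.eye(5)
    out[T - 1] = rng.multivariate_normal(means[T - 1], covs[T - 1] + jitter,
                                         method="cholesky")
    for t in range(T - 2, -1, -1):
        Ppred = A[t] @ covs[t] @ A[t].T + Qs[t]
        Ppred += 1e-6 * np.eye(5)
        J = covs[t] @ A[t].T @ np.linalg.inv(Ppred)
        mean = means[t] + J @ (out[t + 1] - A[t] @ means[t])
        cov = covs[t] - J @ A[t] @ covs[t]
        cov = 0.5 * (cov + cov.T) + jitter
        out[t] = rng.multivariate_normal(mean, cov, method="cholesky")
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# joint posterior (explicit-state form)
# ---------------------------------------------------------------------------

def joint_log_posterior(pv: ParameterVector, bundle: DataBundle,
                        n_quadrature: int = 32) -> float:
    """Exact joint log-posterior with explicit integer latent states.

    Sum of the prior, the discrete state-process mass, and the three data
    stream likelihoods (streams absent from the bundle contribute nothing,
    which is how the single-dataset fits arise).  ``-inf`` propagates cleanly
    from any impossible component.
    """
    from .cmr import dataset_loglik  # local import to avoid cycle at import time

    lp = log_prior(pv)
    if not np.isfinite(lp):
        return -np.inf
    rates = pv.rates()
    if pv.states is not None:
        lp += state_process_logprob(pv.states, rates)
        if not np.isfinite(lp):
            return -np.inf
        if bundle.surveys is not None:
            lp += count_loglik(bundle.surveys, pv.states)
    if bundle.productivity is not None:
        lp += productivity_loglik(bundle.productivity, rates.f)
    if bundle.encounters is not None and np.isfinite(lp):
        lp += dataset_loglik(bundle.encounters, rates, pv.detection(),
                             n_quadrature=n_quadrature)
    return float(lp)
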