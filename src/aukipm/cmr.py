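"""Marginal likelihood of encounter-count histories.

The observation model is a zero-inflated gamma-Poisson: each individual ``i``
carries a latent alive state ``z_{i,t}`` (Bernoulli survival process, first
transition after hatch-year marking at first-year survival ``alpha1``, all
later transitions at adult survival ``alpha2``), an availability state
``k_{i,t}`` (Markov on the previous availability with age-specific entry and
persistence probabilities ``gamma1``/``gamma2`` — temporary emigration and the
gradual return of pre-breeders), and a gamma-distributed detection multiplier
``h_i ~ Gamma(theta, theta)`` with mean 1.  Conditional on being available,
the season count is ``c_{i,t} ~ Poisson(epsilon_{g,t} * h_i)`` where
``epsilon`` is the group (pre-breeder / breeder) mean encounter rate.

The likelihood marginalizes the latent states with a three-state forward
(hidden-Markov) recursion and the heterogeneity ``h`` with fixed-node
Gauss-Laguerre-type quadrature over the gamma density.  Individuals enter the
data only by being encountered, so each history is conditioned on the marking
event: the marking-occasion count contributes a plain gamma-Poisson factor and
the whole history is divided by the marginal probability of at least one
encounter at marking, ``1 - (theta / (theta + epsilon_mark))**theta``.

:func:`brute_force_loglik` re-derives the same quantity by exhaustive
enumeration of latent paths with the gamma integral done analytically; it is
the test oracle for the quadrature path and is kept deliberately independent
of it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal
from scipy.special import gammaln, logsumexp

from .data import EncounterData
from .demography import DetectionParams, VitalRates

DEFAULT_QUADRATURE_NODES = 32

# latent states
DEAD, ALIVE_UNAVAILABLE, ALIVE_AVAILABLE = 0, 1, 2


def _gamma_jacobi_log(theta: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    out = _gamma_jacobi_log_cached(float(theta), int(n_nodes))
    return out


from functools import lru_cache  # noqa: E402  (placed near its single user)


@lru_cache(maxsize=512)
def _gamma_jacobi_log_cached(theta: float, n_nodes: int):
    return _gamma_jacobi_log_impl(theta, n_nodes)


def _gamma_jacobi_log_impl(theta: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss nodes (in the unit-scale variable ``x ~ Gamma(theta, 1)``) and
    *log*-weights for the normalized gamma measure.

    Nodes come from the Jacobi (symmetric tridiagonal) matrix of the
    generalized Laguerre polynomials; weights from the orthonormal-polynomial
    identity ``w_j = 1 / sum_k p_k(x_j)^2`` evaluated with running rescaling.
    Both steps stay finite and *relatively* accurate for any ``theta`` and any
    node count — the textbook generalized Gauss-Laguerre weights carry
    ``Gamma(theta)`` (overflow near ``theta ~ 170``) and eigenvector-squared
    weights lose all relative accuracy below ~1e-290, which matters here
    because exponential tilting (see :func:`forward_logliks`) re-inflates far
    tail nodes.
    """
    if not (np.isfinite(theta) and theta > 0):
        raise ValueError("theta must be positive")
    if n_nodes < 2:
        raise ValueError("need at least 2 quadrature nodes")
    k = np.arange(n_nodes, dtype=float)
    diag = 2.0 * k + theta           # recurrence for weight x^(theta-1) e^-x
    off = np.sqrt(k[1:] * (k[1:] + theta - 1.0))
    x = eigh_tridiagonal(diag, off, eigvals_only=True)
    p_prev = np.zeros_like(x)
    p = np.ones_like(x)
    logscale = np.zeros_like(x)
    ssq = np.ones_like(x)
    for kk in range(1, n_nodes):
        b_km1 = np.sqrt(kk * (kk + theta - 1.0))
        b_km2 = np.sqrt((kk - 1) * (kk + theta - 2.0)) if kk >= 2 else 0.0
        a = 2.0 * (kk - 1) + theta
        p, p_prev = ((x - a) * p - b_km2 * p_prev) / b_km1, p
        ssq += p * p
        mag = np.abs(p)
        big = mag > 1e100
        if big.any():
            s = np.where(big, mag, 1.0)
            p /= s
            p_prev /= s
            ssq /= s * s
            logscale += np.log(s)
    return x, -(np.log(ssq) + 2.0 * logscale)


def gamma_quadrature(theta: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and weights for the Gamma(theta, theta) measure.

    Weights are positive and sum to one; exact for polynomials up to degree
    ``2 * n_nodes - 1`` against the gamma density.
    """
    x, logw = _gamma_jacobi_log(theta, n_nodes)
    return x / theta, np.exp(logw)


def gamma_poisson_zero_mass(theta: float, epsilon) -> np.ndarray | float:
    """Marginal P(c = 0) for one available occasion: ``(theta/(theta+eps))**theta``."""
    eps = np.asarray(epsilon, dtype=float)
    out = np.exp(theta * (np.log(theta) - np.log(theta + eps)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LatentStateSpace:
    """Three-state latent space {DEAD, ALIVE_UNAVAILABLE, ALIVE_AVAILABLE}.

    DEAD is absorbing; emission from non-available states puts all mass on
    ``c = 0``.  Used by the enumeration oracle; the fast path inlines the same
    arithmetic.
    """

    @staticmethod
    def transition_matrix(phi: float, gamma1: float, gamma2: float,
                          force_unavailable: bool = False) -> np.ndarray:
        """Row-stochastic 3x3 transition for one season step.

        ``force_unavailable`` encodes the nestling season: a chick marked in
        the burrow fledges and is off-colony the following season regardless
        of the availability process.
        """
        if force_unavailable:
            gamma1 = gamma2 = 0.0
        P = np.array([
            [1.0, 0.0, 0.0],
            [1.0 - phi, phi * (1.0 - gamma1), phi * gamma1],
            [1.0 - phi, phi * (1.0 - gamma2), phi * gamma2],
        ])
        assert np.allclose(P.sum(axis=1), 1.0)
        return P

    @staticmethod
    def emission(count: int, epsilon: float, h: float) -> np.ndarray:
        """Emission probabilities of ``count`` from each state given the
        heterogeneity multiplier ``h``: non-available states emit only 0."""
        zero = 1.0 if count == 0 else 0.0
        lam = np.array([epsilon * h])
        avail = float(_poisson_pmf(np.array([count]), lam)[0])
        return np.array([zero, zero, avail])


def _poisson_pmf(c: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Elementwise Poisson pmf, safe at lam == 0 (mass 1 on c == 0)."""
    lam_safe = np.where(lam > 0.0, lam, 1.0)
    pmf = np.exp(c * np.log(lam_safe) - lam_safe - gammaln(c + 1.0))
    return np.where(lam > 0.0, pmf, (c == 0).astype(float))


def _age_class_matrix(mark: np.ndarray, chick: np.ndarray, T: int) -> np.ndarray:
    """(n, T) age class per season: chicks are 0 (hatch year) at marking and
    age one class per season capped at 4; adults are 4 throughout."""
    t = np.arange(T)[None, :]
    chick_age = np.clip(t - mark[:, None], 0, 4)
    return np.where(chick[:, None], chick_age, 4)


def forward_logliks(counts: np.ndarray, mark: np.ndarray, chick: np.ndarray,
                    alpha1: np.ndarray, alpha2: np.ndarray,
                    gamma1: np.ndarray, gamma2: np.ndarray,
                    epsilon: np.ndarray, theta: np.ndarray,
                    n_quadrature: int = DEFAULT_QUADRATURE_NODES) -> np.ndarray:
    """Per-history log-likelihoods for a batch of parameter sets.

    Parameters carry a leading batch axis ``P`` (use ``P = 1`` for a single
    parameter set): ``alpha1``/``alpha2`` are (P, T-1), ``gamma1``/``gamma2``
    (P, 4), ``epsilon`` (P, 2, T), ``theta`` (P,).  Histories are (n, T)
    counts with (n,) marking indices and chick flags.  Returns (P, n) log
    probabilities, already conditioned on the marking event.

    The forward recursion runs over the three latent states for every history
    and quadrature node simultaneously; probabilities stay in natural scale
    (float64 range is ample at study-scale horizons) and are logged once at
    the end.

    The gamma integral uses exponentially tilted quadrature: for a history
    whose maximum total encounter rate over the post-marking span is ``S``,
    nodes and weights are taken for the Gamma(theta, theta + S/2) measure and
    the tilt ``exp(S/2 * h)`` is folded into log-weights.  This keeps the
    integrand's exponential content centred on the measure, which is what
    makes 32 nodes adequate even at ``theta`` = 0.5, where the untilted rule
    needs hundreds of nodes.  Tilting only rescales nodes and reweights, so
    the Jacobi eigenproblem is solved once per parameter set.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n, T = counts.shape
    P = alpha1.shape[0]
    Q = int(n_quadrature)
    if Q < 8:
        raise ValueError("n_quadrature must be at least 8")
    for name, arr, shape in (("alpha1", alpha1, (P, T - 1)), ("alpha2", alpha2, (P, T - 1)),
                             ("gamma1", gamma1, (P, 4)), ("gamma2", gamma2, (P, 4)),
                             ("epsilon", epsilon, (P, 2, T))):
        if arr.shape != shape:
            raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
    if not (np.all(np.isfinite(alpha1)) and np.all(np.isfinite(alpha2))
            and np.all(np.isfinite(gamma1)) and np.all(np.isfinite(gamma2))
            and np.all(np.isfinite(epsilon)) and np.all(np.isfinite(theta))):
        raise ValueError("non-finite parameter passed to the CMR likelihood")

    xs = np.empty((P, Q))
    logw = np.empty((P, Q))
    for p in range(P):
        xs[p], logw[p] = _gamma_jacobi_log(float(theta[p]), Q)

    # sort histories by mark year so the active set is always a prefix slice
    order = np.argsort(mark, kind="stable")
    counts = counts[order]
    mark_s = mark[order]
    chick_s = np.asarray(chick, dtype=bool)[order]

    age = _age_class_matrix(mark_s, chick_s, T)        # (n, T)
    group = (age >= 4).astype(int)                     # (n, T) 0=pre-breeder
    eps_nt = epsilon[:, group, np.arange(T)[None, :]]  # (P, n, T)

    # per-history exponential tilt (see docstring)
    post_mark = np.arange(T)[None, :] >= mark_s[:, None]
    S = np.einsum("pnt,nt->pn", eps_nt, post_mark.astype(float))
    tilt = 0.5 * S                                     # (P, n)
    rate = theta[:, None] + tilt
    nodes = xs[:, None, :] / rate[:, :, None]          # (P, n, Q)
    logW = (logw[:, None, :] + tilt[:, :, None] * nodes
            + theta[:, None, None] * (np.log(theta[:, None, None]) - np.log(rate[:, :, None])))

    p0 = np.zeros((P, n, Q))
    p1 = np.zeros((P, n, Q))
    p2 = np.zeros((P, n, Q))

    g1_age = gamma1[:, np.clip(age, 1, 4) - 1]         # (P, n, T)
    g2_age = gamma2[:, np.clip(age, 1, 4) - 1]
    lgc = gammaln(counts + 1.0)                        # (n, T) log c!
    # log eps with zeros clamped far negative: c * clamp underflows exp to
    # exactly 0 for c > 0 while contributing nothing for c == 0
    log_eps_nt = np.log(np.where(eps_nt > 0.0, eps_nt, 1.0))
    log_eps_nt[eps_nt == 0.0] = -1e30

    starts = np.searchsorted(mark_s, np.arange(T + 1))
    for t in range(T):
        lo, hi = starts[t], starts[t + 1]
        if hi > lo:                                    # histories marked at t
            c_m = counts[lo:hi, t][None, :, None]
            eps_m = eps_nt[:, lo:hi, t][:, :, None]
            lam = eps_m * nodes[:, lo:hi, :]
            em = _poisson_pmf(c_m, lam)
            # epsilon exactly 0 at marking: the zero-truncated count piles all
            # mass on c = 1 in the limit (see module docstring)
            em = np.where(eps_m == 0.0, (c_m == 1).astype(float), em)
            p2[:, lo:hi, :] = em
        if t == T - 1:
            break
        na = starts[t + 1]                             # active prefix size
        if na == 0:
            continue
        sl = slice(0, na)
        forced = chick_s[sl] & (mark_s[sl] == t)       # nestling season
        phi = np.where(forced[None, :], alpha1[:, t, None], alpha2[:, t, None])
        g1 = np.where(forced[None, :], 0.0, g1_age[:, sl, t])
        g2 = np.where(forced[None, :], 0.0, g2_age[:, sl, t])
        a0, a1_, a2_ = p0[:, sl, :], p1[:, sl, :], p2[:, sl, :]
        phi_ = phi[:, :, None]
        pa = (a1_ * g1[:, :, None] + a2_ * g2[:, :, None]) * phi_
        pu = (a1_ * (1.0 - g1[:, :, None]) + a2_ * (1.0 - g2[:, :, None])) * phi_
        pd = a0 + (a1_ + a2_) * (1.0 - phi_)
        c_next = counts[sl, t + 1]
        lam = eps_nt[:, sl, t + 1][:, :, None] * nodes[:, sl, :]
        log_em = (c_next[None, :, None] * (log_eps_nt[:, sl, t + 1][:, :, None]
                                           + np.log(nodes[:, sl, :]))
                  - lam - lgc[None, sl, t + 1, None])
        em2 = np.exp(log_em)
        is_zero = (c_next == 0).astype(float)[None, :, None]
        p2[:, sl, :] = pa * em2
        p1[:, sl, :] = pu * is_zero
        p0[:, sl, :] = pd * is_zero

    F = p0 + p1 + p2
    shift = logW.max(axis=2, keepdims=True)            # (P, n, 1)
    lik = np.einsum("pnq,pnq->pn", np.exp(logW - shift), F)
    eps_mark = eps_nt[:, np.arange(n), mark_s]         # (P, n)
    trunc = 1.0 - np.exp(theta[:, None] * (np.log(theta[:, None])
                                           - np.log(theta[:, None] + eps_mark)))
    trunc = np.where(eps_mark > 0.0, trunc, 1.0)
    with np.errstate(divide="ignore"):
        out = np.log(lik) + shift[:, :, 0] - np.log(trunc)
    unsort = np.empty_like(order)
    unsort[order] = np.arange(n)
    return out[:, unsort]


def forward_logliks_fast(counts: np.ndarray, mark: np.ndarray, chick: np.ndarray,
                         alpha1: np.ndarray, alpha2: np.ndarray,
                         gamma1: np.ndarray, gamma2: np.ndarray,
                         epsilon: np.ndarray, theta: np.ndarray,
                         n_quadrature: int = DEFAULT_QUADRATURE_NODES) -> np.ndarray:
    """Compiled-loop variant of :func:`forward_logliks` (same contract).

    Used by the fitting engine; equivalence with the numpy route is asserted
    in the test suite.
    """
    from ._kernels import cmr_forward_kernel

    counts = np.ascontiguousarray(counts, dtype=np.int64)
    n, T = counts.shape
    P = alpha1.shape[0]
    Q = int(n_quadrature)
    mark = np.ascontiguousarray(mark, dtype=np.int64)
    chick = np.ascontiguousarray(chick, dtype=np.bool_)

    xs = np.empty((P, Q))
    logw = np.empty((P, Q))
    for p in range(P):
        xs[p], logw[p] = _gamma_jacobi_log(float(theta[p]), Q)

    age = _age_class_matrix(mark, chick, T)
    group = np.ascontiguousarray((age >= 4).astype(np.int64))
    eps_nt = epsilon[:, group, np.arange(T)[None, :]]
    post_mark = np.arange(T)[None, :] >= mark[:, None]
    tilt = 0.5 * np.einsum("pnt,nt->pn", eps_nt, post_mark.astype(float))
    rate = theta[:, None] + tilt
    nodes = np.ascontiguousarray(xs[:, None, :] / rate[:, :, None])
    logW = np.ascontiguousarray(
        logw[:, None, :] + tilt[:, :, None] * nodes
        + theta[:, None, None] * (np.log(theta[:, None, None]) - np.log(rate[:, :, None])))
    shift = np.ascontiguousarray(logW.max(axis=2))
    lgc = np.ascontiguousarray(gammaln(counts + 1.0))

    ll = cmr_forward_kernel(counts, mark, chick,
                            np.ascontiguousarray(alpha1), np.ascontiguousarray(alpha2),
                            np.ascontiguousarray(gamma1), np.ascontiguousarray(gamma2),
                            np.ascontiguousarray(epsilon), group, nodes, logW, shift, lgc)
    eps_mark = eps_nt[:, np.arange(n), mark]
    trunc = 1.0 - np.exp(theta[:, None] * (np.log(theta[:, None])
                                           - np.log(theta[:, None] + eps_mark)))
    trunc = np.where(eps_mark > 0.0, trunc, 1.0)
    return ll - np.log(trunc)


def _params_to_arrays(rates: VitalRates, det: DetectionParams, T: int):
    a1 = rates.alpha1[None, :]
    a2 = rates.alpha2[None, :]
    eps = det.epsilon
    if eps.shape[1] == 1 and T > 1:
        eps = np.repeat(eps, T, axis=1)
    if eps.shape[1] != T:
        raise ValueError(f"epsilon covers {eps.shape[1]} years, data cover {T}")
    return (a1, a2, det.gamma1[None, :], det.gamma2[None, :], eps[None, :, :],
            np.array([det.theta]))


def individual_loglik(counts: np.ndarray, mark_idx: int, age_at_mark: int,
                      rates: VitalRates, det: DetectionParams,
                      n_quadrature: int = DEFAULT_QUADRATURE_NODES) -> float:
    """Log-probability of one encounter history given parameters.

    ``counts`` is the (T,) season count vector (zeros before marking),
    ``age_at_mark`` is 1 (chick) or 4 (adult).  Marginalizes latent states by
    the forward recursion and heterogeneity by ``n_quadrature`` gamma
    quadrature nodes; conditioned on the marking event.
    """
    counts = np.asarray(counts, dtype=np.int64)[None, :]
    T = counts.shape[1]
    arrays = _params_to_arrays(rates, det, T)
    ll = forward_logliks(counts, np.array([mark_idx]), np.array([age_at_mark == 1]),
                         *arrays, n_quadrature=n_quadrature)
    return float(ll[0, 0])


def dataset_loglik(enc: EncounterData, rates: VitalRates, det: DetectionParams,
                   n_quadrature: int = DEFAULT_QUADRATURE_NODES) -> float:
    """Sum of individual log-likelihoods (independence across individuals).

    Identical histories are collapsed and weighted, so the cost scales with
    the number of distinct histories, not individuals.
    """
    if enc.n_individuals == 0:
        warnings.warn("empty encounter dataset: log-likelihood is 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    uniq, mult = enc.collapse()
    arrays = _params_to_arrays(rates, det, enc.n_years)
    ll = forward_logliks(uniq.counts, uniq.mark_idx, uniq.is_chick, *arrays,
                         n_quadrature=n_quadrature)
    return float(ll[0] @ mult)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

_MAX_ENUM_SPAN = 8


def brute_force_loglik(counts: np.ndarray, mark_idx: int, age_at_mark: int,
                       rates: VitalRates, det: DetectionParams) -> float:
    """Exact log-probability by enumerating every latent (z, k) path.

    For each path the gamma heterogeneity integrates analytically: with
    available-occasion rates ``eps_j``, counts ``c_j`` and ``c+ = sum c_j``,

        prod_j eps_j^c_j / c_j!  *  theta^theta Gamma(c+ + theta)
                                    / (Gamma(theta) (theta + sum eps_j)^(c+ + theta))

    Occasions spent dead or unavailable force ``c_j = 0``.  The result is
    divided by the marking-event probability ``1 - (theta/(theta+eps_m))^theta``
    (matching :func:`individual_loglik`).  Exponential in the post-marking
    span, guarded at ``T - mark <= 8``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    T = counts.size
    m = int(mark_idx)
    span = T - 1 - m
    if span > _MAX_ENUM_SPAN:
        raise ValueError(f"enumeration over {3 ** span} paths refused (span {span} > "
                         f"{_MAX_ENUM_SPAN})")
    chick = age_at_mark == 1
    theta = det.theta
    eps = det.epsilon
    if eps.shape[1] == 1 and T > 1:
        eps = np.repeat(eps, T, axis=1)
    age = np.where(chick, np.clip(np.arange(T) - m, 0, 4), 4)
    group = (age >= 4).astype(int)
    eps_t = eps[group, np.arange(T)]

    # transition matrices for steps m -> m+1 ... T-2 -> T-1
    mats = []
    for t in range(m, T - 1):
        phi = rates.alpha1[t] if (chick and t == m) else rates.alpha2[t]
        a = int(np.clip(age[t], 1, 4))
        mats.append(LatentStateSpace.transition_matrix(
            phi, det.gamma1[a - 1], det.gamma2[a - 1],
            force_unavailable=bool(chick and t == m)))

    log_terms = []
    lg_theta = theta * np.log(theta) - gammaln(theta)
    for path in itertools.product((DEAD, ALIVE_UNAVAILABLE, ALIVE_AVAILABLE),
                                  repeat=span):
        states = (ALIVE_AVAILABLE,) + path
        logp = 0.0
        ok = True
        for step, (s_from, s_to) in enumerate(zip(states[:-1], states[1:])):
            pr = mats[step][s_from, s_to]
            if pr <= 0.0:
                ok = False
                break
            logp += np.log(pr)
        if not ok:
            continue
        avail = [m + j for j, s in enumerate(states) if s == ALIVE_AVAILABLE]
        hidden = [m + j for j, s in enumerate(states) if s != ALIVE_AVAILABLE]
        if any(counts[t] != 0 for t in hidden):
            continue
        c = counts[avail]
        e = eps_t[avail]
        if np.any((c > 0) & (e == 0.0)):
            continue
        c_plus = int(c.sum())
        with np.errstate(divide="ignore"):
            log_emit = np.where((c == 0) & (e == 0.0), 0.0,
                                c * np.log(np.where(e > 0, e, 1.0))) - gammaln(c + 1.0)
        log_int = (lg_theta + gammaln(c_plus + theta)
                   - (c_plus + theta) * np.log(theta + e.sum()))
        log_terms.append(logp + log_emit.sum() + log_int)

    if not log_terms:
        return -np.inf
    total = logsumexp(np.array(log_terms))
    eps_m = eps_t[m]
    if eps_m > 0.0:
        total -= np.log1p(-np.exp(theta * (np.log(theta) - np.log(theta + eps_m))))
    return float(total)
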