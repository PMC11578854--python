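"""Transient life table response experiment (tLTRE).

Decomposes temporal variance in the *realized* growth rate of the whole
population into contributions from the temporal variances and covariances of
the demographic rates and the stage structure, using the standard first-order
approach: with theta_t the vector of year-specific rates (alpha1, alpha2, f,
omega) and stage proportions (n1..n4, nimm), and lambda(theta) the one-step
growth function,

    Var(lambda_t)  ~=  sum_ij  cov_t(theta_i, theta_j) s_i s_j,

where s = dlambda/dtheta at the temporal mean.  The growth function here is
the expected one-step growth of the all-class total implied by the state
process:

    lambda(theta) = (f/2) alpha1 (n4 + nimm)
                    + alpha2 (n1 + n2 + n3 + n4 + nimm)
                    + omega (n1 + n2 + n3 + n4).

This all-class growth is what the decomposition needs (recruitment and
first-year survival act contemporaneously on it); the breeding-population
ratio ``Ntot_{t+1}/Ntot_t`` reported elsewhere is a different, lagged
quantity and is labelled distinctly.  lambda is multilinear in its
arguments, so the analytic gradient is exact and the finite-difference
check in the tests is purely a guard on the implementation.

Annual-change contributions use the same sensitivities evaluated at the
midpoint of consecutive years: contribution_{t,i} = (theta_{i,t+1} -
theta_{i,t}) s_i(midpoint), whose row sums track lambda_{t+1} - lambda_t.

Process correlations between the year series of two rates are computed
within each posterior draw and summarized across draws, which separates
process covariation from sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LtreInput", "LtreResult", "PARAM_NAMES", "growth_function",
           "sensitivities", "variance_contributions", "annual_contributions",
           "process_correlations", "ltre_input_from_draws"]

PARAM_NAMES = ("alpha1", "alpha2", "f", "omega", "n1", "n2", "n3", "n4", "nimm")


@dataclass(frozen=True)
class LtreInput:
    """Aligned year series of rates and stage proportions.

    ``alpha1``, ``alpha2``, ``f``, ``omega`` have length ``T - 1`` (the rates
    acting on each interval; a constant ``omega`` is broadcast), and the
    stage proportions are those at the *start* of each interval, each class
    divided by the all-class total.  Proportions must sum to one each year.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    f: np.ndarray
    omega: np.ndarray
    proportions: np.ndarray            # (T-1, 5) in stage order

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        if props.ndim != 2 or props.shape[1] != 5:
            raise ValueError("proportions must be (T-1, 5)")
        n = props.shape[0]
        for name in ("alpha1", "alpha2", "f", "omega"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size == 1:
                arr = np.full(n, float(arr[0]))
            if arr.size != n:
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("stage proportions must sum to 1 each year")
        object.__setattr__(self, "proportions", props)

    @property
    def n_intervals(self) -> int:
        return self.alpha1.size

    def matrix(self) -> np.ndarray:
        """(T-1, 9) parameter matrix in ``PARAM_NAMES`` order."""
        return np.column_stack([self.alpha1, self.alpha2, self.f, self.omega,
                                self.proportions])


@dataclass(frozen=True)
class LtreResult:
    """Variance decomposition output.

    ``contributions`` is the 9x9 matrix ``C_ij = cov(theta_i, theta_j) s_i
    s_j``; summing a row gives that parameter's total contribution, split
    into its own-variance part (``C_ii``) and its summed covariance part.
    ``percent`` expresses row totals relative to the grand total (summing to
    100 up to rounding).  ``annual`` is the (T-2, 9) matrix of annual-change
    contributions.
    """

    contributions: np.ndarray
    sensitivities: np.ndarray
    annual: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES

    @property
    def totals(self) -> np.ndarray:
        return self.contributions.sum(axis=1)

    @property
    def own_variance(self) -> np.ndarray:
        return np.diag(self.contributions)

    @property
    def covariance_part(self) -> np.ndarray:
        return self.totals - self.own_variance

    @property
    def total_variance(self) -> float:
        return float(self.contributions.sum())

    @property
    def percent(self) -> np.ndarray:
        tot = self.total_variance
        if tot == 0.0:
            return np.zeros(len(self.param_names))
        return 100.0 * self.totals / tot

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: parameter, variance part, covariance part, percent."""
        return pd.DataFrame({
            "parameter": self.param_names,
            "contribution": self.totals,
            "variance_part": self.own_variance,
            "covariance_part": self.covariance_part,
            "percent": self.percent,
        })


def growth_function(theta: np.ndarray) -> float | np.ndarray:
    """One-step growth of the all-class total for parameter vector(s)
    ``theta`` in ``PARAM_NAMES`` order (last axis).

    Raises if the five stage proportions do not sum to one.
    """
    theta = np.asarray(theta, dtype=float)
    props = theta[..., 4:9]
    if not np.allclose(props.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("stage proportions must sum to 1")
    a1, a2, f, om = (theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3])
    n1, n2, n3, n4, ni = (props[..., 0], props[..., 1], props[..., 2],
                          props[..., 3], props[..., 4])
    lam = (f / 2.0 * a1 * (n4 + ni)
           + a2 * (n1 + n2 + n3 + n4 + ni)
           + om * (n1 + n2 + n3 + n4))
    return float(lam) if lam.ndim == 0 else lam


def sensitivities(theta_mean: np.ndarray, numeric: bool = False,
                  step: float = 1e-6) -> np.ndarray:
    """Gradient of :func:`growth_function` at ``theta_mean``.

    The growth function is multilinear, so the analytic partials (default)
    are exact; ``numeric=True`` returns central finite differences instead
    (the proportion constraint is relaxed for the perturbed evaluations, as
    the coordinates are treated as free in the decomposition).
    """
    th = np.asarray(theta_mean, dtype=float)
    a1, a2, f, om, n1, n2, n3, n4, ni = th
    if not numeric:
        return np.array([
            f / 2.0 * (n4 + ni),               # d/d alpha1
            n1 + n2 + n3 + n4 + ni,            # d/d alpha2
            a1 / 2.0 * (n4 + ni),              # d/d f
            n1 + n2 + n3 + n4,                 # d/d omega
            a2 + om,                           # d/d n1
            a2 + om,                           # d/d n2
            a2 + om,                           # d/d n3
            f / 2.0 * a1 + a2 + om,            # d/d n4
            f / 2.0 * a1 + a2,                 # d/d nimm
        ])

    def lam_free(v):
        a1_, a2_, f_, om_, m1, m2, m3, m4, mi = v
        return (f_ / 2.0 * a1_ * (m4 + mi) + a2_ * (m1 + m2 + m3 + m4 + mi)
                + om_ * (m1 + m2 + m3 + m4))

    out = np.empty(9)
    for i in range(9):
        hi = th.copy()
        lo = th.copy()
        hi[i] += step
        lo[i] -= step
        out[i] = (lam_free(hi) - lam_free(lo)) / (2.0 * step)
    return out


def variance_contributions(inp: LtreInput) -> LtreResult:
    """First-order decomposition of Var(lambda_t) over the year series."""
    if inp.n_intervals < 3:
        raise ValueError("need at least 3 intervals to estimate temporal (co)variances")
    M = inp.matrix()
    s = sensitivities(M.mean(axis=0))
    cov = np.cov(M.T, ddof=1)
    C = cov * np.outer(s, s)
    return LtreResult(contributions=C, sensitivities=s,
                      annual=annual_contributions(inp))


def annual_contributions(inp: LtreInput) -> np.ndarray:
    """(T-2, 9) contributions of annual parameter changes to annual changes
    in growth: ``(theta_{i,t+1} - theta_{i,t}) * s_i`` at the midpoint."""
    M = inp.matrix()
    if M.shape[0] < 2:
        raise ValueError("need at least 2 intervals for annual changes")
    diffs = np.diff(M, axis=0)
    mids = 0.5 * (M[1:] + M[:-1])
    out = np.empty_like(diffs)
    for t in range(diffs.shape[0]):
        out[t] = diffs[t] * sensitivities(mids[t])
    return out


def process_correlations(series: dict[str, np.ndarray],
                         pairs: tuple[tuple[str, str], ...] = (
                             ("alpha2", "f"), ("alpha2", "alpha1"),
                             ("alpha1", "f")),
                         prob: float = 0.95) -> pd.DataFrame:
    """Pairwise Pearson correlations of annual rate series within each
    posterior draw, summarized across draws (mean and equal-tailed interval).

    ``series`` maps a rate name to a (n_draws, T) array; series of unequal
    length are truncated to the shortest common span.
    """
    lo_q = (1.0 - prob) / 2.0
    rows = []
    for a, b in pairs:
        A = np.atleast_2d(series[a])
        B = np.atleast_2d(series[b])
        T = min(A.shape[1], B.shape[1])
        A, B = A[:, :T], B[:, :T]
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        denom = np.sqrt((Ac ** 2).sum(axis=1) * (Bc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Ac * Bc).sum(axis=1) / denom
        r = r[np.isfinite(r)]
        rows.append({"pair": f"{a}~{b}", "mean": float(np.mean(r)),
                     "lo": float(np.quantile(r, lo_q)),
                     "hi": float(np.quantile(r, 1.0 - lo_q))})
    return pd.DataFrame(rows)


def ltre_input_from_draws(draws, mode: str = "posterior_mean") -> LtreInput | list[LtreInput]:
    """Build tLTRE inputs from a fitted model.

    ``mode="posterior_mean"`` (default) uses the posterior-mean year series
    of the rates and the posterior-mean stage proportions; ``mode="draws"``
    returns one :class:`LtreInput` per retained state draw so contributions
    can be summarized with credible intervals.
    """
    if draws.state_draws is None:
        raise ValueError("fit has no latent-state draws (no survey stream?)")
    states = draws.state_draws                      # (n, T, 5)
    totals = states.sum(axis=2, keepdims=True)
    props = states / np.clip(totals, 1e-12, None)
    a1 = draws.stacked("alpha1")
    a2 = draws.stacked("alpha2")
    f = draws.stacked("f")
    om = draws.stacked("omega")
    idx = draws.diagnostics.get("state_draw_indices")
    if idx is None:
        idx = np.linspace(0, a1.shape[0] - 1, states.shape[0]).astype(int)
    Tm1 = a1.shape[1]
    if mode == "posterior_mean":
        return LtreInput(alpha1=a1.mean(axis=0), alpha2=a2.mean(axis=0),
                         f=f.mean(axis=0)[:Tm1], omega=float(om.mean()),
                         proportions=props.mean(axis=0)[:Tm1])
    if mode == "draws":
        out = []
        for k, i in enumerate(idx):
            out.append(LtreInput(alpha1=a1[i], alpha2=a2[i], f=f[i][:Tm1],
                                 omega=float(om[i]), proportions=props[k][:Tm1]))
        return out
    raise ValueError("mode must be 'posterior_mean' or 'draws'")
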