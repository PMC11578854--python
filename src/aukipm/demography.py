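"""Shared domain types and deterministic demographic algebra.

The model is a female-based, pre-breeding-census matrix population model with
five classes in fixed order ``(N1, N2, N3, N4, Nimm)``: first-, second-,
third-year birds, breeders aged 4+, and breeding-age immigrants.  Only the 4+
class and immigrants breed.  Recruitment combines productivity ``f`` (chicks
fledged per pair; halved for a female-based model) with first-year apparent
survival ``alpha1``; all later transitions use adult apparent survival
``alpha2``; immigrants arrive at a constant per-capita rate ``omega`` applied
to the four resident classes.

This module holds the deterministic algebra only (expected-value projection
matrix, stable stage structure, realized growth, the encounter-rate /
detection-probability transform).  Stochastic propagation lives in
:mod:`aukipm.simulate`, likelihoods in :mod:`aukipm.cmr` and
:mod:`aukipm.model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed stage order used by every array in the package.
STAGE_ORDER = ("N1", "N2", "N3", "N4", "Nimm")

#: Age classes; "4" means 4 years and older (the only breeding class).
AGE_CLASSES = (1, 2, 3, 4)

#: Relative gap required between the two largest eigenvalue moduli before the
#: leading eigenpair is considered well defined.
_EIGEN_GAP = 1e-8


class DominantEigenvalueError(RuntimeError):
    """Raised when a projection matrix has no strictly dominant eigenvalue."""


@dataclass(frozen=True)
class StudyDesign:
    """Temporal frame of a study: calendar years and survey schedule.

    Parameters
    ----------
    years:
        Ordered calendar years, length ``T >= 3``.  The reference study frame
        spans 22 seasons.
    survey_years:
        Years in which breeding-pair counts exist (a sparse subset; the
        reference study has six surveys in 22 years).
    species_label:
        Free-text label carried through outputs.
    """

    years: tuple[int, ...]
    survey_years: tuple[int, ...]
    species_label: str = "synthetic"

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "survey_years", tuple(int(y) for y in self.survey_years))
        if len(years) < 3:
            raise ValueError("a study needs at least 3 years")
        if list(years) != sorted(set(years)):
            raise ValueError("years must be strictly increasing")
        if not set(self.survey_years) <= set(years):
            raise ValueError("survey_years must be a subset of years")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        """Map a calendar year to its 0-based index in ``years``."""
        try:
            return self.years.index(int(year))
        except ValueError as exc:
            raise KeyError(f"year {year} is not part of the study frame") from exc

    @property
    def survey_indices(self) -> np.ndarray:
        return np.array([self.year_index(y) for y in self.survey_years], dtype=int)


def _as_prob_array(x, name: str, length: int | None = None) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if length is not None and arr.size == 1:
        arr = np.full(length, float(arr[0]))
    if length is not None and arr.size != length:
        raise ValueError(f"{name} must have length {length}, got {arr.size}")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return arr


@dataclass(frozen=True)
class VitalRates:
    """Year-indexed demographic rates plus the constant immigration rate.

    ``alpha1`` and ``alpha2`` are apparent survival probabilities over the
    ``T - 1`` year-to-year transitions; ``f`` is productivity (chicks fledged
    per monitored pair) in each of the ``T`` years; ``omega`` is the constant
    immigration-plus-noise rate.  The female-based recruitment probability is
    ``f/2 * alpha1`` and must be a valid binomial success probability.
    Scalars broadcast to the full length.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    f: np.ndarray
    omega: float
    n_years: int | None = None

    def __post_init__(self) -> None:
        n = self.n_years
        if n is None:
            n = max(np.atleast_1d(np.asarray(self.f)).size,
                    np.atleast_1d(np.asarray(self.alpha1)).size + 1)
        object.__setattr__(self, "n_years", int(n))
        object.__setattr__(self, "alpha1", _as_prob_array(self.alpha1, "alpha1", n - 1))
        object.__setattr__(self, "alpha2", _as_prob_array(self.alpha2, "alpha2", n - 1))
        object.__setattr__(self, "f", _as_prob_array(self.f, "f", n))
        omega = float(self.omega)
        if not np.isfinite(omega) or omega < 0.0:
            raise ValueError("omega must be a finite nonnegative rate")
        object.__setattr__(self, "omega", omega)
        if np.any(self.f[:-1] / 2.0 * self.alpha1 > 1.0):
            raise ValueError("f/2 * alpha1 exceeds 1: not a binomial probability")


@dataclass(frozen=True)
class PopulationState:
    """Latent integer abundances per year, stage order ``STAGE_ORDER``.

    ``Ntot`` is the breeding population, identically ``N4 + Nimm``.
    """

    N1: np.ndarray
    N2: np.ndarray
    N3: np.ndarray
    N4: np.ndarray
    Nimm: np.ndarray
    extinct: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name in STAGE_ORDER:
            arr = np.asarray(getattr(self, name))
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
            object.__setattr__(self, name, arr.astype(np.int64))
        lengths = {getattr(self, name).size for name in STAGE_ORDER}
        if len(lengths) != 1:
            raise ValueError("all stage series must share one length")

    @property
    def Ntot(self) -> np.ndarray:
        return self.N4 + self.Nimm

    @property
    def n_years(self) -> int:
        return self.N1.size

    def as_matrix(self) -> np.ndarray:
        """(T, 5) array in stage order."""
        return np.stack([getattr(self, name) for name in STAGE_ORDER], axis=1)

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "PopulationState":
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[1] != 5:
            raise ValueError("expected a (T, 5) stage matrix")
        return cls(*(mat[:, j] for j in range(5)))


@dataclass(frozen=True)
class DetectionParams:
    """Availability, encounter-rate and heterogeneity parameters.

    gamma1[a], gamma2[a] : probability of being available for detection at a
        season given absence (gamma1) or presence (gamma2) the season before,
        for age class ``a`` in 1..4+ (index 0..3).  Age-structured to capture
        the gradual return of pre-breeders to the colony.
    epsilon : (2, T) mean expected encounters per season for the two encounter
        groups, row 0 = pre-breeders (ages 1-3), row 1 = breeders (4+).
        A (2,) vector broadcasts over years.
    theta : gamma overdispersion of the individual detection multiplier
        ``h_i ~ Gamma(theta, theta)`` (mean 1; smaller theta = more spread).
    """

    gamma1: np.ndarray
    gamma2: np.ndarray
    epsilon: np.ndarray
    theta: float
    n_years: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma1", _as_prob_array(self.gamma1, "gamma1", 4))
        object.__setattr__(self, "gamma2", _as_prob_array(self.gamma2, "gamma2", 4))
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.ndim == 1:
            if eps.size != 2:
                raise ValueError("epsilon must be (2,) or (2, T)")
            n = self.n_years or 1
            eps = np.repeat(eps[:, None], n, axis=1)
        if eps.ndim != 2 or eps.shape[0] != 2:
            raise ValueError("epsilon must be (2,) or (2, T)")
        if np.any(~np.isfinite(eps)) or np.any(eps < 0.0):
            raise ValueError("epsilon must be finite and nonnegative")
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "n_years", eps.shape[1])
        theta = float(self.theta)
        if not (np.isfinite(theta) and theta > 0.0):
            raise ValueError("theta must be a positive real")
        object.__setattr__(self, "theta", theta)


# ---------------------------------------------------------------------------
# deterministic algebra
# ---------------------------------------------------------------------------

def build_projection_matrix(alpha1: float, alpha2: float, f: float,
                            omega: float) -> np.ndarray:
    """Expected-value projection matrix for one transition, stage order
    ``(N1, N2, N3, N4, Nimm)``.

    Row N1 carries recruitment ``f/2 * alpha1`` from the two breeding classes;
    rows N2 and N3 carry ``alpha2`` from the preceding class; row N4 carries
    ``alpha2`` from N3, N4 and Nimm (immigrants already present graduate into
    the resident breeding class); row Nimm carries ``omega`` from the four
    resident classes only, so its Nimm column is zero.
    """
    alpha1 = float(alpha1)
    alpha2 = float(alpha2)
    f = float(f)
    omega = float(omega)
    for name, val in (("alpha1", alpha1), ("alpha2", alpha2), ("f", f), ("omega", omega)):
        if not np.isfinite(val) or val < 0.0:
            raise ValueError(f"{name} must be finite and nonnegative")
    recruit = f / 2.0 * alpha1
    if recruit > 1.0:
        raise ValueError("f/2 * alpha1 exceeds 1: not a binomial probability")
    A = np.zeros((5, 5))
    A[0, 3] = A[0, 4] = recruit
    A[1, 0] = alpha2
    A[2, 1] = alpha2
    A[3, 2] = A[3, 3] = A[3, 4] = alpha2
    A[4, 0] = A[4, 1] = A[4, 2] = A[4, 3] = omega
    return A


def stable_stage_distribution(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized leading right eigenvector and asymptotic growth rate.

    Raises :class:`DominantEigenvalueError` when the two largest eigenvalue
    moduli are closer than a relative gap of 1e-8 (no strictly dominant
    eigenvalue, e.g. purely cyclic dynamics).
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (5, 5) or np.any(A < 0):
        raise ValueError("expected a nonnegative 5x5 projection matrix")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    lam = vals[order[0]]
    if np.abs(lam) == 0.0:
        raise DominantEigenvalueError("matrix is nilpotent: no positive growth rate")
    gap = (np.abs(lam) - np.abs(vals[order[1]])) / np.abs(lam)
    if gap < _EIGEN_GAP:
        raise DominantEigenvalueError(
            f"leading eigenvalues tied within relative gap {gap:.2e} < {_EIGEN_GAP:.0e}")
    v = np.real(vecs[:, order[0]])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    return v, float(np.real(lam))


def realized_growth(ntot: Sequence[float]) -> np.ndarray:
    """Per-interval realized growth ``lambda_t = Ntot[t+1] / Ntot[t]``.

    Intervals with a zero denominator are returned as NaN and flagged with a
    warning rather than dropped, so the output always has length ``T - 1``.
    """
    ntot = np.asarray(ntot, dtype=float)
    if ntot.ndim != 1 or ntot.size < 2:
        raise ValueError("need a series of at least two totals")
    denom = ntot[:-1]
    out = np.full(ntot.size - 1, np.nan)
    ok = denom > 0
    out[ok] = ntot[1:][ok] / denom[ok]
    if np.any(~ok):
        warnings.warn("zero population in denominator: growth undefined (NaN) "
                      f"for interval(s) {np.nonzero(~ok)[0].tolist()}",
                      RuntimeWarning, stacklevel=2)
    return out


def detection_probability(epsilon) -> np.ndarray | float:
    """Season detection probability ``p = 1 - exp(-epsilon)``.

    ``epsilon`` is the expected number of encounters per season; ``p`` is the
    chance of at least one.  Monotone increasing, exactly invertible via
    :func:`encounter_rate`.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 0.0) or np.any(~np.isfinite(eps)):
        raise ValueError("epsilon must be finite and nonnegative")
    p = -np.expm1(-eps)
    return float(p) if np.isscalar(epsilon) or p.ndim == 0 else p


def encounter_rate(p) -> np.ndarray | float:
    """Inverse of :func:`detection_probability`: ``epsilon = -log(1 - p)``."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0.0) or np.any(p_arr >= 1.0):
        raise ValueError("p must lie in [0, 1)")
    eps = -np.log1p(-p_arr)
    return float(eps) if np.isscalar(p) or eps.ndim == 0 else eps
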