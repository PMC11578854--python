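"""Individual-based generator of the three data streams from known truth.

The generator draws an age-structured population through the exact stochastic
state process (binomial survival/recruitment, Poisson immigration), observes
it with Poisson survey error in survey years, fledges chicks binomially from
monitored burrows, and simulates every marked individual's encounter-count
history through the latent alive/available process with gamma detection
heterogeneity — i.e. precisely the statistical structure the integrated model
assumes, so that inference, the transient LTRE, and the trend tests can be
validated by parameter recovery without restricted field data.

Marked individuals are a detection-biased sample: an individual enters the
data only if encountered at least once in its marking season, so the
generator redraws the pair ``(h_i, c_mark)`` jointly until ``c_mark >= 1``.
This matches the likelihood's marking-event conditioning term exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .data import ADULT_AGE, CHICK_AGE, DataBundle, EncounterData, ProductivityData, SurveyCounts
from .demography import (DetectionParams, PopulationState, StudyDesign, VitalRates,
                         build_projection_matrix, stable_stage_distribution)

__all__ = [
    "ScenarioConfig", "simulate_population", "simulate_counts",
    "simulate_productivity", "simulate_encounters", "simulate_bundle",
    "generate_scenario", "reduced_scenario", "calibration_scenario",
    "paper_scale_scenario", "one_step_transition",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one synthetic study.

    ``rates`` holds the realized true year series (built from logit-scale
    means and year effects by the scenario constructors, or supplied
    directly); ``truth`` records the scalar generating values for recovery
    tests.  All marking cohorts and burrow counts are per-year constants.
    """

    design: StudyDesign
    rates: VitalRates
    detection: DetectionParams
    initial_total_pairs: int
    chicks_marked_per_year: int
    adults_marked_per_year: int
    burrows_per_year: int
    rng_seed: int
    initial_immigrant_lambda: float = 50.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("initial_total_pairs", "chicks_marked_per_year",
                     "adults_marked_per_year", "burrows_per_year"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rates.n_years != self.design.n_years:
            raise ValueError("rates and design disagree on the number of years")


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    return np.random.default_rng(config_or_seed)


def one_step_transition(n: np.ndarray, alpha1: float, alpha2: float, f: float,
                        omega: float, rng: np.random.Generator) -> np.ndarray:
    """One stochastic projection of a stage vector ``(N1..N4, Nimm)``."""
    n = np.asarray(n, dtype=np.int64)
    ntot = n[3] + n[4]
    out = np.empty(5, dtype=np.int64)
    out[0] = rng.binomial(ntot, f / 2.0 * alpha1)
    out[1] = rng.binomial(n[0], alpha2)
    out[2] = rng.binomial(n[1], alpha2)
    out[3] = rng.binomial(n[2] + ntot, alpha2)
    out[4] = rng.poisson(omega * n[:4].sum())
    return out


def _initial_state(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    A = build_projection_matrix(config.rates.alpha1[0], config.rates.alpha2[0],
                                config.rates.f[0], config.rates.omega)
    v, _ = stable_stage_distribution(A)
    n_imm = rng.poisson(config.initial_immigrant_lambda)
    n4 = max(config.initial_total_pairs - n_imm, 0)
    n = np.array([round(v[0] / v[3] * n4), round(v[1] / v[3] * n4),
                  round(v[2] / v[3] * n4), n4, n_imm], dtype=np.int64)
    return n


def simulate_population(config: ScenarioConfig,
                        rng: np.random.Generator | int | None = None) -> PopulationState:
    """Stochastic trajectory of the five abundance classes.

    Exact recursion of the state process under a pre-breeding census;
    extinction (``Ntot = 0``) is flagged on the returned state, not an error.
    """
    rng = _rng(config.rng_seed if rng is None else rng)
    T = config.design.n_years
    N = np.zeros((T, 5), dtype=np.int64)
    N[0] = _initial_state(config, rng)
    r = config.rates
    for t in range(T - 1):
        N[t + 1] = one_step_transition(N[t], r.alpha1[t], r.alpha2[t], r.f[t],
                                       r.omega, rng)
    state = PopulationState.from_matrix(N)
    if np.any(state.Ntot == 0):
        state = replace(state, extinct=True)
        warnings.warn("breeding population hit zero during the simulation",
                      RuntimeWarning, stacklevel=2)
    return state


def simulate_counts(states: PopulationState, design: StudyDesign,
                    rng: np.random.Generator | int) -> SurveyCounts:
    """Poisson survey observations of the breeding population, survey years only."""
    rng = _rng(rng)
    ntot = states.Ntot
    return SurveyCounts({int(t): int(rng.poisson(ntot[t])) for t in design.survey_indices})


def simulate_productivity(f_series: np.ndarray, burrows_per_year,
                          rng: np.random.Generator | int) -> ProductivityData:
    """Binomial fledging from monitored burrows: ``J_t ~ Bin(B_t, f_t)``."""
    rng = _rng(rng)
    f_series = np.asarray(f_series, dtype=float)
    B = np.broadcast_to(np.asarray(burrows_per_year, dtype=np.int64), f_series.shape)
    J = rng.binomial(B, f_series)
    return ProductivityData(burrows=B.copy(), fledged=J)


def _draw_marked(n: int, eps_mark: float, theta: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Joint (h, c_mark) for n marked individuals, conditioned on c_mark >= 1
    by redrawing both together (detection-biased h of marked birds)."""
    if eps_mark <= 0.0:
        # limiting case: the truncated count concentrates on 1
        return rng.gamma(theta, 1.0 / theta, size=n), np.ones(n, dtype=np.int64)
    h = np.empty(n)
    c = np.zeros(n, dtype=np.int64)
    todo = np.arange(n)
    while todo.size:
        h_try = rng.gamma(theta, 1.0 / theta, size=todo.size)
        c_try = rng.poisson(eps_mark * h_try)
        h[todo] = h_try
        c[todo] = c_try
        todo = todo[c_try == 0]
    return h, c


def simulate_encounters(config: ScenarioConfig, states: PopulationState,
                        rng: np.random.Generator | int) -> EncounterData:
    """Encounter-count histories for all marking cohorts.

    Chicks are marked in the burrow in their hatch year (available and
    counted at marking, off-colony the following season); adults are marked
    as 4+ breeders.  Cohort sizes are truncated with a warning if the
    simulated population cannot supply them.
    """
    rng = _rng(rng)
    T = config.design.n_years
    det = config.detection
    r = config.rates
    eps = det.epsilon
    if eps.shape[1] == 1:
        eps = np.repeat(eps, T, axis=1)
    all_counts, all_mark, all_age = [], [], []
    for m in range(T):
        chicks_avail = int(states.Ntot[m] * r.f[m])
        adults_avail = int(states.Ntot[m])
        n_chicks = min(config.chicks_marked_per_year, chicks_avail)
        n_adults = min(config.adults_marked_per_year, adults_avail)
        if n_chicks < config.chicks_marked_per_year or n_adults < config.adults_marked_per_year:
            warnings.warn(f"year index {m}: marking cohort truncated to the "
                          f"simulated population ({n_chicks} chicks, {n_adults} adults)",
                          RuntimeWarning, stacklevel=2)
        for n_cohort, is_chick in ((n_chicks, True), (n_adults, False)):
            if n_cohort == 0:
                continue
            grp_mark = 0 if is_chick else 1
            h, c_mark = _draw_marked(n_cohort, float(eps[grp_mark, m]),
                                     det.theta, rng)
            counts = np.zeros((n_cohort, T), dtype=np.int64)
            counts[:, m] = c_mark
            alive = np.ones(n_cohort, dtype=bool)
            avail = np.ones(n_cohort, dtype=bool)
            for t in range(m, T - 1):
                if is_chick and t == m:
                    phi = r.alpha1[t]
                    g_next = np.zeros(n_cohort)          # forced off-colony
                else:
                    phi = r.alpha2[t]
                    age = min(t - m, 4) if is_chick else 4
                    g_next = np.where(avail, det.gamma2[age - 1], det.gamma1[age - 1])
                alive &= rng.random(n_cohort) < phi
                avail = alive & (rng.random(n_cohort) < g_next)
                age_next = min(t + 1 - m, 4) if is_chick else 4
                grp = 0 if age_next <= 3 else 1
                lam = np.where(avail, eps[grp, t + 1] * h, 0.0)
                counts[:, t + 1] = rng.poisson(lam)
            all_counts.append(counts)
            all_mark.append(np.full(n_cohort, m))
            all_age.append(np.full(n_cohort, CHICK_AGE if is_chick else ADULT_AGE))
    return EncounterData(counts=np.concatenate(all_counts),
                         mark_idx=np.concatenate(all_mark),
                         age_at_mark=np.concatenate(all_age))


def simulate_bundle(config: ScenarioConfig) -> tuple[DataBundle, PopulationState]:
    """Generate all three streams from one seeded generator."""
    rng = _rng(config.rng_seed)
    states = simulate_population(config, rng)
    surveys = simulate_counts(states, config.design, rng)
    prod = simulate_productivity(config.rates.f, config.burrows_per_year, rng)
    enc = simulate_encounters(config, states, rng)
    bundle = DataBundle(design=config.design, surveys=surveys, encounters=enc,
                        productivity=prod)
    return bundle, states


def generate_scenario(config: ScenarioConfig, out_dir, overwrite: bool = False):
    """Write a self-describing scenario directory (three CSVs + truth file).

    Refuses to overwrite an existing scenario unless ``overwrite`` is set.
    Returns the in-memory bundle and true trajectory.
    """
    from . import io as aio  # deferred: io imports this module's types

    bundle, states = simulate_bundle(config)
    aio.write_scenario(out_dir, config, bundle, states, overwrite=overwrite)
    return bundle, states


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

def _build_rates(T: int, mean_alpha1: float, mean_alpha2: float, mean_f: float,
                 omega: float, sd_survival: float, sd_f: float,
                 rng: np.random.Generator) -> tuple[VitalRates, dict]:
    """Year series from logit-scale means and year effects; the survival
    effect SD defaults to the model's fixed unit SD so generator and fitted
    model share one structure."""
    a1 = expit(logit(mean_alpha1) + sd_survival * rng.standard_normal(T - 1))
    a2 = expit(logit(mean_alpha2) + sd_survival * rng.standard_normal(T - 1))
    f = expit(logit(mean_f) + sd_f * rng.standard_normal(T))
    truth = {"mean_alpha1": mean_alpha1, "mean_alpha2": mean_alpha2,
             "mean_f": mean_f, "omega": omega, "sigma_f": sd_f,
             "sd_survival": sd_survival}
    return VitalRates(alpha1=a1, alpha2=a2, f=f, omega=omega, n_years=T), truth


_DEFAULT_GAMMA1 = (0.05, 0.20, 0.40, 0.50)
_DEFAULT_GAMMA2 = (0.30, 0.50, 0.70, 0.90)
_DEFAULT_EPSILON = (1.0, 2.5)


def _preset(T: int, first_year: int, survey_step: int, pairs: int, chicks: int,
            adults: int, burrows: int, seed: int, label: str,
            mean_alpha1=0.30, mean_alpha2=0.85, mean_f=0.55, omega=0.08,
            theta=39.0, sd_f=0.5, imm_lambda=50.0,
            survey_indices=None) -> ScenarioConfig:
    rng = np.random.default_rng(seed)
    years = tuple(range(first_year, first_year + T))
    if survey_indices is None:
        survey_indices = range(0, T, survey_step)
    design = StudyDesign(years=years,
                         survey_years=tuple(years[i] for i in survey_indices),
                         species_label=label)
    rates, truth = _build_rates(T, mean_alpha1, mean_alpha2, mean_f, omega,
                                sd_survival=1.0, sd_f=sd_f, rng=rng)
    det = DetectionParams(gamma1=_DEFAULT_GAMMA1, gamma2=_DEFAULT_GAMMA2,
                          epsilon=np.repeat(np.array(_DEFAULT_EPSILON)[:, None], T, axis=1),
                          theta=theta)
    truth.update({"theta": theta, "gamma1": _DEFAULT_GAMMA1, "gamma2": _DEFAULT_GAMMA2,
                  "epsilon": _DEFAULT_EPSILON, "initial_total_pairs": pairs})
    return ScenarioConfig(design=design, rates=rates, detection=det,
                          initial_total_pairs=pairs, chicks_marked_per_year=chicks,
                          adults_marked_per_year=adults, burrows_per_year=burrows,
                          rng_seed=seed, initial_immigrant_lambda=imm_lambda,
                          truth=truth)


def reduced_scenario(seed: int = 0) -> ScenarioConfig:
    """Reduced-scale test scenario: 15 seasons, 100 chicks + 40 adults marked
    per year, 80 monitored burrows, surveys every 4th year, ~1200 initial
    pairs; truth at literature-scale values (first-year survival 0.30, adult
    survival 0.85, productivity 0.55, immigration 0.08, theta 39)."""
    return _preset(T=15, first_year=2000, survey_step=4, pairs=1200, chicks=100,
                   adults=40, burrows=80, seed=seed, label="reduced")


def calibration_scenario(seed: int = 0) -> ScenarioConfig:
    """Smaller scenario used for repeated-replicate calibration checks:
    10 seasons, 60 chicks + 25 adults per year, 60 burrows, surveys every 3rd
    year, ~1000 initial pairs.  Same truth as :func:`reduced_scenario`."""
    return _preset(T=10, first_year=2000, survey_step=3, pairs=1000, chicks=60,
                   adults=25, burrows=60, seed=seed, label="calibration")


def paper_scale_scenario(species: str = "ATPU", seed: int = 0) -> ScenarioConfig:
    """Full study-scale scenario: 22 seasons, six surveys, cohort sizes and
    initial populations at the scale of the two reference colonies (a large
    stable one and a small growing one)."""
    surveys = (0, 4, 8, 12, 17, 21)
    if species.upper() == "ATPU":
        return _preset(T=22, first_year=1998, survey_step=4, pairs=8000,
                       chicks=300, adults=134, burrows=90, seed=seed,
                       label="ATPU-like", mean_alpha1=0.30, mean_alpha2=0.85,
                       mean_f=0.55, omega=0.08, theta=39.0, sd_f=0.8,
                       survey_indices=surveys)
    if species.upper() == "RAZO":
        return _preset(T=22, first_year=1998, survey_step=4, pairs=400,
                       chicks=67, adults=36, burrows=90, seed=seed,
                       label="RAZO-like", mean_alpha1=0.33, mean_alpha2=0.85,
                       mean_f=0.53, omega=0.21, theta=16.2, sd_f=0.3,
                       survey_indices=surveys)
    raise ValueError("species must be 'ATPU' or 'RAZO'")
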