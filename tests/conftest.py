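"""Shared fixtures: small random model draws and session-scoped fits.

The two expensive fits (integrated and mark-recapture-only on the reduced
scenario) are session-scoped so recovery, model-comparison, LTRE and trend
tests all reuse them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from aukipm import DetectionParams, VitalRates
from aukipm.fit import FitConfig, fit_cmr_only, fit_ipm
from aukipm.model import ModelSpec
from aukipm.simulate import reduced_scenario, simulate_bundle


def random_rates(rng: np.random.Generator, T: int) -> VitalRates:
    return VitalRates(alpha1=rng.uniform(0.1, 0.6, T - 1),
                      alpha2=rng.uniform(0.6, 0.95, T - 1),
                      f=rng.uniform(0.3, 0.8, T),
                      omega=float(rng.uniform(0.0, 0.3)))


def random_detection(rng: np.random.Generator, T: int,
                     theta: float | None = None) -> DetectionParams:
    return DetectionParams(gamma1=rng.uniform(0.05, 0.6, 4),
                           gamma2=rng.uniform(0.3, 0.95, 4),
                           epsilon=rng.uniform(0.2, 3.0, (2, T)),
                           theta=float(theta if theta is not None
                                       else rng.uniform(2.0, 60.0)))


def random_history(rng: np.random.Generator, T: int):
    """A random encounter history: (counts, mark_idx, age_at_mark)."""
    m = int(rng.integers(0, T - 1))
    chick = bool(rng.integers(0, 2))
    c = np.zeros(T, dtype=np.int64)
    c[m] = int(rng.integers(1, 4))
    for t in range(m + 1, T):
        c[t] = int(rng.integers(0, 5)) if rng.random() < 0.5 else 0
    if chick and m + 1 < T:
        c[m + 1] = 0                    # nestlings are off-colony next season
    return c, m, (1 if chick else 4)


@pytest.fixture(scope="session")
def reduced_setup():
    cfg = reduced_scenario(1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, states = simulate_bundle(cfg)
    spec = ModelSpec(design=cfg.design,
                     initial_total_pairs=cfg.initial_total_pairs,
                     initial_immigrant_lambda=cfg.initial_immigrant_lambda)
    return cfg, bundle, states, spec


@pytest.fixture(scope="session")
def reduced_fit(reduced_setup):
    cfg, bundle, states, spec = reduced_setup
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_ipm(bundle, spec, FitConfig(seed=2))


@pytest.fixture(scope="session")
def cmr_only_fit(reduced_setup):
    cfg, bundle, states, spec = reduced_setup
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_cmr_only(bundle.encounters, spec, FitConfig(seed=3))
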