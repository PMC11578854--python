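"""The core likelihood: marginal probability of one encounter-count history
under the zero-inflated gamma-Poisson model, computed two ways — the fast
forward recursion with gamma quadrature, and exhaustive enumeration of every
latent alive/available path with the gamma integral done analytically."""

import numpy as np

from aukipm import (DetectionParams, VitalRates, brute_force_loglik,
                    individual_loglik)

T = 5
rates = VitalRates(alpha1=[0.30] * (T - 1), alpha2=[0.85] * (T - 1),
                   f=[0.55] * T, omega=0.08)
det = DetectionParams(gamma1=[0.05, 0.20, 0.40, 0.50],
                      gamma2=[0.30, 0.50, 0.70, 0.90],
                      epsilon=np.repeat([[1.0], [2.5]], T, axis=1),
                      theta=39.0)

# an adult marked in season 0: seen twice at marking, missed for two years,
# then seen three times — temporary emigration or just bad luck?
history = np.array([2, 0, 0, 3, 1])
ll_quad = individual_loglik(history, mark_idx=0, age_at_mark=4,
                            rates=rates, det=det)
ll_enum = brute_force_loglik(history, 0, 4, rates, det)
print(f"history {history.tolist()} (adult, marked season 0)")
print(f"  quadrature forward recursion: log L = {ll_quad:.10f}")
print(f"  exhaustive path enumeration:  log L = {ll_enum:.10f}")
print(f"  |difference| = {abs(ll_quad - ll_enum):.2e}")

chick = np.array([1, 0, 0, 0, 2])
ll_chick = individual_loglik(chick, 0, 1, rates, det)
print(f"\nchick history {chick.tolist()}: log L = {ll_chick:.6f}")
print("\nThe two routes agree to near machine precision; the chick's")
print("probability folds together surviving its first year, the gradual")
print("age-dependent return to the colony, and its personal detectability.")
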