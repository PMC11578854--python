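"""Fit the integrated model to synthetic data and compare the posterior with
the generating truth — the package's central correctness argument.  Uses the
small calibration scenario so the whole script runs in well under a minute."""

import warnings

from aukipm.fit import FitConfig, fit_ipm, summarize
from aukipm.model import ModelSpec
from aukipm.simulate import calibration_scenario, simulate_bundle

cfg = calibration_scenario(seed=3)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle, states = simulate_bundle(cfg)
    spec = ModelSpec(design=cfg.design,
                     initial_total_pairs=cfg.initial_total_pairs)
    draws = fit_ipm(bundle, spec, FitConfig(seed=1, draws=600, burn=250))

print(f"sampler: {draws.sampler}; acceptance {draws.acceptance:.2f}; "
      f"converged: {draws.converged}")
print(f"{'parameter':>18} {'truth':>7} {'post mean':>10} {'95% interval':>18}")
for name in ("mean_alpha1", "mean_alpha2", "mean_f", "omega", "theta", "sigma_f"):
    lo, hi = draws.credible_interval(name)
    mean = draws.stacked(name).mean()
    print(f"{name:>18} {cfg.truth[name]:>7.3g} {mean:>10.3f} "
          f"[{lo:>7.3f}, {hi:>7.3f}]")
print("\nEach generating value should sit inside its interval in the great")
print("majority of runs; `summarize(draws)` gives the full annual table.")
print(summarize(draws).head(8).to_string(index=False))
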