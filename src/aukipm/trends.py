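"""Post hoc linear trend tests on annual demographic-rate estimates.

Ordinary least squares of the annual posterior-mean estimate on calendar
year, with a two-sided t-test on the slope.  Regressions run on posterior
means — not on draws — matching the usual post hoc practice; a
draw-propagated variant is available but off by default.  A mask drops
years whose estimates are structurally biased (e.g. the last few first-year
survival estimates, which are floored by cohorts that have not yet returned
to the colony).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TrendResult", "fit_trend", "trend_table"]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of an annual rate: slope is per calendar year."""

    label: str
    slope: float
    intercept: float
    p_value: float
    stderr: float
    years_used: tuple[int, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def fit_trend(annual_means, years, mask=None, label: str = "rate") -> TrendResult:
    """Least-squares trend of ``annual_means`` against ``years``.

    ``mask`` lists year *values* to exclude.  Year is centered before
    fitting for conditioning; the slope is reported per calendar year and
    the intercept at the mean retained year.  A constant series has slope 0
    and its p-value is reported as 1 (the t-statistic is 0/0; no evidence of
    trend).  Requires at least 3 retained years with at least two distinct
    year values.
    """
    y = np.asarray(annual_means, dtype=float)
    yr = np.asarray(years, dtype=float)
    if y.shape != yr.shape or y.ndim != 1:
        raise ValueError("annual_means and years must be 1-D and aligned")
    keep = np.isfinite(y)
    if mask is not None:
        keep &= ~np.isin(yr, np.asarray(list(mask), dtype=float))
    y, yr = y[keep], yr[keep]
    if y.size < 3:
        raise ValueError("need at least 3 unmasked annual estimates")
    if np.unique(yr).size < 2:
        raise ValueError("degenerate regressor: all retained years identical")
    if np.allclose(y, y.mean(), rtol=0.0, atol=1e-12 * max(1.0, np.abs(y).max())):
        # constant series: no trend, and the t statistic is 0/0 noise
        return TrendResult(label=label, slope=0.0, intercept=float(y.mean()),
                           p_value=1.0, stderr=0.0,
                           years_used=tuple(int(v) for v in yr))
    xc = yr - yr.mean()
    res = sm.OLS(y, sm.add_constant(xc)).fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    if not np.isfinite(p):           # zero-residual degenerate fits
        p = 0.0 if abs(slope) > 0 else 1.0
    return TrendResult(label=label, slope=slope, intercept=float(res.params[0]),
                       p_value=p, stderr=float(res.bse[1]),
                       years_used=tuple(int(v) for v in yr))


def trend_table(summary: pd.DataFrame, masks: dict[str, list[int]] | None = None,
                rates: tuple[str, ...] = ("alpha1", "alpha2", "f")) -> pd.DataFrame:
    """Trend tests for each annual rate in a posterior summary table
    (as produced by :func:`aukipm.fit.summarize`)."""
    masks = masks or {}
    rows = []
    for rate in rates:
        sub = summary[(summary["parameter"] == rate) & summary["year"].notna()]
        if len(sub) < 3:
            continue
        res = fit_trend(sub["mean"].to_numpy(), sub["year"].to_numpy(),
                        mask=masks.get(rate), label=rate)
        rows.append({"rate": rate, "slope": res.slope, "p_value": res.p_value,
                     "stderr": res.stderr, "n_years": len(res.years_used)})
    return pd.DataFrame(rows)
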