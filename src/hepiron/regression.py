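"""Unpenalized follow-up regressions for selected variables.

For every variable surviving stability selection, an ordinary least squares
model of the R2* iron outcome on the exposure is fitted twice: adjusted for
age, and adjusted for age plus log hepatic fat fraction (HFF itself only
age-adjusted).  Reported per model: the unstandardized coefficient (s^-1
per exposure unit), its 95 % t-interval, the two-sided p-value and the full
model's adjusted R^2.  Plain OLS inference, no robust errors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .lasso import log_with_zero_shift


@dataclass(frozen=True)
class RegressionResult:
    exposure: str
    adjustment: str            # "age" or "age+hff"
    beta: float
    ci_low: float
    ci_high: float
    p: float
    adj_r2: float
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


_DUMMY = re.compile(r"^(?:log\()?(?P<var>[^\[\)]+)\)?(?:\[(?P<level>[^\]]+)\])?$")


def _column(cohort: Cohort, name: str) -> tuple[np.ndarray, str]:
    """Resolve a design-style column name ('var', 'log(var)', 'var[level]')
    to an analysis-scale numeric vector."""
    m = _DUMMY.match(name)
    if not m:
        raise KeyError(f"cannot parse exposure name {name!r}")
    var, level = m.group("var"), m.group("level")
    if var not in cohort.data.columns:
        raise KeyError(f"variable {var!r} not in cohort")
    ser = cohort.data[var]
    if level is not None:
        vals = (ser == level).astype(float).to_numpy()
        return vals, var
    vdef = cohort.catalog.get(var)
    vals = pd.to_numeric(ser, errors="raise").to_numpy(float)
    if vdef is not None and vdef.log_transform:
        vals = log_with_zero_shift(vals)
    return vals, var


def fit_adjusted_model(cohort: Cohort, exposure: str,
                       adjust: tuple[str, ...] = ("age", "hff")
                       ) -> RegressionResult:
    """OLS of HIC on one exposure with the given adjustment set.

    ``adjust`` may contain ``age`` and ``hff`` (the latter enters as log
    HFF).  The exposure is log-transformed when its catalog entry is
    flagged.  Exposure coinciding with an adjuster is an error.
    """
    x, base_var = _column(cohort, exposure)
    if base_var in adjust:
        raise ValueError(f"exposure {exposure!r} is also an adjuster")
    cols = {"exposure": x}
    for adj in adjust:
        if adj == "age":
            cols["age"] = pd.to_numeric(cohort.data["age"], errors="raise").to_numpy(float)
        elif adj == "hff":
            cols["log(hff)"] = log_with_zero_shift(
                pd.to_numeric(cohort.data["hff"], errors="raise").to_numpy(float))
        else:
            cols[adj], _ = _column(cohort, adj)
    y = pd.to_numeric(cohort.data["hic"], errors="raise").to_numpy(float)
    X = pd.DataFrame(cols)
    mask = ~(X.isna().any(axis=1) | np.isnan(y))
    X, y = X[mask], y[mask]
    if len(X) < X.shape[1] + 2:
        raise ValueError("too few complete cases for the adjusted model")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05).loc["exposure"]
    return RegressionResult(
        exposure=exposure,
        adjustment="+".join(adjust) if adjust else "none",
        beta=float(fit.params["exposure"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(fit.pvalues["exposure"]),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs))


def run_followup_table(cohort: Cohort, selected: list[str]) -> pd.DataFrame:
    """Fit both adjustment sets for every selected variable.

    HFF itself (and the log(hff) design column) gets the age-only model, so
    the row count is 2*|selected| - 1 when HFF is among them.  Age, being
    part of every adjustment set, gets no row of its own.  Variables absent
    from the cohort are skipped with a warning.
    """
    if not selected:
        raise ValueError("selected variable set is empty")
    if cohort.n == 0:
        raise ValueError("empty cohort stratum")
    rows = []
    for name in selected:
        base = _DUMMY.match(name).group("var")
        if base == "age":
            continue
        try:
            if base == "hff":
                fits = [fit_adjusted_model(cohort, name, ("age",))]
            else:
                fits = [fit_adjusted_model(cohort, name, ("age", "hff")),
                        fit_adjusted_model(cohort, name, ("age",))]
        except KeyError:
            warnings.warn(f"selected variable {name!r} absent from cohort; skipped")
            continue
        for f in fits:
            rows.append({"variable": f.exposure, "adjustment": f.adjustment,
                         "beta": f.beta, "ci_low": f.ci_low,
                         "ci_high": f.ci_high, "p_value": f.p,
                         "adj_r2": f.adj_r2, "n": f.n})
    return pd.DataFrame(rows)
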