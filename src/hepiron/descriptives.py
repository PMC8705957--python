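"""Descriptive layer: group summaries, two-group tests, Spearman
correlations and summary-statistic arithmetic.

Conventions: symmetric continuous variables are summarised as mean ± SD and
compared with Welch's t-test; skewed ones (|skew| > 1, or log-flagged in the
catalog) as median (IQR) with the Mann–Whitney U test; categorical variables
as counts/percent with a chi-square test without continuity correction.
Quantiles use linear interpolation (type 7).  All p-values are two-sided and
deliberately uncorrected for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    iqr: float | None = None
    counts: dict | None = None     # level -> count
    percents: dict | None = None   # level -> percent of non-missing

    def format(self, style: str, digits: int = 1) -> str:
        if self.counts is not None:
            return "; ".join(f"{k}: {self.percents[k]:.1f}% ({v})"
                             for k, v in self.counts.items())
        if style == "median_iqr":
            return f"{self.median:.{digits}f} ({self.iqr:.{digits}f})"
        return f"{self.mean:.{digits}f} ± {self.sd:.{digits}f}"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p: float
    method: str  # welch_t | mann_whitney | chi_square | spearman


def _clean(values) -> np.ndarray:
    arr = pd.Series(values)
    return pd.to_numeric(arr, errors="raise").dropna().to_numpy(float)


def summarize_variable(values, style: str = "mean_sd") -> GroupSummary:
    """Summarise one numeric or categorical vector, excluding missings."""
    ser = pd.Series(values)
    if style == "categorical" or ser.dtype == object or isinstance(
            ser.dtype, pd.CategoricalDtype):
        ser = ser.dropna()
        if ser.empty:
            raise ValueError("all values missing")
        counts = ser.value_counts(sort=False).to_dict()
        n = int(sum(counts.values()))
        percents = {k: 100.0 * v / n for k, v in counts.items()}
        return GroupSummary(n=n, counts=counts, percents=percents)
    arr = _clean(ser)
    if arr.size == 0:
        raise ValueError("all values missing")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # type-7 interpolation
    return GroupSummary(n=arr.size,
                        mean=float(np.mean(arr)),
                        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
                        median=float(med), iqr=float(q3 - q1))


def _auto_method(x, y) -> str:
    sx, sy = pd.Series(x), pd.Series(y)
    if sx.dtype == object or sy.dtype == object:
        return "chi_square"
    skew = max(abs(stats.skew(_clean(sx))), abs(stats.skew(_clean(sy))))
    return "mann_whitney" if skew > 1 else "welch_t"


def compare_two_groups(x, y, method: str = "auto") -> TestResult:
    """Two-sided two-group comparison (e.g. men vs women)."""
    if method == "auto":
        method = _auto_method(x, y)
    if method == "chi_square":
        sx = pd.Series(x).dropna()
        sy = pd.Series(y).dropna()
        if sx.empty or sy.empty:
            raise ValueError("both groups must be non-empty")
        levels = sorted(set(sx) | set(sy))
        if len(levels) < 2:
            raise ValueError("chi-square requires >= 2 levels")
        table = np.array([[np.sum(sx == lv) for lv in levels],
                          [np.sum(sy == lv) for lv in levels]])
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(float(chi2), float(dof), float(p), "chi_square")
    ax, ay = _clean(x), _clean(y)
    if ax.size == 0 or ay.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.var(ax) == 0 and np.var(ay) == 0:
        warnings.warn("zero variance in both groups; returning p = 1")
        return TestResult(0.0, float(ax.size + ay.size - 2), 1.0, method)
    if method == "welch_t":
        t, p = stats.ttest_ind(ax, ay, equal_var=False)
        df = _welch_df(np.var(ax, ddof=1), ax.size, np.var(ay, ddof=1), ay.size)
        return TestResult(float(t), float(df), float(p), "welch_t")
    if method == "mann_whitney":
        u, p = stats.mannwhitneyu(ax, ay, alternative="two-sided")
        return TestResult(float(u), None, float(p), "mann_whitney")
    raise ValueError(f"unknown method {method!r}")


def _welch_df(v1, n1, v2, n2) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Welch's t-test from printed summary statistics alone.

    Satterthwaite degrees of freedom; two-sided p.  This is what lets the
    headline sex contrast (41.8 ± 4.7 s^-1 in 206 men vs 39.2 ± 4.1 s^-1 in
    147 women) be verified without participant-level data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    se2 = sd1 ** 2 / n1 + sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(se2)
    df = _welch_df(sd1 ** 2, n1, sd2 ** 2, n2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "welch_t")


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with midrank ties and t-approximation p."""
    pairs = pd.DataFrame({"x": pd.to_numeric(pd.Series(x), errors="coerce"),
                          "y": pd.to_numeric(pd.Series(y), errors="coerce")}).dropna()
    if len(pairs) < 3:
        raise ValueError("need >= 3 complete pairs")
    if pairs["x"].nunique() == 1 or pairs["y"].nunique() == 1:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(pairs["x"], pairs["y"])
    return TestResult(float(rho), float(len(pairs) - 2), float(p), "spearman")


def pooled_mean_from_groups(means, ns) -> float:
    """n-weighted mean of per-group means: sum(n_i m_i) / sum(n_i)."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    if means.size == 0 or means.size != ns.size:
        raise ValueError("means and ns must be equal-length and non-empty")
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sum(means * ns) / np.sum(ns))


def build_table_one(cohort: Cohort, digits: int = 1) -> pd.DataFrame:
    """Variable-by-sex descriptive table with male/female/total summaries
    and the two-group p-value (test routed by variable type/skew)."""
    male, female = cohort.stratify_by_sex()
    rows = []
    from .cohort import VariableDef
    entries = dict(cohort.catalog)
    for outcome in ("hic", "hic_right", "hic_left"):
        if outcome in cohort.data.columns:
            entries[outcome] = VariableDef(outcome, "continuous", units="s^-1")
    for name, vdef in entries.items():
        if name not in cohort.data.columns:
            continue
        xm, xf = male.data[name], female.data[name]
        xa = cohort.data[name]
        if xm.dropna().empty or xf.dropna().empty:
            continue
        if vdef.dtype in ("categorical", "binary"):
            style = "categorical"
            sm = summarize_variable(xm.astype(object), style)
            sf = summarize_variable(xf.astype(object), style)
            st = summarize_variable(xa.astype(object), style)
            test = compare_two_groups(xm.astype(object), xf.astype(object),
                                      "chi_square")
        else:
            skewed = vdef.log_transform or abs(stats.skew(xm.dropna())) > 1
            style = "median_iqr" if skewed else "mean_sd"
            sm = summarize_variable(xm, style)
            sf = summarize_variable(xf, style)
            st = summarize_variable(xa, style)
            test = compare_two_groups(
                xm, xf, "mann_whitney" if skewed else "welch_t")
        rows.append({"variable": name, "units": vdef.units,
                     "male": sm.format(style, digits),
                     "female": sf.format(style, digits),
                     "total": st.format(style, digits),
                     "n_male": sm.n, "n_female": sf.n,
                     "p_value": test.p, "test": test.method})
    return pd.DataFrame(rows)
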