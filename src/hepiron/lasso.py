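"""Penalized variable selection: design construction, LASSO coordinate
descent, cross-validated penalty tuning and bootstrap stability selection.

The selection statistic is the *inclusion frequency* pi_j: the fraction of
bootstrap resamples in which variable j has a nonzero coefficient at that
resample's cross-validation-optimal penalty.  Variables with pi_j strictly
above the relevance threshold (default 20 %) are deemed relevant.

Modelling conventions
---------------------
* Candidate columns are standardized (mean 0, SD 1); the outcome is centred
  but never scaled, so coefficients stay in s^-1.
* Standardization is recomputed inside every bootstrap resample — selection
  would otherwise be scale-dependent.
* The penalty is tuned per bootstrap resample by 10-fold cross-validation
  with the CV-minimum rule over a 100-point log-spaced grid from lambda_max
  down to 1e-3 * lambda_max.
* Dummy columns of a categorical are penalized individually (no group
  penalty).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from . import _solver
from .cohort import Cohort, VariablePanel


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LassoConfig:
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: str = "min"   # "min" (CV-optimal) or "1se" (conservative)
    n_folds: int = 10
    n_bootstrap: int = 1000
    inclusion_threshold: float = 0.20
    zero_tol: float = 1e-12
    tol: float = 1e-8
    max_sweeps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if not 0.0 < self.inclusion_threshold < 1.0:
            raise ValueError("inclusion threshold must be in (0, 1)")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


class DesignMatrix:
    """Numeric design for penalized regression.

    ``X`` holds the standardized columns, ``X_raw`` the analysis-scale
    columns (dummy-coded, log-transformed) before standardization.  Columns
    with zero variance are rejected at construction.
    """

    def __init__(self, X_raw: np.ndarray, y: np.ndarray,
                 column_names: list[str], penalty_weights=None):
        X_raw = np.asarray(X_raw, float)
        y = np.asarray(y, float)
        if np.isnan(X_raw).any() or np.isnan(y).any():
            raise ValueError("design must not contain missing entries")
        self.X_raw = X_raw
        self.y = y
        self.column_names = list(column_names)
        self.means = X_raw.mean(axis=0)
        self.sds = X_raw.std(axis=0)
        zero = np.where(self.sds < 1e-12)[0]
        if zero.size:
            names = [column_names[j] for j in zero]
            raise ValueError(f"zero-variance column(s): {names}")
        self.X = (X_raw - self.means) / self.sds
        self.penalty_weights = (np.ones(X_raw.shape[1])
                                if penalty_weights is None
                                else np.asarray(penalty_weights, float))

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def p(self):
        return self.X.shape[1]


def log_with_zero_shift(values: np.ndarray) -> np.ndarray:
    """Natural log; exact zeros are shifted by half the minimum positive
    value so the transform is defined."""
    v = np.asarray(values, float)
    if (v < 0).any():
        raise ValueError("cannot log-transform negative values")
    if (v == 0).any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("cannot log-transform an all-zero column")
        v = np.where(v == 0, pos.min() / 2.0, v)
    return np.log(v)


def build_design(cohort: Cohort, panel: VariablePanel,
                 outcome: str = "hic") -> DesignMatrix:
    """Expand the candidate panel into a standardized numeric design.

    Complete cases only (missing entries are an error — run the exclusion
    filter first).  Categorical variables become dummy columns against the
    catalog's reference level, named ``var[level]``; log-flagged variables
    are natural-log transformed.
    """
    df = cohort.data
    names = list(panel.forced) + [v for v in panel.candidates if v != outcome]
    cols, colnames, weights = [], [], []
    for name in names:
        if name not in df.columns:
            raise KeyError(f"variable {name!r} not present in the cohort")
        vdef = cohort.catalog.get(name)
        w = 0.0 if name in panel.forced else 1.0
        if vdef is not None and vdef.dtype == "categorical":
            ref, *others = vdef.levels
            vals = df[name]
            bad = vals.dropna()[~vals.dropna().isin(vdef.levels)]
            if len(bad):
                raise ValueError(f"{name}: unknown level(s) {sorted(set(bad))}")
            for lv in others:
                cols.append((vals == lv).astype(float).to_numpy())
                colnames.append(f"{name}[{lv}]")
                weights.append(w)
        else:
            vals = pd.to_numeric(df[name], errors="raise").to_numpy(float)
            if vdef is not None and vdef.log_transform:
                vals = log_with_zero_shift(vals)
                colnames.append(f"log({name})")
            else:
                colnames.append(name)
            cols.append(vals)
            weights.append(w)
    X = np.column_stack(cols)
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(float)
    return DesignMatrix(X, y, colnames, np.asarray(weights))


# --------------------------------------------------------------------------
# single-fit machinery
# --------------------------------------------------------------------------

def _gram(X: np.ndarray, y: np.ndarray):
    n = X.shape[0]
    xbar = X.mean(axis=0)
    ybar = y.mean()
    G = X.T @ X / n - np.outer(xbar, xbar)
    c = X.T @ y / n - xbar * ybar
    return G, c, xbar, ybar


def lambda_max(design: DesignMatrix) -> float:
    """Smallest penalty that zeroes every (penalized) coefficient:
    max_j |x_j'(y - ybar)| / n on the standardized design."""
    _, c, _, _ = _gram(design.X, design.y)
    pen = design.penalty_weights > 0
    if not pen.any():
        return 0.0
    return float(np.max(np.abs(c[pen]) / design.penalty_weights[pen]))


def lambda_grid(design: DesignMatrix, config: LassoConfig) -> np.ndarray:
    lmax = lambda_max(design)
    if lmax <= 0.0:
        return np.array([0.0])
    return np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambda)


@dataclass(frozen=True)
class LassoFit:
    beta: np.ndarray              # standardized-column scale
    beta_original: np.ndarray     # analysis scale (s^-1 per raw unit)
    intercept: float
    lam: float
    sweeps: int
    column_names: list


def fit_lasso(design: DesignMatrix, lam: float,
              config: LassoConfig = LassoConfig()) -> LassoFit:
    """Cyclic coordinate descent with soft-thresholding at one penalty."""
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    G, c, xbar, ybar = _gram(design.X, design.y)
    beta, sweeps = _solver.cd_single(G, c, lam, design.penalty_weights,
                                     config.tol, config.max_sweeps)
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge at lambda={lam:g} "
            f"after {-sweeps} sweeps (tol={config.tol:g}, n={design.n}, "
            f"p={design.p})")
    beta_orig = beta / design.sds
    intercept = float(design.y.mean() - design.means @ beta_orig)
    return LassoFit(beta, beta_orig, intercept, float(lam), int(sweeps),
                    design.column_names)


def kkt_violation(design: DesignMatrix, fit: LassoFit,
                  zero_tol: float = 1e-12) -> float:
    """Max violation of the stationarity conditions at the solution:
    |x_j'r/n| <= lam for zero coefficients, = lam*sign(b_j) otherwise."""
    G, c, _, _ = _gram(design.X, design.y)
    g = c - G @ fit.beta
    lamw = fit.lam * design.penalty_weights
    viol = 0.0
    for j in range(design.p):
        if abs(fit.beta[j]) <= zero_tol:
            viol = max(viol, abs(g[j]) - lamw[j])
        else:
            viol = max(viol, abs(g[j] - lamw[j] * np.sign(fit.beta[j])))
    return float(viol)


def assign_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels by seeded random permutation, sizes differing by <= 1."""
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.int64)
    folds[perm] = np.arange(n) % n_folds
    return folds


def cv_select_lambda(design: DesignMatrix, config: LassoConfig,
                     rng: np.random.Generator):
    """Tune the penalty by k-fold cross-validation over the grid.

    ``lambda_rule='min'`` takes the penalty minimizing mean out-of-fold
    squared error (ties to the heavier penalty); ``'1se'`` takes the
    heaviest penalty whose CV error is within one standard error (across
    folds) of that minimum — the conservative convention that keeps
    selection stable under resampling.
    """
    if design.n < config.n_folds:
        raise ValueError("fewer observations than folds")
    folds = assign_folds(design.n, config.n_folds, rng)
    sizes = np.bincount(folds, minlength=config.n_folds)
    if sizes.min() < 2:
        raise ValueError("a CV fold has fewer than 2 observations")
    grid = lambda_grid(design, config)
    X, y = design.X, design.y
    sse_folds, nf = _solver.cv_fold_errors(
        X.T @ X, X.T @ y, X.sum(axis=0), float(y.sum()), X, y,
        folds, config.n_folds, grid, design.penalty_weights,
        config.tol, config.max_sweeps)
    errors = sse_folds.sum(axis=0) / design.n
    k_min = int(np.argmin(errors))
    if config.lambda_rule == "min" or len(grid) == 1:
        best = k_min
    else:
        fold_means = sse_folds / nf[:, None]
        se = fold_means.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        best = int(np.argmax(errors <= errors[k_min] + se[k_min]))
    return float(grid[best]), grid, errors


# --------------------------------------------------------------------------
# bootstrap stability selection
# --------------------------------------------------------------------------

def _one_bootstrap(X_raw, y, weights, config, seed, b):
    rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
    n, p = X_raw.shape
    idx = rng.integers(0, n, size=n)
    Xr, yr = X_raw[idx], y[idx]
    sds = Xr.std(axis=0)
    keep = sds >= 1e-12
    Xs = (Xr[:, keep] - Xr[:, keep].mean(axis=0)) / sds[keep]
    sub = DesignMatrix.__new__(DesignMatrix)
    sub.X_raw = Xr[:, keep]
    sub.X = Xs
    sub.y = yr
    sub.column_names = [str(j) for j in range(int(keep.sum()))]
    sub.means = Xr[:, keep].mean(axis=0)
    sub.sds = sds[keep]
    sub.penalty_weights = weights[keep]
    lam, _, _ = cv_select_lambda(sub, config, rng)
    G, c, _, _ = _gram(Xs, yr)
    beta, sweeps = _solver.cd_single(G, c, lam, sub.penalty_weights,
                                     config.tol, config.max_sweeps)
    if sweeps < 0:
        raise ConvergenceError(f"bootstrap {b}: no convergence at lambda={lam:g}")
    included = np.zeros(p, dtype=bool)
    included[np.where(keep)[0]] = np.abs(beta) > config.zero_tol
    dropped = np.where(~keep)[0]
    return included, lam, dropped


class StabilitySelection:
    """Bootstrap-LASSO stability selection model.

    For each of B bootstrap resamples (rows drawn with replacement), the
    design is re-standardized, the penalty tuned by seeded 10-fold
    cross-validation, the LASSO fitted at the optimum, and the nonzero
    pattern recorded.  ``fit`` returns a :class:`StabilityResults`.
    """

    def __init__(self, design: DesignMatrix, config: LassoConfig = LassoConfig()):
        self.design = design
        self.config = config

    @classmethod
    def from_cohort(cls, cohort: Cohort, panel: VariablePanel,
                    outcome: str = "hic",
                    config: LassoConfig = LassoConfig()) -> "StabilitySelection":
        return cls(build_design(cohort, panel, outcome), config)

    def fit(self, n_jobs: int = 1) -> "StabilityResults":
        cfg = self.config
        d = self.design
        args = (d.X_raw, d.y, d.penalty_weights, cfg, int(cfg.seed))
        if n_jobs == 1:
            results = [_one_bootstrap(*args, b) for b in range(cfg.n_bootstrap)]
        else:
            results = Parallel(n_jobs=n_jobs)(
                delayed(_one_bootstrap)(*args, b) for b in range(cfg.n_bootstrap))
        inc = np.array([r[0] for r in results])
        lams = np.array([r[1] for r in results])
        dropped = [(b, d.column_names[j]) for b, r in enumerate(results)
                   for j in r[2]]
        pi = pd.Series(inc.mean(axis=0), index=d.column_names,
                       name="inclusion_frequency")
        return StabilityResults(pi, lams, cfg, dropped)


class StabilityResults:
    """Per-variable bootstrap inclusion frequencies and relevance flags."""

    def __init__(self, inclusion_frequency: pd.Series,
                 selected_lambdas: np.ndarray, config: LassoConfig,
                 dropped: list):
        order = np.lexsort((inclusion_frequency.index,
                            -inclusion_frequency.values))
        self.inclusion_frequency = inclusion_frequency.iloc[order]
        self.selected_lambdas = selected_lambdas
        self.config = config
        self.dropped = dropped
        self.n_bootstrap = len(selected_lambdas)

    @property
    def relevant(self) -> pd.Series:
        return self.inclusion_frequency > self.config.inclusion_threshold

    def select_relevant(self, threshold: float | None = None) -> list[str]:
        """Variables with pi strictly above the threshold, by descending pi."""
        thr = self.config.inclusion_threshold if threshold is None else threshold
        pi = self.inclusion_frequency
        return list(pi.index[pi > thr])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.inclusion_frequency.index,
            "inclusion_frequency": self.inclusion_frequency.values,
            "relevant": self.relevant.values,
        })

    def summary(self) -> str:
        lines = [f"Bootstrap stability selection (B={self.n_bootstrap}, "
                 f"threshold>{self.config.inclusion_threshold:.0%})",
                 f"median selected lambda: {np.median(self.selected_lambdas):.4g}",
                 "-" * 56,
                 f"{'variable':<36}{'pi':>8}  relevant"]
        for name, v in self.inclusion_frequency.items():
            lines.append(f"{name:<36}{v:>8.3f}  "
                         f"{'*' if v > self.config.inclusion_threshold else ''}")
        return "\n".join(lines)
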