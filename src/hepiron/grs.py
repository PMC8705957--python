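"""Weighted genetic risk score for hepatic iron.

Each SNP's weight is the slope of a sex-stratified univariate linear
regression of the R2* iron outcome on its allele dosage (intercept
included, no covariates); a participant's score is the weighted dosage sum
using the weights of their own sex.  As in the source analysis, weights are
by default estimated on the same cohort they score (in-sample circularity
preserved); pass a different cohort to ``fit`` for a split-sample design.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, VariableDef
from .descriptives import TestResult, welch_t_from_summary

GRS_COLUMN = "genetic_risk_score"


class GenotypeMatrix:
    """Per-participant allele dosages (values in [0, 2]) for a SNP panel."""

    def __init__(self, dosages: pd.DataFrame, panel=()):
        arr = dosages.to_numpy(float)
        if np.isnan(arr).any():
            raise ValueError("dosage matrix must be complete")
        if (arr < 0).any() or (arr > 2).any():
            raise ValueError("dosages must lie in [0, 2]")
        self.dosages = dosages
        self.panel = tuple(panel)

    @property
    def snp_ids(self):
        return list(self.dosages.columns)

    @property
    def ids(self):
        return list(self.dosages.index)

    def allele_frequencies(self) -> pd.Series:
        return self.dosages.mean(axis=0) / 2.0


def estimate_weights(genotypes: GenotypeMatrix, cohort: Cohort) -> pd.DataFrame:
    """Sex-specific per-SNP weights: slope of HIC ~ dosage within stratum.

    Monomorphic SNPs in a stratum get weight 0 with a warning.
    """
    df = cohort.data.set_index("id")
    missing = [i for i in genotypes.ids if i not in df.index]
    if missing:
        raise KeyError(f"genotype ids absent from cohort: {missing[:5]}")
    out = {}
    for sex in ("male", "female"):
        ids = df.index[df["sex"] == sex]
        ids = [i for i in genotypes.ids if i in set(ids)]
        if len(ids) < 10:
            raise ValueError(f"need >= 10 participants in the {sex} stratum")
        y = df.loc[ids, "hic"].to_numpy(float)
        weights = []
        for snp in genotypes.snp_ids:
            d = genotypes.dosages.loc[ids, snp].to_numpy(float)
            if d.std() < 1e-12:
                warnings.warn(f"{snp} is monomorphic in the {sex} stratum; weight 0")
                weights.append(0.0)
                continue
            fit = sm.OLS(y, sm.add_constant(d)).fit()
            weights.append(float(fit.params[1]))
        out[sex] = weights
    return pd.DataFrame(out, index=genotypes.snp_ids)


def compute_grs(genotypes: GenotypeMatrix, weights: pd.DataFrame,
                sex_by_id: pd.Series) -> pd.Series:
    """Continuous score: sum_j w_j(sex) * dosage_ij.  Deterministic."""
    missing = [i for i in genotypes.ids if i not in sex_by_id.index]
    if missing:
        raise KeyError(f"no sex recorded for genotype ids: {missing[:5]}")
    D = genotypes.dosages
    missing_w = [s for s in D.columns if s not in weights.index]
    if missing_w:
        raise KeyError(f"no weight for SNP(s): {missing_w}")
    scores = pd.Series(np.nan, index=D.index, name=GRS_COLUMN)
    for sex in ("male", "female"):
        ids = [i for i in D.index if sex_by_id.loc[i] == sex]
        if ids:
            w = weights[sex].reindex(D.columns).to_numpy()
            scores.loc[ids] = D.loc[ids].to_numpy() @ w
    return scores


def quartile_labels(scores: pd.Series) -> pd.Series:
    """Q1..Q4 by midrank with stable id-order tie-break; group sizes within
    a stratum differ by at most one."""
    order = np.lexsort((scores.index, scores.to_numpy()))
    n = len(scores)
    labels = np.empty(n, dtype=object)
    qs = np.minimum((np.arange(n) * 4) // n, 3)
    labels[order] = [f"Q{q + 1}" for q in qs]
    return pd.Series(labels, index=scores.index, name="grs_quartile")


class GeneticRiskScore:
    """Model object tying a genotype matrix to a cohort."""

    def __init__(self, genotypes: GenotypeMatrix, cohort: Cohort):
        self.genotypes = genotypes
        self.cohort = cohort

    def fit(self, weight_cohort: Cohort | None = None) -> "GRSResults":
        wc = weight_cohort if weight_cohort is not None else self.cohort
        weights = estimate_weights(self.genotypes, wc)
        sex_by_id = self.cohort.data.set_index("id")["sex"]
        scores = compute_grs(self.genotypes, weights, sex_by_id)
        return GRSResults(weights, scores, self.cohort)


class GRSResults:
    def __init__(self, weights: pd.DataFrame, scores: pd.Series, cohort: Cohort):
        self.weights = weights
        self.scores = scores
        self.cohort = cohort

    def quartiles(self) -> pd.Series:
        """Sex-stratified quartile labels for the scored participants."""
        sex_by_id = self.cohort.data.set_index("id")["sex"]
        parts = []
        for sex in ("male", "female"):
            ids = [i for i in self.scores.index if sex_by_id.loc[i] == sex]
            if ids:
                parts.append(quartile_labels(self.scores.loc[ids]))
        return pd.concat(parts).reindex(self.scores.index)

    def quartile_contrast(self) -> tuple[pd.DataFrame, dict]:
        """Per-sex per-quartile HIC means and the Welch Q1-vs-Q4 test."""
        df = self.cohort.data.set_index("id")
        quart = self.quartiles()
        rows, tests = [], {}
        for sex in ("male", "female"):
            ids = [i for i in self.scores.index if df.loc[i, "sex"] == sex]
            if len(ids) < 8:
                raise ValueError(f"need >= 8 scored participants per sex ({sex})")
            hic = df.loc[ids, "hic"].astype(float)
            q = quart.loc[ids]
            groups = {lab: hic[q == lab] for lab in ("Q1", "Q2", "Q3", "Q4")}
            for lab, vals in groups.items():
                rows.append({"sex": sex, "quartile": lab, "n": len(vals),
                             "hic_mean": vals.mean(), "hic_sd": vals.std(ddof=1)})
            g1, g4 = groups["Q1"], groups["Q4"]
            tests[sex] = welch_t_from_summary(
                g4.mean(), g4.std(ddof=1), len(g4),
                g1.mean(), g1.std(ddof=1), len(g1))
        return pd.DataFrame(rows), tests

    def append_to(self, cohort: Cohort | None = None,
                  name: str = GRS_COLUMN) -> Cohort:
        """Add the continuous score as a candidate covariate column."""
        target = cohort if cohort is not None else self.cohort
        if name in target.data.columns:
            raise ValueError(f"column {name!r} already present")
        out = target.copy()
        out.data[name] = out.data["id"].map(self.scores)
        out.catalog[name] = VariableDef(name, "continuous", units="s^-1")
        return out

    def summary(self) -> str:
        lines = ["Genetic risk score (sex-stratified univariate weights, s^-1 per dosage)"]
        lines.append(self.weights.round(4).to_string())
        lines.append(f"scored participants: {len(self.scores)}")
        return "\n".join(lines)
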