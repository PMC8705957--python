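"""Participant/cohort data model and the variable catalog.

A :class:`Cohort` wraps a pandas DataFrame with one row per participant,
carrying the MRI liver outcomes (R2* hepatic iron content in s^-1, averaged
over the left and right lobe; hepatic fat fraction in percent) plus a broad
covariate panel (body composition, blood lipids, glucose markers, renal
markers, blood count, electrolytes, blood pressure, liver enzymes, behaviour
and medication flags).  Every analysis downstream is stratified by sex, so
the cohort knows how to partition itself.

Missing values are represented as NaN / <NA> internally — never as sentinel
numbers — because participant exclusion is missingness-driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

SEXES = ("male", "female")

#: columns every cohort table must provide (hic may be derived from lobes)
MANDATORY_COLUMNS = ("id", "sex")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


@dataclass(frozen=True)
class VariableDef:
    """Catalog entry for one variable.

    ``dtype`` is one of ``continuous | binary | categorical``.  For
    categorical variables ``levels`` lists the admissible codes with the
    *reference level first* (reference = largest group, e.g. normoglycemic,
    never-smoker).  ``log_transform`` marks highly skewed variables that are
    natural-log transformed before any regression stage.  Units are metadata
    only and never converted implicitly.
    """

    name: str
    dtype: str = "continuous"
    log_transform: bool = False
    units: str = ""
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.dtype not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name}")
        if self.dtype == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name} needs levels")


def _v(name, dtype="continuous", log=False, units="", levels=None):
    return VariableDef(name, dtype, log, units, levels)


def default_catalog() -> dict[str, VariableDef]:
    """The default covariate catalog (the full descriptive panel).

    Log flags follow the "(log)" rows of the follow-up regression tables:
    triglycerides, fasting insulin, urine albumin, sodium and HFF, plus the
    strongly right-skewed liver enzymes, CRP, leucocytes and 2h insulin.
    """
    defs = [
        _v("age", units="years"),
        # body composition
        _v("body_weight", units="kg"),
        _v("height", units="cm"),
        _v("bmi", units="kg/m^2"),
        _v("waist_circumference", units="cm"),
        _v("hip_circumference", units="cm"),
        _v("subcutaneous_fat", units="L"),
        _v("visceral_fat", units="L"),
        # blood lipids
        _v("total_cholesterol", units="mg/dL"),
        _v("hdl_cholesterol", units="mg/dL"),
        _v("ldl_cholesterol", units="mg/dL"),
        _v("triglycerides", log=True, units="mg/dL"),
        # glucose metabolism
        _v("fasting_glucose", units="mg/dL"),
        _v("fasting_insulin", log=True, units="mU/mL"),
        _v("hba1c", units="%"),
        _v("diabetes_status", "categorical",
           levels=("normoglycemic", "prediabetes", "diabetes")),
        # renal function
        _v("gfr", units="mL/min/1.73m^2"),
        _v("uric_acid", units="mg/dL"),
        _v("creatinine", units="mg/dL"),
        _v("serum_albumin", units="g/dL"),
        _v("cystatin_c", units="mg/L"),
        _v("urine_albumin", log=True, units="mg/L"),
        _v("urine_creatinine", units="g/L"),
        # complete blood count
        _v("hematocrit", units="L/L"),
        _v("thrombocytes", units="/nL"),
        _v("erythrocytes", units="/pL"),
        _v("leucocytes", log=True, units="/nL"),
        _v("hemoglobin", units="g/L"),
        # electrolytes
        _v("potassium", units="mmol/L"),
        _v("sodium", log=True, units="mmol/L"),
        _v("magnesium", units="mmol/L"),
        _v("phosphate", units="mmol/L"),
        # blood pressure
        _v("sbp", units="mmHg"),
        _v("dbp", units="mmHg"),
        _v("hypertension", "binary"),
        # liver enzymes & outcome-adjacent
        _v("ggt", log=True, units="U/L"),
        _v("ast", log=True, units="U/L"),
        _v("alt", log=True, units="U/L"),
        _v("hff", log=True, units="%"),
        # further laboratory values
        _v("alkaline_phosphatase", units="U/L"),
        _v("crp", log=True, units="mg/L"),
        _v("vitamin_d", units="ng/mL"),
        # behaviour
        _v("alcohol", units="g/day"),
        _v("smoking_status", "categorical",
           levels=("never-smoker", "ex-smoker", "smoker")),
        _v("physical_activity", "binary"),
        # medication flags
        _v("beta_blockers", "binary"),
        _v("ace_inhibitors", "binary"),
        _v("calcium_antagonists", "binary"),
        _v("diuretics", "binary"),
        _v("lipid_lowering", "binary"),
        # OGTT subsample variables (not in the main candidate panel)
        _v("two_hour_glucose", units="mg/dL"),
        _v("two_hour_insulin", log=True, units="uU/mL"),
    ]
    return {d.name: d for d in defs}


#: variables present in the catalog but excluded from the default LASSO panel
NON_CANDIDATE = ("two_hour_glucose", "two_hour_insulin")


@dataclass(frozen=True)
class VariablePanel:
    """The candidate variable set entered into selection.

    ``forced`` variables (possibly none) are always retained downstream and
    must be disjoint from the candidates.
    """

    candidates: tuple[str, ...]
    forced: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        overlap = set(self.candidates) & set(self.forced)
        if overlap:
            raise ValueError(f"forced and candidate overlap: {sorted(overlap)}")

    @classmethod
    def default(cls, catalog: dict[str, VariableDef] | None = None,
                exclude: tuple[str, ...] = ()) -> "VariablePanel":
        catalog = catalog if catalog is not None else default_catalog()
        drop = set(NON_CANDIDATE) | set(exclude)
        return cls(tuple(n for n in catalog if n not in drop))


class Cohort:
    """Typed participant table plus its variable catalog.

    Parameters
    ----------
    data : DataFrame with at least ``id``, ``sex`` and the liver outcomes.
    catalog : mapping name -> VariableDef for the covariate panel.
    validate : run structural invariants (unique ids, sex codes, lobe-mean
        consistency of HIC, HFF range).
    """

    def __init__(self, data: pd.DataFrame, catalog: dict[str, VariableDef] | None = None,
                 validate: bool = True):
        self.data = data.reset_index(drop=True)
        self.catalog = dict(catalog) if catalog is not None else default_catalog()
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------
    def _validate(self):
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"mandatory column {col!r} missing")
        if not ("hic" in df.columns or
                ("hic_right" in df.columns and "hic_left" in df.columns)):
            raise CohortValidationError(
                "need 'hic' or both 'hic_right' and 'hic_left'")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise CohortValidationError(f"duplicate participant ids: {dups}")
        bad_sex = df.loc[df["sex"].notna() & ~df["sex"].isin(SEXES), "id"]
        if len(bad_sex):
            raise CohortValidationError(
                f"unknown sex code for ids: {bad_sex.tolist()}")
        # derive / check the lobe-averaged iron outcome
        if "hic_right" in df.columns and "hic_left" in df.columns:
            lobe_mean = (pd.to_numeric(df["hic_right"], errors="coerce")
                         + pd.to_numeric(df["hic_left"], errors="coerce")) / 2.0
            if "hic" not in df.columns:
                df["hic"] = lobe_mean
            else:
                both = df["hic"].notna() & lobe_mean.notna()
                off = both & (np.abs(df.loc[both, "hic"] - lobe_mean[both]) > 1e-9)
                if off.any():
                    raise CohortValidationError(
                        "hic differs from the lobe mean for ids: "
                        f"{df.loc[off, 'id'].tolist()}")
                df.loc[df["hic"].isna(), "hic"] = lobe_mean
        hic = pd.to_numeric(df["hic"], errors="coerce")
        if (hic.dropna() <= 0).any():
            raise CohortValidationError("non-positive HIC values present")
        for col in ("hff", "hff_right", "hff_left"):
            if col in df.columns:
                v = pd.to_numeric(df[col], errors="coerce").dropna()
                if ((v < 0) | (v > 100)).any():
                    raise CohortValidationError(
                        f"{col} outside [0, 100] for some participants")

    # -- basic accessors ---------------------------------------------------
    def __len__(self):
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def __repr__(self):
        counts = self.data["sex"].value_counts().to_dict()
        return f"<Cohort n={self.n} ({counts})>"

    def variable(self, name: str) -> pd.Series:
        return self.data[name]

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.catalog, validate=False)

    # -- stratification ----------------------------------------------------
    def stratify_by_sex(self) -> tuple["Cohort", "Cohort"]:
        """Partition into (male, female) strata, order preserved."""
        missing = self.data.loc[self.data["sex"].isna(), "id"]
        if len(missing):
            raise CohortValidationError(
                f"sex missing for ids: {missing.tolist()}")
        male = self.data[self.data["sex"] == "male"]
        female = self.data[self.data["sex"] == "female"]
        return (Cohort(male, self.catalog, validate=False),
                Cohort(female, self.catalog, validate=False))

    # -- missingness -------------------------------------------------------
    def missing_any(self, columns) -> pd.Series:
        """Boolean mask: participant has >=1 missing value among columns."""
        cols = [c for c in columns if c in self.data.columns]
        return self.data[cols].isna().any(axis=1)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path):
        self.data.to_csv(path, index=False, float_format="%.12g", na_rep="")

    def catalog_to_yaml(self, path):
        doc = {n: {"dtype": d.dtype, "log_transform": d.log_transform,
                   "units": d.units,
                   **({"levels": list(d.levels)} if d.levels else {})}
               for n, d in self.catalog.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def catalog_from_yaml(path) -> dict[str, VariableDef]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {n: VariableDef(n, e.get("dtype", "continuous"),
                           e.get("log_transform", False), e.get("units", ""),
                           tuple(e["levels"]) if "levels" in e else None)
            for n, e in doc.items()}


def load_cohort(path, catalog: dict[str, VariableDef] | None = None) -> Cohort:
    """Read a cohort CSV (UTF-8, header row, one participant per row).

    Empty cells and ``NA`` denote missing values.  Unparseable numeric cells
    become missing (with a warning naming the columns) rather than being
    dropped silently.  Missing mandatory columns are a hard error.
    """
    catalog = catalog if catalog is not None else default_catalog()
    df = pd.read_csv(path, dtype=str, na_values=["", "NA"],
                     keep_default_na=False, skipinitialspace=True)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"mandatory column {col!r} missing in {path}")
    if not ("hic" in df.columns or
            ("hic_right" in df.columns and "hic_left" in df.columns)):
        raise CohortValidationError(
            f"{path}: need 'hic' or both lobe columns 'hic_right'/'hic_left'")
    numeric_like = [c for c in df.columns
                    if c not in ("id", "sex")
                    and catalog.get(c, VariableDef(c)).dtype != "categorical"]
    coerced = []
    for col in numeric_like:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.notna().sum() == 0 and df[col].notna().any():
            continue  # fully non-numeric column (e.g. a class label): keep as-is
        if (parsed.isna() & df[col].notna()).any():
            coerced.append(col)
        df[col] = parsed
    if coerced:
        warnings.warn(f"unparseable numeric cells set to missing in: {coerced}")
    return Cohort(df, catalog)


def write_cohort(cohort: Cohort, path):
    cohort.to_csv(path)
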