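"""Threshold rules: participant-flow exclusions, iron-overload grades,
steatosis and glycemic status.

Grade cutoffs follow the SHIP-derived R2* thresholds: mild overload above
41 s^-1 (strict), moderate from 62.5 s^-1 and severe from 70.1 s^-1 (both
inclusive lower bounds — only the 41 boundary direction is printed, the
upper grades adopt the conventional closed-left reading).  Steatosis is a
hepatic fat fraction of at least 5.6 % (inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, NON_CANDIDATE

IRON_GRADES = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class ClassifierConfig:
    mild_cutoff: float = 41.0       # s^-1, exclusive lower bound
    moderate_cutoff: float = 62.5   # s^-1, inclusive
    severe_cutoff: float = 70.1     # s^-1, inclusive
    steatosis_cutoff: float = 5.6   # %, inclusive
    # ADA-style lab thresholds, configurable because the operational
    # prediabetes definition is site-specific
    diabetes_fasting: float = 126.0
    diabetes_two_hour: float = 200.0
    diabetes_hba1c: float = 6.5
    prediabetes_fasting: float = 100.0
    prediabetes_two_hour: float = 140.0
    prediabetes_hba1c: float = 5.7

    def __post_init__(self):
        if not (0 < self.mild_cutoff < self.moderate_cutoff < self.severe_cutoff):
            raise ValueError("iron cutoffs must satisfy 0 < mild < moderate < severe")
        if self.steatosis_cutoff <= 0:
            raise ValueError("steatosis cutoff must be positive")


DEFAULT_CONFIG = ClassifierConfig()


def classify_iron_overload(hic, config: ClassifierConfig = DEFAULT_CONFIG):
    """Grade R2* values into none/mild/moderate/severe.

    Accepts a scalar or array; every positive value maps to exactly one
    grade, and the grade is monotone in ``hic``.
    """
    arr = np.asarray(hic, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("HIC must be positive")
    grades = np.select(
        [arr >= config.severe_cutoff, arr >= config.moderate_cutoff,
         arr > config.mild_cutoff],
        ["severe", "moderate", "mild"], default="none")
    if np.isscalar(hic) or arr.ndim == 0:
        return str(grades)
    return pd.Categorical(grades, categories=IRON_GRADES, ordered=True)


def classify_steatosis(hff, config: ClassifierConfig = DEFAULT_CONFIG):
    """Steatosis iff hepatic fat fraction >= cutoff (inclusive)."""
    arr = np.asarray(hff, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("HFF must lie in [0, 100] percent")
    out = np.where(arr >= config.steatosis_cutoff, "steatosis", "no_steatosis")
    if np.isscalar(hff) or arr.ndim == 0:
        return str(out)
    return out


def classify_glycemia(fasting_glucose=None, two_hour_glucose=None, hba1c=None,
                      physician_diagnosis=None,
                      config: ClassifierConfig = DEFAULT_CONFIG):
    """Glycemic status: diagnosed diabetes dominates, otherwise lab bands.

    Returns ``None`` (missing class) when every input is missing.
    """
    def missing(x):
        return x is None or (isinstance(x, float) and np.isnan(x))

    if physician_diagnosis is not None and not (
            isinstance(physician_diagnosis, float) and np.isnan(physician_diagnosis)):
        if physician_diagnosis:
            return "diabetes"
    labs = [(fasting_glucose, config.diabetes_fasting, config.prediabetes_fasting),
            (two_hour_glucose, config.diabetes_two_hour, config.prediabetes_two_hour),
            (hba1c, config.diabetes_hba1c, config.prediabetes_hba1c)]
    seen = False
    pre = False
    for value, diab_cut, pre_cut in labs:
        if missing(value):
            continue
        seen = True
        if value >= diab_cut:
            return "diabetes"
        if value >= pre_cut:
            pre = True
    if not seen:
        if physician_diagnosis is None or (
                isinstance(physician_diagnosis, float) and np.isnan(physician_diagnosis)):
            return None
        return "normoglycemic" if not physician_diagnosis else "diabetes"
    return "prediabetes" if pre else "normoglycemic"


def required_columns(cohort: Cohort) -> list[str]:
    """Fields whose absence excludes a participant: the iron outcome plus
    every candidate covariate of the catalog."""
    cols = []
    if "hic_right" in cohort.data.columns and "hic_left" in cohort.data.columns:
        cols += ["hic_right", "hic_left"]
    else:
        cols += ["hic"]
    cols += [n for n in cohort.catalog
             if n in cohort.data.columns and n not in NON_CANDIDATE]
    return cols


def apply_exclusions(cohort: Cohort, required: list[str] | None = None
                     ) -> tuple[Cohort, pd.DataFrame]:
    """Complete-case filter emulating the participant flow.

    Removes every participant with a missing value in any required field and
    returns the retained cohort together with an exclusion log (one row per
    excluded participant with the offending fields).  Idempotent.
    """
    req = required if required is not None else required_columns(cohort)
    req = [c for c in req if c in cohort.data.columns]
    miss = cohort.data[req].isna()
    dropped = miss.any(axis=1)
    reasons = [
        "missing: " + ", ".join(miss.columns[row.values])
        for _, row in miss[dropped].iterrows()
    ]
    log = pd.DataFrame({"id": cohort.data.loc[dropped, "id"].values,
                        "reason": reasons})
    kept = cohort.data[~dropped]
    if kept.empty:
        warnings.warn("exclusion filter removed every participant")
    return Cohort(kept, cohort.catalog, validate=False), log


def append_classes(cohort: Cohort, config: ClassifierConfig = DEFAULT_CONFIG) -> Cohort:
    """Append iron-overload grade and steatosis class columns."""
    out = cohort.copy()
    df = out.data
    df["iron_overload"] = classify_iron_overload(df["hic"].to_numpy(float), config)
    if "hff" in df.columns:
        df["steatosis"] = classify_steatosis(df["hff"].to_numpy(float), config)
    return out
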