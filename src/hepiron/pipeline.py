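"""End-to-end orchestration: generate or load → exclude → stratify →
descriptives → stability selection (per variant) → GRS → follow-up
regressions, with one seeded generator stream split per stage and a
machine-readable run manifest.

Analysis variants
-----------------
``main``            the default candidate panel
``exclude_hff``     hepatic fat removed from the candidate set
``with_grs``        continuous genetic risk score appended to the panel
``ogtt_subsample``  participants with OGTT data only (no diagnosed
                    diabetes), 2h glucose/insulin added as candidates

Identical config + seed reproduce byte-identical result tables; the
manifest intentionally carries no timestamp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, append_classes, apply_exclusions
from .cohort import Cohort, VariablePanel, load_cohort
from .descriptives import build_table_one
from .grs import GRS_COLUMN, GeneticRiskScore, GenotypeMatrix
from .lasso import LassoConfig, StabilitySelection, build_design
from .regression import run_followup_table
from .simulate import (DEFAULT_SNP_PANEL, generate_cohort_and_genotypes,
                       inject_missingness, default_study_config)

VARIANTS = ("main", "exclude_hff", "with_grs", "ogtt_subsample")


@dataclass
class RunConfig:
    seed: int
    outdir: str
    generator: dict | None = None          # {'n_male':..,'n_female':..,'n_missing':..}
    inputs: dict | None = None             # {'cohort_csv':.., 'dosage_csv':..}
    lasso: dict = field(default_factory=dict)
    variants: tuple = ("main",)
    n_jobs: int = 1

    def __post_init__(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError("give exactly one of 'generator' or 'inputs'")
        bad = set(self.variants) - set(VARIANTS)
        if bad:
            raise ValueError(f"unknown variants: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["variants"] = tuple(doc.get("variants", ("main",)))
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _materialize(config: RunConfig):
    """Stage 1: generate or load the cohort (and genotypes if available)."""
    if config.generator is not None:
        g = dict(config.generator)
        gen = default_study_config(n_male=g.get("n_male", 206),
                               n_female=g.get("n_female", 147),
                               snp_panel=DEFAULT_SNP_PANEL
                               if "with_grs" in config.variants else ())
        cohort, genotypes = generate_cohort_and_genotypes(gen, seed=config.seed)
        n_missing = g.get("n_missing", 0)
        if n_missing:
            cohort = inject_missingness(cohort, n_missing, seed=config.seed)
        return cohort, genotypes
    inp = config.inputs
    cohort = load_cohort(inp["cohort_csv"])
    genotypes = None
    if inp.get("dosage_csv"):
        dos = pd.read_csv(inp["dosage_csv"], index_col=0)
        genotypes = GenotypeMatrix(dos)
    return cohort, genotypes


def _variant_inputs(variant: str, cohort: Cohort, grs_results):
    """Cohort/panel pair entering selection for one analysis variant."""
    if variant == "main":
        return cohort, VariablePanel.default(cohort.catalog)
    if variant == "exclude_hff":
        return cohort, VariablePanel.default(cohort.catalog, exclude=("hff",))
    if variant == "with_grs":
        if grs_results is None:
            raise ValueError("with_grs variant requires genotype data")
        scored = grs_results.append_to(cohort)
        return scored, VariablePanel.default(scored.catalog)
    if variant == "ogtt_subsample":
        mask = (cohort.data["diabetes_status"] != "diabetes") \
            & cohort.data["two_hour_glucose"].notna() \
            & cohort.data["two_hour_insulin"].notna()
        sub = Cohort(cohort.data[mask], cohort.catalog, validate=False)
        panel = VariablePanel(tuple(
            n for n in sub.catalog
            if n not in ("diabetes_status",)))
        return sub, panel
    raise ValueError(variant)


def _csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lasso_cfg = LassoConfig(**{**config.lasso, "seed": config.seed})
    outputs = []

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(name, exc) from exc

    cohort, genotypes = stage("materialize", _materialize, config)
    cohort, excl_log = stage("exclusions", apply_exclusions, cohort)
    cohort = stage("classification", append_classes, cohort)
    _csv(excl_log, outdir / "exclusions.csv")
    outputs.append("exclusions.csv")
    cohort.to_csv(outdir / "cohort.csv")
    outputs.append("cohort.csv")

    table1 = stage("descriptives", build_table_one, cohort)
    _csv(table1, outdir / "table1.csv")
    outputs.append("table1.csv")

    grs_results = None
    if genotypes is not None:
        keep = [i for i in genotypes.ids if i in set(cohort.data["id"])]
        genotypes = GenotypeMatrix(genotypes.dosages.loc[keep], genotypes.panel)
        grs_results = stage("grs", GeneticRiskScore(genotypes, cohort).fit)
        grs_results.weights.rename_axis("snp_id").reset_index().to_csv(
            outdir / "grs_weights.csv", index=False, float_format="%.10g")
        quart, tests = grs_results.quartile_contrast()
        contrast = quart.copy()
        for sex, tr in tests.items():
            contrast.loc[contrast["sex"] == sex, "q4_vs_q1_p"] = tr.p
        _csv(contrast, outdir / "grs_quartiles.csv")
        outputs += ["grs_weights.csv", "grs_quartiles.csv"]

    for variant in config.variants:
        suffix = "" if variant == "main" else f"_{variant}"
        vcohort, panel = stage(f"variant:{variant}", _variant_inputs,
                               variant, cohort, grs_results)
        male, female = vcohort.stratify_by_sex()
        for sex_name, stratum, table_name in (
                ("male", male, "table2"), ("female", female, "table3")):
            sel = stage(
                f"selection:{variant}:{sex_name}",
                lambda: StabilitySelection.from_cohort(
                    stratum, panel, config=lasso_cfg).fit(n_jobs=config.n_jobs))
            _csv(sel.to_frame(), outdir / f"inclusion_{sex_name}{suffix}.csv")
            outputs.append(f"inclusion_{sex_name}{suffix}.csv")
            selected = sel.select_relevant()
            if selected:
                table = stage(f"regression:{variant}:{sex_name}",
                              run_followup_table, stratum, selected)
            else:
                table = pd.DataFrame(columns=["variable", "adjustment", "beta",
                                              "ci_low", "ci_high", "p_value",
                                              "adj_r2", "n"])
            _csv(table, outdir / f"{table_name}{suffix}.csv")
            outputs.append(f"{table_name}{suffix}.csv")

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"hepiron": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n_after_exclusion": int(cohort.n),
        "n_excluded": int(len(excl_log)),
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
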