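"""Cohort assembly: inclusion/exclusion with an attrition log, index and
follow-up windows, outcome ascertainment, baseline covariates, and analysis
group assignment.

Design: a new-user opioid cohort.  The index date is 3 days after the first
opioid episode's start; follow-up runs from the index date to the earlier of
index + 60 days and the episode end.  The outcome is the first pain-coded ED
visit inside that window.  Baseline covariates are assessed over the 180
days before the index date.  Three analysis contrasts are carried per row:

A. phenoconverted IM/PM vs phenoconverted NM/UM (all persons);
B. inhibitor-exposed vs inhibitor-free, restricted to genotypic NMs;
C. genotypic IM/PM vs NM/UM, restricted to inhibitor-free persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import config

__all__ = ["CohortConfig", "build_cohort", "ascertain_outcome", "assign_groups"]


@dataclass
class CohortConfig:
    """Tunable conventions and code lists for cohort construction."""

    pain_codes: frozenset[str] = config.PAIN_ED_CODES
    cancer_codes: frozenset[str] = config.CANCER_CODES
    dx_code_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(config.DX_CODE_MAP)
    )
    med_history_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(config.MED_HISTORY_MAP)
    )
    index_lag_days: int = config.INDEX_LAG_DAYS
    followup_days: int = config.FOLLOWUP_DAYS
    baseline_days: int = config.BASELINE_DAYS
    min_supply_days: int = config.MIN_SUPPLY_DAYS
    washout_days: int = config.WASHOUT_DAYS
    min_overlap_days: int = config.MIN_OVERLAP_DAYS
    min_age: int = 18
    study_end: pd.Timestamp | None = None  # default: latest date seen in the data


def _days(delta: pd.Series) -> pd.Series:
    return delta.dt.days


def apply_inclusion_exclusion(
    demographics: pd.DataFrame,
    episodes: pd.DataFrame,
    encounters: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cfg: CohortConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the inclusion/exclusion cascade; returns the base cohort plus a
    per-rule attrition log (counts remaining after each filter)."""
    attrition: dict[str, int] = {"persons": len(demographics)}

    opioids = episodes.loc[episodes["drug_class"] == "opioid"].copy()
    # first episode per person; same-day ties break alphabetically by drug
    opioids = opioids.sort_values(["person_id", "start_date", "drug"], kind="stable")
    first = opioids.drop_duplicates("person_id").rename(
        columns={"start_date": "opioid_start", "end_date": "opioid_end", "drug": "opioid_drug"}
    )
    base = demographics.merge(
        first[["person_id", "opioid_drug", "opioid_start", "opioid_end"]],
        on="person_id",
        how="inner",
    )
    attrition["has_opioid_episode"] = len(base)

    base = base.loc[base["age"] >= cfg.min_age]
    attrition["age_18_or_older"] = len(base)

    supply = _days(base["opioid_end"] - base["opioid_start"]) + 1
    base = base.loc[supply >= cfg.min_supply_days].copy()
    attrition["opioid_supply_7_days"] = len(base)

    base["index_date"] = base["opioid_start"] + pd.Timedelta(days=cfg.index_lag_days)
    base["followup_end"] = np.minimum(
        base["index_date"] + pd.Timedelta(days=cfg.followup_days), base["opioid_end"]
    )

    pheno_cols = ["person_id", "diplotype", "genotype_activity_score", "phenotype"]
    base = base.merge(phenotypes[pheno_cols], on="person_id", how="left")
    base["phenotype"] = base["phenotype"].fillna("Indeterminate")
    base = base.loc[base["phenotype"] != "Indeterminate"].copy()
    attrition["determinate_genotype"] = len(base)

    cancer = encounters.loc[encounters["code"].isin(cfg.cancer_codes)]
    m = cancer.merge(base[["person_id", "index_date"]], on="person_id")
    lag = _days(m["index_date"] - m["date"])
    flagged = m.loc[(lag >= 1) & (lag <= cfg.baseline_days), "person_id"].unique()
    base = base.loc[~base["person_id"].isin(flagged)].copy()
    attrition["no_recent_cancer"] = len(base)

    return base.reset_index(drop=True), attrition


def _attach_inhibitor_status(
    base: pd.DataFrame, episodes: pd.DataFrame, cfg: CohortConfig, study_end: pd.Timestamp
) -> pd.DataFrame:
    """Concomitant inhibitor level over the follow-up window, plus the
    inhibitor-free flag (no inhibitor episode inside
    [opioid start - washout, study end])."""
    inh = episodes.loc[episodes["drug_class"] == "inhibitor"]
    m = inh.merge(
        base[["person_id", "opioid_start", "index_date", "followup_end"]],
        on="person_id",
    )
    out = base.copy()
    if len(m):
        overlap = (
            _days(np.minimum(m["end_date"], m["followup_end"])
                  - np.maximum(m["start_date"], m["index_date"])) + 1
        ).clip(lower=0)
        qualifying = overlap >= cfg.min_overlap_days
        strong = m.loc[qualifying & (m["inhibitor_strength"] == "strong"), "person_id"]
        moderate = m.loc[qualifying & (m["inhibitor_strength"] == "moderate"), "person_id"]
        touches = m.loc[
            (m["end_date"] >= m["opioid_start"] - pd.Timedelta(days=cfg.washout_days))
            & (m["start_date"] <= study_end),
            "person_id",
        ]
        out["inhibitor_level"] = np.select(
            [out["person_id"].isin(strong), out["person_id"].isin(moderate)],
            ["strong", "moderate"],
            default="none",
        )
        out["inhibitor_free"] = ~out["person_id"].isin(touches)
    else:
        out["inhibitor_level"] = "none"
        out["inhibitor_free"] = True
    return out


def _apply_phenoconversion(base: pd.DataFrame) -> pd.DataFrame:
    out = base.copy()
    factor = out["inhibitor_level"].map(config.INHIBITOR_FACTORS).astype(float)
    out["inhibitor_factor"] = factor
    adjusted = factor * out["genotype_activity_score"]
    out["adjusted_activity_score"] = adjusted
    thr = config.DEFAULT_THRESHOLDS
    cat = np.select(
        [adjusted > thr["nm_upper"], adjusted >= thr["nm_lower"], adjusted > 0],
        ["UM", "NM", "IM"],
        default="PM",
    )
    out["phenotype_pheno"] = np.char.add("p", cat.astype(str))
    return out


def ascertain_outcome(
    base: pd.DataFrame, encounters: pd.DataFrame, pain_codes: frozenset[str]
) -> pd.DataFrame:
    """Binary first-pain-ED-visit outcome within [index_date, followup_end].

    Only ED-setting encounters with a configured pain code count; the
    earliest qualifying date is recorded.
    """
    ed_pain = encounters.loc[
        (encounters["setting"] == "ED") & (encounters["code"].isin(pain_codes))
    ]
    m = ed_pain.merge(base[["person_id", "index_date", "followup_end"]], on="person_id")
    m = m.loc[(m["date"] >= m["index_date"]) & (m["date"] <= m["followup_end"])]
    first = m.groupby("person_id")["date"].min().rename("first_event_date")
    out = base.merge(first, on="person_id", how="left")
    out["outcome"] = out["first_event_date"].notna().astype(int)
    return out


def assemble_covariates(
    base: pd.DataFrame,
    encounters: pd.DataFrame,
    rx: pd.DataFrame,
    cfg: CohortConfig,
) -> pd.DataFrame:
    """Attach the 24 baseline characteristics.

    Diagnosis flags come from any-setting encounters in the 180 days before
    index; medication-history flags from prescription ingredients in the same
    window; prior ED visits is a count of baseline ED encounters.  Age, sex,
    race, and MME/day pass through from demographics.
    """
    out = base.copy()
    out["sex_female"] = (out["sex"] == "F").astype(int)

    windows = out[["person_id", "index_date"]]
    enc = encounters.merge(windows, on="person_id")
    lag = _days(enc["index_date"] - enc["date"])
    enc = enc.loc[(lag >= 1) & (lag <= cfg.baseline_days)]
    for flag, codes in cfg.dx_code_map.items():
        persons = enc.loc[enc["code"].isin(codes), "person_id"].unique()
        out[flag] = out["person_id"].isin(persons).astype(int)
    ed_counts = enc.loc[enc["setting"] == "ED"].groupby("person_id").size()
    out["prior_ed_visits"] = (
        out["person_id"].map(ed_counts).fillna(0).astype(int)
    )

    meds = rx.merge(windows, on="person_id")
    med_lag = _days(meds["index_date"] - meds["start_date"])
    meds = meds.loc[(med_lag >= 1) & (med_lag <= cfg.baseline_days)]
    drug_lower = meds["drug"].str.lower()
    for flag, names in cfg.med_history_map.items():
        persons = meds.loc[drug_lower.isin(names), "person_id"].unique()
        out[flag] = out["person_id"].isin(persons).astype(int)
    return out


def assign_groups(base: pd.DataFrame) -> pd.DataFrame:
    """Label the three analysis contrasts and the opioid subgroup.

    Every person lands in exactly one arm of analysis A; B is restricted to
    genotypic NMs and C to inhibitor-free persons.
    """
    out = base.copy()
    out["exposed_A"] = out["phenotype_pheno"].isin(["pIM", "pPM"]).astype(int)
    out["in_B"] = (out["phenotype"] == "NM").astype(int)
    out["exposed_B"] = (~out["inhibitor_free"]).astype(int)
    out["in_C"] = out["inhibitor_free"].astype(int)
    out["exposed_C"] = out["phenotype"].isin(["IM", "PM"]).astype(int)
    out["drug_subgroup"] = np.where(
        out["opioid_drug"].isin(["hydrocodone", "tramadol", "codeine"]),
        "HTC",
        "oxycodone",
    )
    return out


def build_cohort(
    phenotypes: pd.DataFrame,
    episodes: pd.DataFrame,
    encounters: pd.DataFrame,
    demographics: pd.DataFrame,
    rx: pd.DataFrame,
    cfg: CohortConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full cohort pipeline; returns (cohort table, attrition log).

    Inputs are the upstream tables: per-person consensus phenotypes
    (:func:`opioidpgx.phenotype.assign_phenotypes`), stitched exposure
    episodes (:func:`opioidpgx.exposure.stitch_table`), coded encounters
    (person_id, date, setting, code), demographics (person_id, age, sex,
    race, mme_per_day), and the raw prescription table (for
    medication-history covariates).
    """
    if cfg is None:
        cfg = CohortConfig()
    study_end = cfg.study_end
    if study_end is None:
        candidates = [encounters["date"].max(), episodes["end_date"].max()]
        study_end = max(c for c in candidates if pd.notna(c))

    base, attrition = apply_inclusion_exclusion(
        demographics, episodes, encounters, phenotypes, cfg
    )
    base = _attach_inhibitor_status(base, episodes, cfg, study_end)
    base = _apply_phenoconversion(base)
    base = ascertain_outcome(base, encounters, cfg.pain_codes)
    base = assemble_covariates(base, encounters, rx, cfg)
    base = assign_groups(base)
    return base, attrition
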