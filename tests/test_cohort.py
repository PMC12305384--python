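"""Inclusion/exclusion, follow-up windows, outcome, covariates, groups."""

import numpy as np
import pandas as pd
import pytest

from opioidpgx.cohort import build_cohort

from conftest import (
    empty_rx,
    make_demographics,
    make_encounters,
    make_episodes,
    make_phenotypes,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    """Nine hand-built persons exercising every filter and group rule.

    All opioid episodes run day 100-160 (index 103, follow-up end 160)
    except person 2 (6-day supply) and person 9 (days 200-260).
    """
    demographics = make_demographics(
        [
            (1, 17, "F", "White", 10.0),   # under 18 -> excluded
            (2, 50, "F", "White", 10.0),   # 6-day supply -> excluded
            (3, 50, "M", "Black", 10.0),   # NM, inhibitor-free
            (4, 50, "F", "Other", 10.0),   # NM + strong inhibitor -> pPM
            (5, 50, "F", "White", 10.0),   # genotypic PM, inhibitor-free
            (6, 50, "M", "White", 10.0),   # indeterminate genotype -> excluded
            (7, 50, "F", "White", 10.0),   # cancer at index-180 -> excluded
            (8, 50, "F", "White", 10.0),   # cancer at index-181 -> retained
            (9, 30, "M", "White", 10.0),   # outcome event in window
        ]
    )
    phenotypes = make_phenotypes(
        [
            (1, "*1/*1", 2.0, "NM"),
            (2, "*1/*1", 2.0, "NM"),
            (3, "*1/*1", 2.0, "NM"),
            (4, "*1/*1", 2.0, "NM"),
            (5, "*4/*4", 0.0, "PM"),
            (6, None, np.nan, "Indeterminate"),
            (7, "*1/*1", 2.0, "NM"),
            (8, "*1/*1", 2.0, "NM"),
            (9, "*1/*41", 1.5, "NM"),
        ]
    )
    op = [(p, "hydrocodone", "opioid", "not-applicable", 100, 160)
          for p in (1, 3, 4, 5, 6, 7, 8)]
    op.append((2, "hydrocodone", "opioid", "not-applicable", 100, 105))
    op.append((9, "tramadol", "opioid", "not-applicable", 200, 260))
    op.append((4, "fluoxetine", "inhibitor", "strong", 110, 130))
    episodes = make_episodes(op)
    encounters = make_encounters(
        [
            (7, 103 - 180, "other", "C50.9"),    # inside the 180-day window
            (8, 103 - 181, "other", "C50.9"),    # one day outside
            (9, 213, "ED", "R52"),               # outcome event at index+10
            (3, 110, "other", "R52"),            # pain code but not ED
            (5, 161, "ED", "R52"),               # one day past follow-up end
            (4, 73, "other", "F32.9"),           # depression at index-30
            (5, 108, "other", "F32.9"),          # depression post-index
            (3, 50, "ED", "Z00.00"),             # baseline ED visit
        ]
    )
    cohort, attrition = build_cohort(
        phenotypes, episodes, encounters, demographics, empty_rx()
    )
    return cohort.set_index("person_id"), attrition


class TestInclusionExclusion:
    def test_attrition_cascade(self, tiny_cohort):
        _, attrition = tiny_cohort
        assert attrition == {
            "persons": 9,
            "has_opioid_episode": 9,
            "age_18_or_older": 8,         # person 1 under 18
            "opioid_supply_7_days": 7,    # person 2 at 6 days
            "determinate_genotype": 6,    # person 6 indeterminate
            "no_recent_cancer": 5,        # person 7 cancer in window
        }
        counts = list(attrition.values())
        assert counts == sorted(counts, reverse=True)

    def test_cancer_window_boundary(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert 7 not in cohort.index
        assert 8 in cohort.index

    def test_index_and_followup_dates(self, tiny_cohort):
        cohort, _ = tiny_cohort
        epoch = pd.Timestamp("2018-01-01")
        assert cohort.loc[3, "index_date"] == epoch + pd.Timedelta(days=103)
        # follow-up capped by the episode end (day 160 < index + 60 = 163)
        assert cohort.loc[3, "followup_end"] == epoch + pd.Timedelta(days=160)
        assert cohort.loc[9, "followup_end"] == epoch + pd.Timedelta(days=260)


class TestOutcome:
    def test_ed_pain_visit_in_window_counts(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[9, "outcome"] == 1
        assert cohort.loc[9, "first_event_date"] == (
            pd.Timestamp("2018-01-01") + pd.Timedelta(days=213)
        )

    def test_non_ed_setting_does_not_count(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[3, "outcome"] == 0

    def test_event_past_followup_end_does_not_count(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[5, "outcome"] == 0


class TestCovariates:
    def test_baseline_dx_flag(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[4, "depression"] == 1
        assert cohort.loc[5, "depression"] == 0  # post-index code
        assert cohort.loc[3, "depression"] == 0

    def test_prior_ed_count_and_demographics(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[3, "prior_ed_visits"] == 1
        assert cohort.loc[4, "prior_ed_visits"] == 0
        assert cohort.loc[3, "sex_female"] == 0
        assert cohort.loc[4, "sex_female"] == 1


class TestGroups:
    def test_phenoconverted_nm_with_strong_inhibitor(self, tiny_cohort):
        cohort, _ = tiny_cohort
        row = cohort.loc[4]
        assert row["inhibitor_level"] == "strong"
        assert row["phenotype_pheno"] == "pPM"
        assert row["exposed_A"] == 1
        assert row["in_B"] == 1 and row["exposed_B"] == 1
        assert row["in_C"] == 0

    def test_genotypic_pm_without_inhibitor(self, tiny_cohort):
        cohort, _ = tiny_cohort
        row = cohort.loc[5]
        assert row["phenotype_pheno"] == "pPM"
        assert row["exposed_A"] == 1
        assert row["in_B"] == 0
        assert row["in_C"] == 1 and row["exposed_C"] == 1

    def test_unconverted_nm_is_comparison_everywhere(self, tiny_cohort):
        cohort, _ = tiny_cohort
        row = cohort.loc[3]
        assert row["phenotype_pheno"] == "pNM"
        assert row["exposed_A"] == 0
        assert row["in_B"] == 1 and row["exposed_B"] == 0
        assert row["in_C"] == 1 and row["exposed_C"] == 0

    def test_drug_subgroups(self, tiny_cohort):
        cohort, _ = tiny_cohort
        assert cohort.loc[3, "drug_subgroup"] == "HTC"
        assert cohort.loc[9, "drug_subgroup"] == "HTC"


class TestCohortProperties:
    def test_analysis_a_partitions_cohort(self, headline_small):
        _, result, _ = headline_small
        cohort = result.cohort
        n_exposed = int(cohort["exposed_A"].sum())
        n_comparison = int((1 - cohort["exposed_A"]).sum())
        assert n_exposed + n_comparison == len(cohort)
        assert cohort["phenotype_pheno"].isin(["pUM", "pNM", "pIM", "pPM"]).all()

    def test_b_and_c_restrictions_disjoint_from_exposures(self, headline_small):
        _, result, _ = headline_small
        cohort = result.cohort
        # B: only genotypic NMs; exposure there is inhibitor prescription
        b = cohort[cohort["in_B"] == 1]
        assert (b["phenotype"] == "NM").all()
        # C: only inhibitor-free persons; none of them phenoconvert
        c = cohort[cohort["in_C"] == 1]
        assert (c["inhibitor_level"] == "none").all()
        assert (c["phenotype_pheno"].str.lstrip("p") == c["phenotype"]).all()

    def test_attrition_counts_non_increasing(self, headline_small):
        _, result, _ = headline_small
        counts = list(result.attrition.values())
        assert counts == sorted(counts, reverse=True)

    def test_outcome_respects_window(self, headline_small):
        _, result, _ = headline_small
        cohort = result.cohort
        events = cohort[cohort["outcome"] == 1]
        assert (events["first_event_date"] >= events["index_date"]).all()
        assert (events["first_event_date"] <= events["followup_end"]).all()
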