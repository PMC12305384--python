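"""End-to-end orchestration: synthetic tables (or externally supplied ones)
through phenotyping, exposure-era construction, cohort assembly, and IPTW
analysis."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CohortConfig, build_cohort
from .exposure import stitch_table
from .iptw import AnalysisReport, run_analysis
from .phenotype import assign_phenotypes
from .simulate import ScenarioConfig, SimulatedData, generate, load_scenario

__all__ = ["PipelineResult", "run_pipeline", "run_scenario"]


@dataclass
class PipelineResult:
    phenotypes: pd.DataFrame
    episodes: pd.DataFrame
    cohort: pd.DataFrame
    attrition: dict[str, int]


def run_pipeline(
    calls: pd.DataFrame,
    rx: pd.DataFrame,
    encounters: pd.DataFrame,
    demographics: pd.DataFrame,
    cohort_config: CohortConfig | None = None,
) -> PipelineResult:
    """Raw tables -> analysis-ready cohort with attrition log."""
    phenotypes = assign_phenotypes(calls)
    episodes = stitch_table(rx)
    cohort, attrition = build_cohort(
        phenotypes, episodes, encounters, demographics, rx, cohort_config
    )
    return PipelineResult(phenotypes, episodes, cohort, attrition)


def run_scenario(
    scenario: str | ScenarioConfig,
    seed: int,
    analysis: str | None = "A",
    subgroup: str = "all",
    **overrides,
) -> tuple[SimulatedData, PipelineResult, AnalysisReport | None]:
    """Generate a scenario, run the pipeline, and optionally one analysis.

    ``scenario`` is a shipped scenario name, a YAML path, or a config object;
    ``overrides`` replace top-level scenario fields (e.g. ``n_persons=...``).
    """
    if isinstance(scenario, ScenarioConfig):
        cfg = scenario
    else:
        cfg = load_scenario(scenario, **overrides)
    data = generate(cfg, seed)
    result = run_pipeline(data.calls, data.rx, data.encounters, data.demographics)
    report = None
    if analysis is not None:
        report = run_analysis(result.cohort, analysis=analysis, subgroup=subgroup)
    return data, result, report
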