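"""Synthetic EHR/genotype generator with known ground truth.

Emulates the statistical structure of a person-level pharmacogenomic
pharmacoepidemiology dataset: multi-caller CYP2D6 diplotype reports (with
configurable per-tool error and no-call rates), opioid prescriptions with
refill gaps straddling the stitching boundary, CYP2D6 inhibitor courses
whose overlap with the opioid follow-up window spans the concomitancy
threshold, 24 baseline covariates (a configurable subset confounded with the
exposure class), and a binary pain-ED-visit outcome.

Outcome calibration: the outcome follows a logistic model
``logit p = alpha + tau*E + sum_j beta_j x_j`` whose intercept is solved so
the comparison arm's event rate matches the configured reference rate, and
whose exposure coefficient ``tau`` is solved by root-finding so that the
TRUE MARGINAL odds ratio — obtained by counterfactual standardization over
the simulated analysis population — equals the configured target.  Per-person
counterfactual probabilities are part of the returned ground truth, so
estimators can be checked against the exact estimand they target.

All calendar dates are integer day offsets from an arbitrary epoch,
materialized as timestamps only in the emitted tables.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import config
from .phenotype import StarAllele, assign_phenotypes

__all__ = [
    "ConfounderSpec",
    "ScenarioConfig",
    "SimulatedData",
    "load_scenario",
    "generate",
    "calibrate_outcome_model",
    "standardized_or",
    "mc_marginal_or",
    "simulate_core",
    "write_tables",
]

# Prevalences for non-confounded ("noise") baseline covariates; values follow
# the comparison-arm distribution of a large opioid-treated adult cohort.
NOISE_BINARY: dict[str, float] = {
    "back_pain": 0.129,
    "joint_pain": 0.254,
    "rheumatoid_arthritis": 0.226,
    "headache": 0.090,
    "neuropathic_pain": 0.115,
    "fibromyalgia": 0.012,
    "injury": 0.257,
    "depression": 0.130,
    "psychoses": 0.033,
    "anxiety": 0.113,
    "opioid_use_disorder": 0.011,
    "diabetes": 0.154,
    "kidney_failure": 0.059,
    "liver_disease": 0.054,
    "pain_medication": 0.546,
    "benzodiazepine": 0.301,
    "antipsychotic": 0.129,
    "cns_stimulant": 0.011,
    "muscle_relaxant": 0.202,
}
SEX_FEMALE_P = 0.665
RACE_LEVELS = ("Black", "White", "Other")
RACE_P = (0.189, 0.557, 0.254)
AGE_MEAN, AGE_SD = 51.2, 15.4
AGE_MIN, AGE_MAX = 18.0, 90.0
MME_LOG_MEAN, MME_LOG_SD = 3.2, 0.9
PRIOR_ED_LAMBDA = 0.32

_STRONG_DRUGS = sorted(config.STRONG_INHIBITORS)
_MODERATE_DRUGS = sorted(config.MODERATE_INHIBITORS)
_ED_GENERAL_CODE = "Z00.00"


@dataclass(frozen=True)
class ConfounderSpec:
    """One covariate whose distribution differs between exposure arms and
    which enters the outcome model with coefficient ``beta`` (logit scale)."""

    name: str
    kind: str  # "binary" | "normal"
    beta: float
    p_comparison: float = 0.0
    p_exposed: float = 0.0
    mean_comparison: float = 0.0
    mean_exposed: float = 0.0
    sd: float = 1.0


@dataclass
class ScenarioConfig:
    """Every knob of the generator; shipped YAML scenarios fill these in."""

    name: str = "custom"
    n_persons: int = 10_000
    # genotypes
    allele_frequencies: dict[str, float] = field(
        default_factory=lambda: {"*1": 0.55, "*4": 0.25, "*41": 0.15, "*10": 0.05}
    )
    n_callers: int = 4
    caller_error: float | Sequence[float] = 0.02
    caller_no_call: float | Sequence[float] = 0.05
    # opioid prescriptions
    opioid_mix: dict[str, float] = field(
        default_factory=lambda: {
            "hydrocodone": 0.45, "tramadol": 0.25, "oxycodone": 0.25, "codeine": 0.05
        }
    )
    n_rx_probs: Sequence[float] = (0.5, 0.3, 0.15, 0.05)
    quantities: Sequence[int] = (28, 56, 120, 12)
    quantity_probs: Sequence[float] = (0.55, 0.30, 0.13, 0.02)
    short_gap_prob: float = 0.8
    short_gap_range: tuple[int, int] = (0, 10)
    long_gap_range: tuple[int, int] = (14, 30)
    # inhibitors
    inhibitor_prob: float = 0.15
    strong_fraction: float = 0.6
    overlap_mix: dict[str, float] = field(
        default_factory=lambda: {"concomitant": 0.75, "short": 0.15, "washout_only": 0.10}
    )
    inhibitor_supply_range: tuple[int, int] = (30, 90)
    # outcome
    effect_basis: str = "phenoconversion"  # or "inhibitor"
    target_marginal_or: float = 1.19
    reference_event_rate: float = 0.018
    confounders: list[ConfounderSpec] = field(default_factory=list)
    # misc
    cancer_prob: float = 0.01
    distractor_prob: float = 0.05
    epoch: str = "2018-01-01"
    opioid_start_range: tuple[int, int] = (200, 560)
    study_end_offset: int = 1000

    def __post_init__(self) -> None:
        total = sum(self.allele_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        for probs, label in [
            (self.n_rx_probs, "n_rx_probs"),
            (self.quantity_probs, "quantity_probs"),
            (list(self.opioid_mix.values()), "opioid_mix"),
            (list(self.overlap_mix.values()), "overlap_mix"),
        ]:
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1")
        if self.effect_basis not in ("phenoconversion", "inhibitor"):
            raise ValueError(f"unknown effect_basis {self.effect_basis!r}")


@dataclass
class SimulatedData:
    """Generated tables plus per-person ground truth."""

    calls: pd.DataFrame
    rx: pd.DataFrame
    encounters: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    info: dict

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "calls": self.calls,
            "rx": self.rx,
            "encounters": self.encounters,
            "demographics": self.demographics,
        }


def _rates(value: float | Sequence[float], n_callers: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, float), (n_callers,)).copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("caller rates must lie in [0, 1]")
    return arr


def load_scenario(name_or_path: str | Path, **overrides) -> ScenarioConfig:
    """Load a shipped scenario by name ("headline", "confounded",
    "inhibitor_only") or any scenario YAML by path; keyword overrides replace
    top-level fields (e.g. ``n_persons=200_000``)."""
    path = Path(str(name_or_path))
    if path.suffix in (".yaml", ".yml") and path.exists():
        doc = config.load_yaml(path)
    else:
        resource = importlib.resources.files("opioidpgx.data") / f"{name_or_path}.yaml"
        doc = yaml.safe_load(resource.read_text())
    doc = dict(doc)
    conf = [ConfounderSpec(**c) for c in doc.pop("confounders", [])]
    for key in ("opioid_start_range", "short_gap_range", "long_gap_range",
                "inhibitor_supply_range"):
        if key in doc:
            doc[key] = tuple(doc[key])
    doc.update(overrides)
    return ScenarioConfig(confounders=conf, **doc)


# ---------------------------------------------------------------------------
# Stage 1: genotypes and caller reports
# ---------------------------------------------------------------------------

def simulate_genotypes(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> dict[str, object]:
    """Draw Hardy-Weinberg diplotypes and noisy multi-caller reports.

    Each pseudo-caller independently reports the true diplotype with
    probability 1 - error - no_call, a perturbed diplotype (one allele
    resampled from the pool) with probability error, and a no-call otherwise.
    """
    n = cfg.n_persons
    names = list(cfg.allele_frequencies)
    freqs = np.array([cfg.allele_frequencies[a] for a in names], float)
    keys = [StarAllele.parse(a) for a in names]
    values = np.array(
        [config.DEFAULT_ALLELE_ACTIVITY.get(k.name, np.nan) * k.copy_multiplier
         for k in keys]
    )
    order = sorted(range(len(keys)), key=lambda i: (keys[i].number, keys[i].copy_multiplier))
    sort_rank = np.empty(len(keys), np.int64)
    sort_rank[order] = np.arange(len(keys))

    def _canonical_pair(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        swap = sort_rank[a2] < sort_rank[a1]
        lo = np.where(swap, a2, a1)
        hi = np.where(swap, a1, a2)
        name_arr = np.array([str(k) for k in keys])
        return np.char.add(np.char.add(name_arr[lo], "/"), name_arr[hi])

    a1 = rng.choice(len(names), size=n, p=freqs)
    a2 = rng.choice(len(names), size=n, p=freqs)
    diplotype = _canonical_pair(a1, a2)
    geno_score = values[a1] + values[a2]

    err = _rates(cfg.caller_error, cfg.n_callers)
    nc = _rates(cfg.caller_no_call, cfg.n_callers)
    frames = []
    for c in range(cfg.n_callers):
        u = rng.random(n)
        is_nocall = u < nc[c]
        is_error = (~is_nocall) & (u < nc[c] + err[c])
        rep1, rep2 = a1.copy(), a2.copy()
        if is_error.any():
            idx = np.flatnonzero(is_error)
            new_allele = rng.choice(len(names), size=len(idx), p=freqs)
            which = rng.random(len(idx)) < 0.5
            rep1[idx[which]] = new_allele[which]
            rep2[idx[~which]] = new_allele[~which]
        call = _canonical_pair(rep1, rep2).astype(object)
        call[is_nocall] = pd.NA
        frames.append(
            pd.DataFrame(
                {"person_id": np.arange(n), "caller_id": f"caller_{c}", "diplotype": call}
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return {"calls": calls, "diplotype": diplotype, "genotype_score": geno_score}


# ---------------------------------------------------------------------------
# Stage 2: prescriptions (opioids + inhibitors)
# ---------------------------------------------------------------------------

def simulate_prescriptions(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> dict[str, object]:
    """Draw opioid courses (1-4 refills, gaps straddling the stitch boundary)
    and optional inhibitor courses placed relative to the follow-up window.

    Returns per-person truth for the first stitched opioid episode, the index
    and follow-up dates, and the concomitant inhibitor level.
    """
    n = cfg.n_persons
    K = len(cfg.n_rx_probs)
    drugs = sorted(cfg.opioid_mix)
    drug_idx = rng.choice(
        len(drugs), size=n, p=[cfg.opioid_mix[d] for d in drugs]
    )
    n_rx = rng.choice(np.arange(1, K + 1), size=n, p=list(cfg.n_rx_probs))
    qty = rng.choice(np.asarray(cfg.quantities), size=(n, K), p=list(cfg.quantity_probs))
    supply = np.ceil(qty / config.TABLETS_PER_DAY).astype(np.int64)
    s_lo, s_hi = cfg.short_gap_range
    l_lo, l_hi = cfg.long_gap_range
    gaps = np.where(
        rng.random((n, K - 1)) < cfg.short_gap_prob,
        rng.integers(s_lo, s_hi + 1, size=(n, K - 1)),
        rng.integers(l_lo, l_hi + 1, size=(n, K - 1)),
    )
    start = np.zeros((n, K), np.int64)
    end = np.zeros((n, K), np.int64)
    start[:, 0] = rng.integers(cfg.opioid_start_range[0], cfg.opioid_start_range[1] + 1, n)
    end[:, 0] = start[:, 0] + supply[:, 0] - 1
    for k in range(1, K):
        start[:, k] = end[:, k - 1] + 1 + gaps[:, k - 1]
        end[:, k] = start[:, k] + supply[:, k] - 1

    active = np.arange(K)[None, :] < n_rx[:, None]
    chain = np.ones(n, bool)
    ep_end = end[:, 0].copy()
    for k in range(1, K):
        in_ep = chain & active[:, k] & (gaps[:, k - 1] <= config.OPIOID_MAX_GAP_DAYS)
        ep_end = np.where(in_ep, end[:, k], ep_end)
        chain = in_ep
    ep_start = start[:, 0]

    index_day = ep_start + config.INDEX_LAG_DAYS
    fu_end = np.minimum(index_day + config.FOLLOWUP_DAYS, ep_end)
    window_len = np.maximum(fu_end - index_day + 1, 0)

    person = np.repeat(np.arange(n), K)[active.ravel()]
    rx_op = pd.DataFrame(
        {
            "person_id": person,
            "drug": np.array(drugs)[drug_idx].repeat(K)[active.ravel()],
            "drug_class": "opioid",
            "inhibitor_strength": "not-applicable",
            "start_day": start.ravel()[active.ravel()],
            "quantity": qty.ravel()[active.ravel()],
        }
    )

    # inhibitor course: placement category relative to the follow-up window
    has_inh = rng.random(n) < cfg.inhibitor_prob
    strong = rng.random(n) < cfg.strong_fraction
    cats = sorted(cfg.overlap_mix)  # concomitant, short, washout_only
    cat = rng.choice(len(cats), size=n, p=[cfg.overlap_mix[c] for c in cats])
    cat_name = np.array(cats, dtype=object)[cat]
    # demote when the follow-up window cannot host the intended overlap
    cat_name = np.where((cat_name == "concomitant") & (window_len < 3), "short", cat_name)
    cat_name = np.where((cat_name == "short") & (window_len < 1), "washout_only", cat_name)

    L = rng.integers(cfg.inhibitor_supply_range[0], cfg.inhibitor_supply_range[1] + 1, n)
    ov_target = np.zeros(n, np.int64)
    conc = cat_name == "concomitant"
    ov_target[conc] = rng.integers(3, window_len[conc] + 1)
    shrt = cat_name == "short"
    ov_target[shrt] = np.minimum(rng.integers(1, 3, size=int(shrt.sum())), window_len[shrt])
    inh_start = np.zeros(n, np.int64)
    inh_start[conc | shrt] = fu_end[conc | shrt] - ov_target[conc | shrt] + 1
    wash = cat_name == "washout_only"
    wash_end = ep_start[wash] - rng.integers(1, 121, size=int(wash.sum()))
    inh_start[wash] = wash_end - L[wash] + 1
    inh_end = inh_start + L - 1

    overlap = np.maximum(
        np.minimum(inh_end, fu_end) - np.maximum(inh_start, index_day) + 1, 0
    )
    overlap = np.where(has_inh & (window_len > 0), overlap, 0)
    concomitant = overlap >= config.MIN_OVERLAP_DAYS
    level = np.select(
        [has_inh & concomitant & strong, has_inh & concomitant & ~strong],
        ["strong", "moderate"],
        default="none",
    )

    strong_drug = rng.choice(_STRONG_DRUGS, size=n)
    mod_drug = rng.choice(_MODERATE_DRUGS, size=n)
    inh_drug = np.where(strong, strong_drug, mod_drug)
    idx = np.flatnonzero(has_inh)
    rx_inh = pd.DataFrame(
        {
            "person_id": idx,
            "drug": inh_drug[idx],
            "drug_class": "inhibitor",
            "inhibitor_strength": np.where(strong[idx], "strong", "moderate"),
            "start_day": inh_start[idx],
            "quantity": L[idx] * config.TABLETS_PER_DAY,
        }
    )

    return {
        "rx_opioid": rx_op,
        "rx_inhibitor": rx_inh,
        "opioid_drug": np.array(drugs)[drug_idx],
        "episode_start": ep_start,
        "episode_end": ep_end,
        "index_day": index_day,
        "followup_end": fu_end,
        "has_inhibitor": has_inh,
        "inhibitor_level": level,
        "supply_days": ep_end - ep_start + 1,
    }


# ---------------------------------------------------------------------------
# Outcome model calibration
# ---------------------------------------------------------------------------

def calibrate_outcome_model(
    eta0: np.ndarray,
    exposed: np.ndarray,
    target_or: float,
    reference_rate: float,
) -> tuple[float, float]:
    """Solve (alpha, tau) of ``logit p = alpha + tau*E + eta0``.

    ``alpha`` makes the comparison arm's mean event probability equal the
    reference rate; ``tau`` makes the counterfactually standardized marginal
    OR over the whole supplied population equal ``target_or``.
    """
    eta0 = np.asarray(eta0, float)
    e = np.asarray(exposed, bool)
    if not e.any() or e.all():
        raise ValueError("both exposure arms must be populated for calibration")

    def comp_rate(alpha: float) -> float:
        return float(np.mean(_expit(alpha + eta0[~e]))) - reference_rate

    alpha = brentq(comp_rate, -25.0, 5.0, xtol=1e-12)
    p0_bar = float(np.mean(_expit(alpha + eta0)))
    odds1 = target_or * p0_bar / (1 - p0_bar)
    p1_target = odds1 / (1 + odds1)
    if not 0 < p1_target < 1:
        raise ValueError("target marginal OR unattainable at this reference rate")

    def exp_rate(tau: float) -> float:
        return float(np.mean(_expit(alpha + tau + eta0))) - p1_target

    tau = brentq(exp_rate, -8.0, 8.0, xtol=1e-12)
    return float(alpha), float(tau)


def _expit(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def standardized_or(alpha: float, tau: float, eta0: np.ndarray) -> float:
    """Marginal OR by counterfactual standardization over a population."""
    p1 = float(np.mean(_expit(alpha + tau + eta0)))
    p0 = float(np.mean(_expit(alpha + eta0)))
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def mc_marginal_or(
    p1: np.ndarray,
    p0: np.ndarray,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo standardization oracle: resample persons, draw both
    counterfactual outcomes, return the OR of the counterfactual means."""
    if rng is None:
        rng = np.random.default_rng(0)
    idx = rng.integers(0, len(p1), size=n_draws)
    y1 = rng.random(n_draws) < np.asarray(p1)[idx]
    y0 = rng.random(n_draws) < np.asarray(p0)[idx]
    m1, m0 = y1.mean(), y0.mean()
    return float((m1 / (1 - m1)) / (m0 / (1 - m0)))


# ---------------------------------------------------------------------------
# Stage 3: covariates, outcomes, encounters
# ---------------------------------------------------------------------------

def _draw_covariates(
    n: int,
    exposed: np.ndarray,
    confounders: Sequence[ConfounderSpec],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """All 24 baseline characteristics; confounders conditional on the
    exposure class, the rest i.i.d. noise.  Returns the covariate table and
    the confounder contribution eta0 to the outcome linear predictor."""
    e = np.asarray(exposed, bool)
    cov: dict[str, np.ndarray] = {}
    cov["age"] = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), AGE_MIN, AGE_MAX)
    cov["sex_female"] = (rng.random(n) < SEX_FEMALE_P).astype(int)
    cov["race"] = rng.choice(RACE_LEVELS, size=n, p=RACE_P)
    for name, p in NOISE_BINARY.items():
        cov[name] = (rng.random(n) < p).astype(int)
    cov["mme_per_day"] = np.round(np.exp(rng.normal(MME_LOG_MEAN, MME_LOG_SD, n)), 1)
    cov["prior_ed_visits"] = rng.poisson(PRIOR_ED_LAMBDA, n)

    eta0 = np.zeros(n)
    for spec in confounders:
        if spec.kind == "binary":
            p = np.where(e, spec.p_exposed, spec.p_comparison)
            cov[spec.name] = (rng.random(n) < p).astype(int)
        elif spec.kind == "normal":
            if spec.name != "age":
                raise ValueError("normal confounders are supported for 'age' only")
            mean = np.where(e, spec.mean_exposed, spec.mean_comparison)
            cov["age"] = np.clip(rng.normal(mean, spec.sd, n), AGE_MIN, AGE_MAX)
        else:
            raise ValueError(f"unknown confounder kind {spec.kind!r}")
        eta0 = eta0 + spec.beta * np.asarray(cov[spec.name], float)
    return pd.DataFrame(cov), eta0


def simulate_outcomes(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    exposed: np.ndarray,
    included: np.ndarray,
    index_day: np.ndarray,
    followup_end: np.ndarray,
) -> dict[str, object]:
    """Draw covariates and calibrated outcomes; returns per-person outcome
    probabilities, realized events with dates, and the covariate table."""
    n = cfg.n_persons
    cov, eta0 = _draw_covariates(n, exposed, cfg.confounders, rng)
    inc = np.asarray(included, bool)
    alpha, tau = calibrate_outcome_model(
        eta0[inc], exposed[inc], cfg.target_marginal_or, cfg.reference_event_rate
    )
    p1 = _expit(alpha + tau + eta0)
    p0 = _expit(alpha + eta0)
    p = np.where(exposed, p1, p0)
    y = (rng.random(n) < p) & inc
    # event date uniform within the follow-up window
    span = np.maximum(followup_end - index_day, 0)
    event_day = index_day + rng.integers(0, span + 1)
    return {
        "covariates": cov,
        "eta0": eta0,
        "alpha": alpha,
        "tau": tau,
        "p1": p1,
        "p0": p0,
        "outcome": y,
        "event_day": np.where(y, event_day, -1),
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _encounters_from_state(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    cov: pd.DataFrame,
    cancer: np.ndarray,
    index_day: np.ndarray,
    followup_end: np.ndarray,
    outcome: np.ndarray,
    event_day: np.ndarray,
) -> pd.DataFrame:
    n = cfg.n_persons
    pain_codes = sorted(config.PAIN_ED_CODES)
    parts: list[pd.DataFrame] = []

    def add(person, day, setting, code):
        parts.append(
            pd.DataFrame(
                {"person_id": person, "day": day, "setting": setting, "code": code}
            )
        )

    # baseline diagnosis encounters for each positive flag
    for flag, codes in config.DX_CODE_MAP.items():
        idx = np.flatnonzero(cov[flag].to_numpy() == 1)
        if len(idx):
            days = index_day[idx] - rng.integers(1, config.BASELINE_DAYS + 1, len(idx))
            add(idx, days, "other", sorted(codes)[0])
    # prior ED visits (non-pain code)
    counts = cov["prior_ed_visits"].to_numpy()
    rep = np.repeat(np.arange(n), counts)
    if len(rep):
        days = index_day[rep] - rng.integers(1, config.BASELINE_DAYS + 1, len(rep))
        add(rep, days, "ED", _ED_GENERAL_CODE)
    # cancer exclusion codes
    cidx = np.flatnonzero(cancer)
    if len(cidx):
        days = index_day[cidx] - rng.integers(1, config.BASELINE_DAYS + 1, len(cidx))
        add(cidx, days, "other", sorted(config.CANCER_CODES)[0])
    # outcome events: pain code in the ED within follow-up
    oidx = np.flatnonzero(outcome)
    if len(oidx):
        codes = rng.choice(pain_codes, size=len(oidx))
        add(oidx, event_day[oidx], "ED", codes)
    # distractors: pain codes outside the ED, and ED pain after follow-up
    window_ok = followup_end >= index_day
    d1 = np.flatnonzero((rng.random(n) < cfg.distractor_prob) & window_ok)
    if len(d1):
        span = followup_end[d1] - index_day[d1]
        days = index_day[d1] + rng.integers(0, span + 1)
        add(d1, days, "other", rng.choice(pain_codes, size=len(d1)))
    d2 = np.flatnonzero(rng.random(n) < cfg.distractor_prob)
    if len(d2):
        days = followup_end[d2] + rng.integers(5, 81, len(d2))
        add(d2, days, "ED", rng.choice(pain_codes, size=len(d2)))

    enc = pd.concat(parts, ignore_index=True)
    return enc.sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)


def generate(cfg: ScenarioConfig, seed: int) -> SimulatedData:
    """Generate a full synthetic dataset for one scenario.

    Deterministic: the same config and seed give byte-identical tables.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_persons
    epoch = pd.Timestamp(cfg.epoch)

    geno = simulate_genotypes(cfg, rng)
    rxs = simulate_prescriptions(cfg, rng)

    # exposure class carrying the outcome effect
    factor = pd.Series(rxs["inhibitor_level"]).map(config.INHIBITOR_FACTORS).to_numpy()
    adjusted = factor * geno["genotype_score"]
    thr = config.DEFAULT_THRESHOLDS
    pheno_exposed = adjusted < thr["nm_lower"]  # phenoconverted IM or PM
    if cfg.effect_basis == "phenoconversion":
        exposed = pheno_exposed
    else:
        exposed = rxs["has_inhibitor"].copy()

    # inclusion, mirroring the cohort filters, so calibration targets the
    # analysis population the pipeline will actually assemble
    consensus = assign_phenotypes(geno["calls"])
    determinate = (
        consensus.set_index("person_id")["phenotype"]
        .reindex(np.arange(n))
        .ne("Indeterminate")
        .to_numpy()
    )
    cancer = rng.random(n) < cfg.cancer_prob
    included = (
        determinate
        & ~cancer
        & (rxs["supply_days"] >= config.MIN_SUPPLY_DAYS)
    )

    out = simulate_outcomes(
        cfg, rng, exposed, included, rxs["index_day"], rxs["followup_end"]
    )
    cov = out["covariates"]

    encounters = _encounters_from_state(
        cfg, rng, cov, cancer, rxs["index_day"], rxs["followup_end"],
        out["outcome"], out["event_day"],
    )

    # medication-history prescriptions for positive flags
    med_parts = [rxs["rx_opioid"], rxs["rx_inhibitor"]]
    for flag, names in config.MED_HISTORY_MAP.items():
        idx = np.flatnonzero(cov[flag].to_numpy() == 1)
        if len(idx):
            med_parts.append(
                pd.DataFrame(
                    {
                        "person_id": idx,
                        "drug": sorted(names)[0],
                        "drug_class": "other",
                        "inhibitor_strength": "not-applicable",
                        "start_day": rxs["index_day"][idx]
                        - rng.integers(1, config.BASELINE_DAYS + 1, len(idx)),
                        "quantity": 30,
                    }
                )
            )
    rx = pd.concat(med_parts, ignore_index=True)
    rx["start_date"] = epoch + pd.to_timedelta(rx.pop("start_day"), unit="D")
    rx = rx.sort_values(["person_id", "drug", "start_date"], kind="stable").reset_index(
        drop=True
    )

    encounters["date"] = epoch + pd.to_timedelta(encounters.pop("day"), unit="D")

    demographics = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": np.round(cov["age"].to_numpy(), 1),
            "sex": np.where(cov["sex_female"].to_numpy() == 1, "F", "M"),
            "race": cov["race"].to_numpy(),
            "mme_per_day": cov["mme_per_day"].to_numpy(),
        }
    )
    # the cohort builder reads age back from demographics; keep truth aligned
    cov = cov.assign(age=demographics["age"].to_numpy())

    truth = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "diplotype": geno["diplotype"],
            "genotype_score": geno["genotype_score"],
            "inhibitor_level": rxs["inhibitor_level"],
            "inhibitor_factor": factor,
            "adjusted_score": adjusted,
            "has_inhibitor": rxs["has_inhibitor"],
            "exposed": exposed,
            "included": included,
            "cancer": cancer,
            "index_day": rxs["index_day"],
            "followup_end": rxs["followup_end"],
            "p1": out["p1"],
            "p0": out["p0"],
            "outcome": out["outcome"].astype(int),
        }
    )
    inc = included
    info = {
        "scenario": cfg.name,
        "seed": int(seed),
        "alpha": out["alpha"],
        "tau": out["tau"],
        "target_marginal_or": cfg.target_marginal_or,
        "achieved_marginal_or": standardized_or(
            out["alpha"], out["tau"], out["eta0"][inc]
        ),
        "reference_event_rate": cfg.reference_event_rate,
        "n_included": int(inc.sum()),
        "n_exposed_included": int((exposed & inc).sum()),
    }
    return SimulatedData(
        calls=geno["calls"],
        rx=rx,
        encounters=encounters,
        demographics=demographics,
        truth=truth,
        info=info,
    )


def simulate_core(
    n: int,
    p_exposed: float,
    confounders: Sequence[ConfounderSpec],
    target_or: float,
    reference_rate: float,
    rng: np.random.Generator,
    coefficients: tuple[float, float] | None = None,
) -> dict[str, object]:
    """Statistical core without the EHR plumbing: draw (X, E, Y) from the
    confounded outcome model.  Useful for repeated-replicate studies (e.g.
    CI coverage) where table emission would dominate the cost.

    When ``coefficients`` (alpha, tau) is given, the outcome model is fixed
    rather than recalibrated, so replicates share a common superpopulation
    truth.
    """
    exposed = rng.random(n) < p_exposed
    cov, eta0 = _draw_covariates(n, exposed, confounders, rng)
    if coefficients is None:
        alpha, tau = calibrate_outcome_model(eta0, exposed, target_or, reference_rate)
    else:
        alpha, tau = coefficients
    p = _expit(alpha + tau * exposed + eta0)
    y = rng.random(n) < p
    return {
        "covariates": cov,
        "exposed": exposed.astype(int),
        "outcome": y.astype(int),
        "eta0": eta0,
        "alpha": alpha,
        "tau": tau,
        "marginal_or": standardized_or(alpha, tau, eta0),
    }


def write_tables(data: SimulatedData, outdir: str | Path) -> None:
    """Write calls.csv, rx.csv, encounters.csv, demographics.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.calls.to_csv(outdir / "calls.csv", index=False)
    data.rx.to_csv(outdir / "rx.csv", index=False)
    data.encounters.to_csv(outdir / "encounters.csv", index=False)
    data.demographics.to_csv(outdir / "demographics.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data.info, fh, indent=2)
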