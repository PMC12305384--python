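"""Shipped configuration defaults.

Everything a deployment would want to swap without touching code lives here:
the CYP2D6 allele activity table, metabolizer phenotype cut-points, FDA
inhibitor drug lists, stitching/washout day conventions, and the (synthetic,
illustrative) diagnosis-code vocabularies used by the cohort builder.  All of
it can be overridden from YAML via :func:`load_yaml`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

DATA_DIR = Path(__file__).parent / "data"

# ---------------------------------------------------------------------------
# CYP2D6 activity scoring (CPIC-style defaults)
# ---------------------------------------------------------------------------

#: Activity value per star allele (one gene copy).  Functional alleles score 1,
#: reduced-function 0.5 (*10: 0.25), non-functional 0.  Duplications ("*1x2")
#: multiply the base value by the copy number.
DEFAULT_ALLELE_ACTIVITY: dict[str, float] = {
    "*1": 1.0,
    "*2": 1.0,
    "*35": 1.0,
    "*9": 0.5,
    "*17": 0.5,
    "*29": 0.5,
    "*41": 0.5,
    "*10": 0.25,
    "*3": 0.0,
    "*4": 0.0,
    "*5": 0.0,
    "*6": 0.0,
    "*7": 0.0,
    "*8": 0.0,
    "*11": 0.0,
    "*15": 0.0,
}

#: Metabolizer categories from the diplotype activity score:
#: UM > 2.25;  NM in [1.25, 2.25];  IM in (0, 1.25);  PM == 0.
DEFAULT_THRESHOLDS: dict[str, float] = {"nm_lower": 1.25, "nm_upper": 2.25}

#: Multiplicative inhibitor factor applied to the genotype activity score.
INHIBITOR_FACTORS: dict[str, float] = {"none": 1.0, "moderate": 0.5, "strong": 0.0}

#: FDA-classified CYP2D6 inhibitors (ingredient level, lower case).
STRONG_INHIBITORS: frozenset[str] = frozenset(
    {"bupropion", "fluoxetine", "paroxetine", "terbinafine", "quinidine"}
)
MODERATE_INHIBITORS: frozenset[str] = frozenset(
    {"abiraterone", "cinacalcet", "mirabegron", "duloxetine", "lorcaserin", "rolapitant"}
)

#: CYP2D6-metabolized opioids under study.
OPIOIDS: frozenset[str] = frozenset({"hydrocodone", "tramadol", "codeine", "oxycodone"})

# ---------------------------------------------------------------------------
# Day-count conventions (intervals inclusive of both endpoints)
# ---------------------------------------------------------------------------

TABLETS_PER_DAY = 4          # imputed daily consumption; days-supply = ceil(qty / 4)
OPIOID_MAX_GAP_DAYS = 13     # merge opioid refills when the gap is under 14 days
INHIBITOR_MAX_GAP_DAYS = 3   # merge inhibitor refills when the gap is at most 3 days
MIN_OVERLAP_DAYS = 3         # minimum consecutive opioid-inhibitor overlap
WASHOUT_DAYS = 180           # inhibitor-free look-back from the opioid start
INDEX_LAG_DAYS = 3           # index date = opioid start + 3 days
FOLLOWUP_DAYS = 60           # follow-up ends at index + 60 days or episode end
BASELINE_DAYS = 180          # covariate assessment window before the index date
MIN_SUPPLY_DAYS = 7          # inclusion: first opioid episode must supply >= 7 days
MIN_CONSENSUS_TOOLS = 2      # consensus requires a call from at least 2 tools

# ---------------------------------------------------------------------------
# Code vocabularies (synthetic, illustrative ICD-10-like defaults)
# ---------------------------------------------------------------------------

#: Pain-related diagnosis codes counted as the outcome when seen in the ED.
PAIN_ED_CODES: frozenset[str] = frozenset(
    {"R52", "M54.5", "M25.50", "R51", "G89.29", "M79.1"}
)

#: Cancer diagnosis codes triggering the 6-month pre-index exclusion.
CANCER_CODES: frozenset[str] = frozenset({"C50.9", "C34.90", "C18.9", "C61", "C91.10"})

#: Baseline diagnosis flags (Table-2-style) -> code sets.
DX_CODE_MAP: dict[str, frozenset[str]] = {
    "back_pain": frozenset({"M54.5", "M54.9"}),
    "joint_pain": frozenset({"M25.50", "M79.6"}),
    "rheumatoid_arthritis": frozenset({"M06.9"}),
    "headache": frozenset({"R51", "G43.909"}),
    "neuropathic_pain": frozenset({"G89.4", "G62.9"}),
    "fibromyalgia": frozenset({"M79.7"}),
    "injury": frozenset({"T14.90"}),
    "depression": frozenset({"F32.9", "F33.9"}),
    "psychoses": frozenset({"F29"}),
    "anxiety": frozenset({"F41.9", "F41.1"}),
    "opioid_use_disorder": frozenset({"F11.20"}),
    "diabetes": frozenset({"E11.9"}),
    "kidney_failure": frozenset({"N18.9"}),
    "liver_disease": frozenset({"K76.9"}),
}

#: Baseline medication-history flags -> ingredient sets (lower case).
MED_HISTORY_MAP: dict[str, frozenset[str]] = {
    "pain_medication": frozenset({"acetaminophen", "ibuprofen", "naproxen"}),
    "benzodiazepine": frozenset({"diazepam", "alprazolam", "lorazepam"}),
    "antipsychotic": frozenset({"quetiapine", "risperidone"}),
    "cns_stimulant": frozenset({"methylphenidate", "amphetamine"}),
    "muscle_relaxant": frozenset({"cyclobenzaprine", "methocarbamol"}),
}

#: The 24 baseline characteristics entered in the propensity model (race is one
#: characteristic, expanded to two indicator columns in the design matrix).
COVARIATE_COLUMNS: list[str] = [
    "age",
    "sex_female",
    "race",
    "back_pain",
    "joint_pain",
    "rheumatoid_arthritis",
    "headache",
    "neuropathic_pain",
    "fibromyalgia",
    "injury",
    "depression",
    "psychoses",
    "anxiety",
    "opioid_use_disorder",
    "diabetes",
    "kidney_failure",
    "liver_disease",
    "pain_medication",
    "benzodiazepine",
    "antipsychotic",
    "cns_stimulant",
    "muscle_relaxant",
    "mme_per_day",
    "prior_ed_visits",
]

NO_CALL_TOKENS: frozenset[str] = frozenset({"", "na", "nan", "none", "no-call", "no call", "nocall"})


def classify_inhibitor(drug: str) -> str:
    """Return 'strong', 'moderate', or 'not-applicable' for an ingredient name."""
    name = drug.strip().lower()
    if name in STRONG_INHIBITORS:
        return "strong"
    if name in MODERATE_INHIBITORS:
        return "moderate"
    return "not-applicable"


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load a YAML configuration document into a plain dict."""
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"expected a mapping at the top level of {path}")
    return out


def load_allele_table(path: str | Path) -> dict[str, float]:
    """Load an allele -> activity mapping from YAML (key ``alleles`` or flat)."""
    doc = load_yaml(path)
    table = doc.get("alleles", doc)
    return {str(k): float(v) for k, v in table.items()}
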