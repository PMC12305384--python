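"""CYP2D6 star-allele scoring, consensus diplotype calling, and phenotype
assignment with inhibitor-mediated phenoconversion.

The activity-score system assigns each star allele a numeric activity value
(functional 1, reduced-function 0.5 or 0.25, non-functional 0); a diplotype's
genotype activity score is the sum over its two alleles, with gene
duplications ("*1x2") contributing copy-number times the base value.  The
score maps to a metabolizer category (UM/NM/IM/PM), and a concomitant CYP2D6
inhibitor rescales the score by a factor (strong 0, moderate 0.5) before the
category is read off — the phenoconverted ("p"-prefixed) phenotype.

Consensus calling: multiple haplotype callers report a diplotype per person;
the consensus is the diplotype reported by at least two tools that is also a
strict majority of the tools that produced a call, else Indeterminate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "StarAllele",
    "Diplotype",
    "CallerReport",
    "PhenotypeResult",
    "UnknownAlleleError",
    "allele_activity",
    "diplotype_activity_score",
    "phenotype_from_score",
    "phenoconvert",
    "consensus_diplotype",
    "assign_phenotypes",
    "PHENOTYPE_ORDER",
]

#: Category order by increasing metabolic capacity.
PHENOTYPE_ORDER: dict[str, int] = {"PM": 0, "IM": 1, "NM": 2, "UM": 3}

INDETERMINATE = "Indeterminate"

_ALLELE_RE = re.compile(r"^\*(\d+)(?:x(\d+))?$")


class UnknownAlleleError(KeyError):
    """Raised when a star allele has no entry in the activity table."""

    def __init__(self, allele: str):
        super().__init__(allele)
        self.allele = allele

    def __str__(self) -> str:  # KeyError quotes its arg; give a real message
        return f"star allele {self.allele!r} is not in the activity table"


@dataclass(frozen=True, order=True)
class StarAllele:
    """A CYP2D6 star allele, e.g. ``*4`` or the duplication ``*1x2``.

    Ordering is by numeric allele id, then copy number, which defines the
    canonical within-diplotype ordering.
    """

    number: int
    copy_multiplier: int = 1

    def __post_init__(self) -> None:
        if self.number < 0 or self.copy_multiplier < 1:
            raise ValueError(f"invalid star allele {self}")

    @property
    def name(self) -> str:
        """Base allele label without the duplication suffix."""
        return f"*{self.number}"

    @classmethod
    def parse(cls, text: str) -> "StarAllele":
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse star allele {text!r}")
        return cls(int(m.group(1)), int(m.group(2)) if m.group(2) else 1)

    def __str__(self) -> str:
        if self.copy_multiplier > 1:
            return f"*{self.number}x{self.copy_multiplier}"
        return f"*{self.number}"


@dataclass(frozen=True)
class Diplotype:
    """A pair of star alleles, stored in canonical order so that ``*4/*1``
    and ``*1/*4`` compare (and hash) equal."""

    allele_1: StarAllele
    allele_2: StarAllele

    def __post_init__(self) -> None:
        if self.allele_2 < self.allele_1:
            a1, a2 = self.allele_2, self.allele_1
            object.__setattr__(self, "allele_1", a1)
            object.__setattr__(self, "allele_2", a2)

    @classmethod
    def parse(cls, text: str) -> "Diplotype":
        parts = text.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse diplotype {text!r}")
        return cls(StarAllele.parse(parts[0]), StarAllele.parse(parts[1]))

    def __str__(self) -> str:
        return f"{self.allele_1}/{self.allele_2}"


@dataclass(frozen=True)
class CallerReport:
    """One haplotype caller's verdict for one person; ``call`` is None for a
    no-call."""

    caller_id: str
    call: Diplotype | None


@dataclass(frozen=True)
class PhenotypeResult:
    """Genotype score, inhibitor factor, and the resulting (possibly
    phenoconverted) metabolizer category."""

    genotype_activity_score: float
    inhibitor_factor: float
    adjusted_activity_score: float
    phenotype: str


def allele_activity(
    allele: StarAllele | str,
    allele_table: Mapping[str, float] | None = None,
) -> float:
    """Activity value of one allele: table value times the copy multiplier.

    Raises :class:`UnknownAlleleError` for alleles absent from the table;
    callers may catch it to report an Indeterminate phenotype.
    """
    if allele_table is None:
        allele_table = config.DEFAULT_ALLELE_ACTIVITY
    if isinstance(allele, str):
        allele = StarAllele.parse(allele)
    try:
        base = allele_table[allele.name]
    except KeyError:
        raise UnknownAlleleError(str(allele)) from None
    return base * allele.copy_multiplier


def diplotype_activity_score(
    diplotype: Diplotype | str,
    allele_table: Mapping[str, float] | None = None,
) -> float:
    """Genotype activity score: the sum of the two allele activity values."""
    if isinstance(diplotype, str):
        diplotype = Diplotype.parse(diplotype)
    return allele_activity(diplotype.allele_1, allele_table) + allele_activity(
        diplotype.allele_2, allele_table
    )


def phenotype_from_score(
    score: float, thresholds: Mapping[str, float] | None = None
) -> str:
    """Map an activity score to UM/NM/IM/PM.

    Boundaries follow the printed inequalities: UM strictly above the upper
    cut (2.25); NM inclusive between the cuts; IM strictly between 0 and the
    lower cut (1.25); PM exactly 0.
    """
    if thresholds is None:
        thresholds = config.DEFAULT_THRESHOLDS
    if score < 0:
        raise ValueError(f"activity score must be nonnegative, got {score}")
    if score > thresholds["nm_upper"]:
        return "UM"
    if score >= thresholds["nm_lower"]:
        return "NM"
    if score > 0:
        return "IM"
    return "PM"


def phenoconvert(
    genotype_score: float,
    level: str,
    factors: Mapping[str, float] | None = None,
    thresholds: Mapping[str, float] | None = None,
) -> PhenotypeResult:
    """Apply inhibitor-mediated phenoconversion to a genotype activity score.

    The adjusted score is ``inhibitor factor x genotype score`` (factor 1 for
    no inhibitor, 0.5 for a moderate inhibitor, 0 for a strong inhibitor) and
    the phenotype is read from the adjusted score.
    """
    if factors is None:
        factors = config.INHIBITOR_FACTORS
    if level not in factors:
        raise ValueError(f"unknown inhibitor level {level!r}")
    factor = factors[level]
    adjusted = factor * genotype_score
    return PhenotypeResult(
        genotype_activity_score=genotype_score,
        inhibitor_factor=factor,
        adjusted_activity_score=adjusted,
        phenotype=phenotype_from_score(adjusted, thresholds),
    )


def consensus_diplotype(
    reports: Iterable[CallerReport],
    min_tools: int = config.MIN_CONSENSUS_TOOLS,
) -> Diplotype | None:
    """Majority-vote consensus across haplotype callers.

    Let V be the reports with a non-missing call.  The consensus is the
    canonical diplotype that is (i) reported by at least ``min_tools`` tools
    and (ii) a strict majority of V; otherwise None (Indeterminate).  A 2-2
    split is therefore Indeterminate.  The result does not depend on report
    order or on within-diplotype allele order.
    """
    reports = list(reports)
    ids = [r.caller_id for r in reports]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate caller_id in report set")
    calls = [r.call for r in reports if r.call is not None]
    if not calls:
        return None
    counts: dict[Diplotype, int] = {}
    for c in calls:
        counts[c] = counts.get(c, 0) + 1
    best, n_best = max(counts.items(), key=lambda kv: kv[1])
    if n_best >= min_tools and 2 * n_best > len(calls):
        return best
    return None


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

def _canonicalize_calls(raw: pd.Series) -> pd.Series:
    """Map raw diplotype strings to canonical form; no-calls become NA."""
    out: dict[str, object] = {}
    for text in raw.dropna().unique():
        if str(text).strip().lower() in config.NO_CALL_TOKENS:
            out[text] = pd.NA
        else:
            out[text] = str(Diplotype.parse(str(text)))
    return raw.map(out)


def assign_phenotypes(
    calls: pd.DataFrame,
    allele_table: Mapping[str, float] | None = None,
    thresholds: Mapping[str, float] | None = None,
    min_tools: int = config.MIN_CONSENSUS_TOOLS,
) -> pd.DataFrame:
    """Consensus diplotype, activity score, and genotype phenotype per person.

    Parameters
    ----------
    calls
        Long table with columns ``person_id``, ``caller_id``, ``diplotype``
        (strings such as ``"*1/*4"``; no-calls as NA/"NA").

    Returns
    -------
    DataFrame with columns ``person_id``, ``diplotype`` (canonical string or
    NA), ``genotype_activity_score`` (NaN when unresolvable) and
    ``phenotype`` (UM/NM/IM/PM or Indeterminate).  A person is Indeterminate
    when no consensus exists or when the consensus contains an allele missing
    from the activity table.
    """
    if allele_table is None:
        allele_table = config.DEFAULT_ALLELE_ACTIVITY
    required = {"person_id", "caller_id", "diplotype"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls table must have columns {sorted(required)}")
    dup = calls.duplicated(subset=["person_id", "caller_id"])
    if dup.any():
        raise ValueError("duplicate caller_id within a person's report set")

    df = calls[["person_id", "diplotype"]].copy()
    df["canon"] = _canonicalize_calls(df["diplotype"].astype("object"))
    valid = df.dropna(subset=["canon"])

    n_calls = valid.groupby("person_id").size()
    votes = (
        valid.groupby(["person_id", "canon"]).size().rename("votes").reset_index()
    )
    # strict majority is unique, so the per-person max vote identifies it
    votes = votes.sort_values(["person_id", "votes"], kind="stable")
    top = votes.groupby("person_id").tail(1).set_index("person_id")
    top["n_calls"] = n_calls
    ok = (top["votes"] >= min_tools) & (2 * top["votes"] > top["n_calls"])
    consensus = top.loc[ok, "canon"]

    # score each distinct consensus diplotype once
    def _score(text: str) -> float:
        try:
            return diplotype_activity_score(text, allele_table)
        except UnknownAlleleError:
            return float("nan")

    score_map = {t: _score(t) for t in consensus.unique()}

    persons = calls["person_id"].drop_duplicates()
    out = pd.DataFrame({"person_id": persons})
    out["diplotype"] = out["person_id"].map(consensus)
    out["genotype_activity_score"] = out["diplotype"].map(score_map).astype(float)
    score = out["genotype_activity_score"]
    if thresholds is None:
        thresholds = config.DEFAULT_THRESHOLDS
    out["phenotype"] = np.select(
        [
            score.isna(),
            score > thresholds["nm_upper"],
            score >= thresholds["nm_lower"],
            score > 0,
            score == 0,
        ],
        [INDETERMINATE, "UM", "NM", "IM", "PM"],
        default=INDETERMINATE,
    )
    return out.reset_index(drop=True)
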