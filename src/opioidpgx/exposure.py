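"""Prescription-era construction: end-date imputation, refill stitching,
opioid-inhibitor concomitancy, and washout checks.

EHR prescription rows carry only a start date and a dispensed quantity; the
end date is imputed from an assumed 4-tablets-a-day regimen (days-supply =
ceil(quantity / 4), with the interval inclusive of the start day).  Refills
of the same drug are stitched into exposure episodes when the gap between
one prescription's imputed end and the next start is small: under 14 days
for opioids, at most 3 days for CYP2D6 inhibitors.  All intervals are
inclusive of both endpoints; the gap between consecutive prescriptions is
``next.start - prev.end - 1`` days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import config

__all__ = [
    "PrescriptionRecord",
    "ExposureEpisode",
    "ConcomitancyResult",
    "impute_end_date",
    "stitch_episodes",
    "stitch_table",
    "concomitant_level",
    "inhibitor_free",
    "select_first_opioid",
]


@dataclass(frozen=True)
class PrescriptionRecord:
    person_id: object
    drug: str
    drug_class: str  # opioid | inhibitor | other
    start_date: date
    quantity: int
    inhibitor_strength: str = "not-applicable"


@dataclass(frozen=True)
class ExposureEpisode:
    """A stitched, dated drug-exposure interval (inclusive endpoints)."""

    person_id: object
    drug: str
    drug_class: str
    start_date: date
    end_date: date
    source_count: int
    inhibitor_strength: str = "not-applicable"

    @property
    def supply_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class ConcomitancyResult:
    """Best qualifying opioid-inhibitor overlap and the resulting level."""

    overlap_days: int
    level: str  # none | moderate | strong


def impute_end_date(
    start_date: date, quantity: int, tablets_per_day: int = config.TABLETS_PER_DAY
) -> date:
    """Imputed last covered day: start + ceil(quantity / tablets_per_day) - 1."""
    if quantity < 1:
        raise ValueError(f"quantity must be a positive tablet count, got {quantity}")
    supply = math.ceil(quantity / tablets_per_day)
    return start_date + timedelta(days=supply - 1)


def _default_gap(drug_class: str) -> int:
    return (
        config.INHIBITOR_MAX_GAP_DAYS
        if drug_class == "inhibitor"
        else config.OPIOID_MAX_GAP_DAYS
    )


def stitch_episodes(
    records: Sequence[PrescriptionRecord],
    max_gap_days: int | None = None,
    tablets_per_day: int = config.TABLETS_PER_DAY,
) -> list[ExposureEpisode]:
    """Merge one person's prescriptions of one drug into exposure episodes.

    Two consecutive prescriptions merge when the gap between the earlier
    imputed end and the later start is at most ``max_gap_days`` (default 13
    for opioids — "fewer than 14 days" — and 3 for inhibitors).  The episode
    end is the latest imputed end among its constituents.
    """
    if not records:
        return []
    persons = {r.person_id for r in records}
    drugs = {r.drug for r in records}
    if len(persons) > 1 or len(drugs) > 1:
        raise ValueError("stitch_episodes expects records for a single person and drug")
    first = records[0]
    if max_gap_days is None:
        max_gap_days = _default_gap(first.drug_class)

    intervals = sorted(
        (r.start_date, impute_end_date(r.start_date, r.quantity, tablets_per_day))
        for r in records
    )
    episodes: list[ExposureEpisode] = []
    cur_start, cur_end, count = intervals[0][0], intervals[0][1], 1
    for s, e in intervals[1:]:
        gap = (s - cur_end).days - 1
        if gap <= max_gap_days:
            cur_end = max(cur_end, e)
            count += 1
        else:
            episodes.append(
                ExposureEpisode(
                    first.person_id, first.drug, first.drug_class,
                    cur_start, cur_end, count, first.inhibitor_strength,
                )
            )
            cur_start, cur_end, count = s, e, 1
    episodes.append(
        ExposureEpisode(
            first.person_id, first.drug, first.drug_class,
            cur_start, cur_end, count, first.inhibitor_strength,
        )
    )
    return episodes


def stitch_table(
    rx: pd.DataFrame,
    gap_by_class: dict[str, int] | None = None,
    tablets_per_day: int = config.TABLETS_PER_DAY,
) -> pd.DataFrame:
    """Vectorized stitching for a whole prescription table.

    Parameters
    ----------
    rx
        Columns ``person_id``, ``drug``, ``drug_class``, ``start_date``
        (datetime64), ``quantity``; optional ``inhibitor_strength``.

    Returns
    -------
    Episode table with ``start_date``, ``end_date``, ``source_count`` per
    person/drug episode.  Equivalent to applying :func:`stitch_episodes`
    per person and drug.
    """
    if gap_by_class is None:
        gap_by_class = {
            "opioid": config.OPIOID_MAX_GAP_DAYS,
            "inhibitor": config.INHIBITOR_MAX_GAP_DAYS,
            "other": config.OPIOID_MAX_GAP_DAYS,
        }
    df = rx.copy()
    if (df["quantity"] < 1).any():
        raise ValueError("quantities must be positive tablet counts")
    supply = np.ceil(df["quantity"].to_numpy(float) / tablets_per_day).astype(int)
    df["end_date"] = df["start_date"] + pd.to_timedelta(supply - 1, unit="D")
    df["_gap"] = df["drug_class"].map(gap_by_class).fillna(config.OPIOID_MAX_GAP_DAYS)
    if "inhibitor_strength" not in df.columns:
        df["inhibitor_strength"] = "not-applicable"

    df = df.sort_values(["person_id", "drug", "start_date", "end_date"], kind="stable")
    grp = df.groupby(["person_id", "drug"], sort=False)
    run_end = grp["end_date"].cummax()
    prev_end = run_end.groupby([df["person_id"], df["drug"]], sort=False).shift(1)
    gap_days = (df["start_date"] - prev_end).dt.days - 1
    new_ep = prev_end.isna() | (gap_days > df["_gap"])
    df["_ep"] = new_ep.cumsum()

    episodes = (
        df.groupby("_ep", sort=False)
        .agg(
            person_id=("person_id", "first"),
            drug=("drug", "first"),
            drug_class=("drug_class", "first"),
            inhibitor_strength=("inhibitor_strength", "first"),
            start_date=("start_date", "min"),
            end_date=("end_date", "max"),
            source_count=("start_date", "size"),
        )
        .reset_index(drop=True)
    )
    return episodes


def _overlap_days(a_start: date, a_end: date, b_start: date, b_end: date) -> int:
    """Size of the inclusive-date intersection of two intervals, in days."""
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return max(0, (hi - lo).days + 1)


def concomitant_level(
    window_start: date,
    window_end: date,
    inhibitors: Iterable[ExposureEpisode],
    min_overlap_days: int = config.MIN_OVERLAP_DAYS,
) -> ConcomitancyResult:
    """Classify opioid-inhibitor concomitancy over an assessment window.

    The level is ``strong`` if any strong inhibitor episode overlaps the
    window for at least ``min_overlap_days`` consecutive days, else
    ``moderate`` under the same rule, else ``none`` (strong dominates:
    co-exposure resolves to the smallest inhibitor factor).  ``overlap_days``
    is the largest overlap among episodes of the chosen strength (or overall
    when no episode qualifies).
    """
    best = {"strong": 0, "moderate": 0}
    other = 0
    for ep in inhibitors:
        ov = _overlap_days(window_start, window_end, ep.start_date, ep.end_date)
        if ep.inhibitor_strength in best:
            best[ep.inhibitor_strength] = max(best[ep.inhibitor_strength], ov)
        else:
            other = max(other, ov)
    if best["strong"] >= min_overlap_days:
        return ConcomitancyResult(best["strong"], "strong")
    if best["moderate"] >= min_overlap_days:
        return ConcomitancyResult(best["moderate"], "moderate")
    return ConcomitancyResult(max(best["strong"], best["moderate"], other), "none")


def inhibitor_free(
    opioid_start: date,
    study_end: date,
    inhibitor_episodes: Iterable[ExposureEpisode],
    washout_days: int = config.WASHOUT_DAYS,
) -> bool:
    """True iff no inhibitor episode intersects
    ``[opioid_start - washout_days, study_end]`` (both endpoints inclusive).
    """
    window_start = opioid_start - timedelta(days=washout_days)
    for ep in inhibitor_episodes:
        if ep.end_date >= window_start and ep.start_date <= study_end:
            return False
    return True


def select_first_opioid(episodes: Sequence[ExposureEpisode]) -> ExposureEpisode:
    """The person's earliest opioid episode; same-day ties break
    alphabetically by drug name (deterministic, documented tie-break)."""
    opioids = [e for e in episodes if e.drug_class == "opioid"]
    if not opioids:
        raise LookupError("person has no opioid episode")
    return min(opioids, key=lambda e: (e.start_date, e.drug))
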