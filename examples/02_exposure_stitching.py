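"""Prescription-era construction and opioid-inhibitor concomitancy.

Shows end-date imputation from dispensed quantity (4 tablets/day), refill
stitching at the class-specific gap thresholds, and the 3-day overlap rule.
"""

from datetime import date

from opioidpgx import (
    PrescriptionRecord,
    concomitant_level,
    impute_end_date,
    stitch_episodes,
)

print("End-date imputation (4 tablets a day, interval includes start day)")
print("-" * 68)
for qty in (28, 30, 4):
    end = impute_end_date(date(2020, 1, 1), qty)
    print(f"  start 2020-01-01, quantity {qty:3d} tablets -> end {end}")

print()
print("Refill stitching: opioids merge at gaps under 14 days")
print("-" * 68)
for gap in (10, 13, 14):
    records = [
        PrescriptionRecord("p1", "hydrocodone", "opioid", date(2020, 1, 1), 28),
        PrescriptionRecord("p1", "hydrocodone", "opioid",
                           date(2020, 1, 8 + gap), 28),
    ]
    episodes = stitch_episodes(records)
    print(f"  gap {gap:2d} days -> {len(episodes)} episode(s): "
          + "; ".join(f"{e.start_date}..{e.end_date}" for e in episodes))

print()
print("Concomitancy needs at least 3 overlapping days in the assessment window")
print("-" * 68)
opioid_window = (date(2020, 1, 1), date(2020, 1, 31))
for start_day, supply, strength in [(10, 3, "strong"), (30, 14, "moderate")]:
    inhibitor = stitch_episodes(
        [PrescriptionRecord("p1", "fluoxetine" if strength == "strong" else "duloxetine",
                            "inhibitor", date(2020, 1, start_day), 4 * supply,
                            inhibitor_strength=strength)]
    )
    res = concomitant_level(*opioid_window, inhibitor)
    print(f"  {strength} inhibitor starting Jan {start_day} ({supply} days): "
          f"overlap {res.overlap_days} d -> level {res.level}")
# 3 overlapping days phenoconvert the patient (factor 0); a 2-day brush with
# the inhibitor does not.
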