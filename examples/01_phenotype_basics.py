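"""Activity scores, phenotypes, and inhibitor-mediated phenoconversion.

Builds a handful of diplotypes, scores them, and shows how a concomitant
CYP2D6 inhibitor shifts the metabolizer category.
"""

from opioidpgx import (
    CallerReport,
    Diplotype,
    consensus_diplotype,
    diplotype_activity_score,
    phenoconvert,
)

print("Diplotype scoring and phenoconversion")
print("-" * 60)
for diplotype in ["*1/*1", "*1/*4", "*4/*4", "*1/*41", "*1x2/*1", "*1/*10"]:
    score = diplotype_activity_score(diplotype)
    row = [diplotype, f"score={score:4.2f}"]
    for level in ("none", "moderate", "strong"):
        res = phenoconvert(score, level)
        row.append(f"{level}:{res.phenotype}")
    print("  ".join(row))

# A genotypic NM (*1/*1, score 2.0) on fluoxetine (strong inhibitor) has an
# adjusted score of 0 x 2.0 = 0 and behaves as a poor metabolizer (pPM);
# under a moderate inhibitor the score halves to 1.0, an intermediate
# metabolizer (pIM).

print()
print("Consensus across four haplotype callers")
print("-" * 60)
reports = [
    CallerReport("aldy", Diplotype.parse("*1/*4")),
    CallerReport("cyrius", Diplotype.parse("*4/*1")),   # same call, flipped
    CallerReport("pypgx", None),                        # no-call
    CallerReport("stellarpgx", Diplotype.parse("*1/*2")),
]
print("consensus:", consensus_diplotype(reports))
# *1/*4 is reported by 2 of the 3 tools that made a call: a strict majority
# with at least two agreeing tools, so the consensus is *1/*4.

reports_split = [
    CallerReport("aldy", Diplotype.parse("*1/*4")),
    CallerReport("cyrius", Diplotype.parse("*1/*2")),
]
print("2-2 style split:", consensus_diplotype(reports_split))
# No strict majority -> None (the person would be excluded as Indeterminate).
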