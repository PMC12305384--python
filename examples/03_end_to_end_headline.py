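"""Full pipeline on the headline scenario.

Generates a synthetic cohort calibrated to the published anchors (comparison
arm event rate 1.8%, true marginal OR 1.19, 15% inhibitor exposure), runs
phenotyping, exposure-era construction, cohort assembly, and the primary
IPTW analysis (phenoconverted IM/PM vs NM/UM).
"""

from opioidpgx import run_scenario

data, result, report = run_scenario("headline", seed=42, analysis="A",
                                    n_persons=100_000)

print("Attrition (persons remaining after each filter)")
for step, count in result.attrition.items():
    print(f"  {step:24s} {count:6d}")

cohort = result.cohort
exposed = cohort[cohort["exposed_A"] == 1]
comparison = cohort[cohort["exposed_A"] == 0]
print()
print(f"Cohort: {len(cohort)} persons "
      f"({len(exposed)} phenoconverted IM/PM, {len(comparison)} NM/UM)")
print(f"Pain-ED event rate: exposed {100 * exposed['outcome'].mean():.2f}% "
      f"vs comparison {100 * comparison['outcome'].mean():.2f}%")

res = report.result
print()
print(f"True marginal OR (generator calibration): "
      f"{data.info['achieved_marginal_or']:.3f}")
print(f"Crude OR:       {res.unweighted_or:.3f}")
print(f"IP-weighted OR: {res.weighted_or:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
print(f"Covariates with weighted SMD < 0.1: "
      f"{int(report.balance['balanced'].sum())}/{len(report.balance)}")
# The IP-weighted OR estimates the population-averaged (marginal) odds ratio
# the generator was calibrated to (1.19); with the headline scenario's mild
# net confounding, crude and weighted estimates are close, and the 95% CI of
# the weighted OR covers the calibrated truth.
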