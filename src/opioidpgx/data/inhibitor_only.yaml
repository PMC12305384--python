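# Inhibitor-effect scenario for the analysis-B contrast (inhibitor-exposed vs
# inhibitor-free among genotypic normal metabolizers).  The genotype
# background is fixed to functional alleles so every subject is a genotypic
# NM and the inhibitor contrast is isolated; the outcome effect attaches to
# inhibitor prescription exposure, with true marginal OR 1.49.  Confounding
# reflects that most CYP2D6 inhibitors are antidepressants: inhibitor users
# carry more depression and anxiety diagnoses at baseline.
name: inhibitor_only
n_persons: 100000
allele_frequencies:
  "*1": 0.70
  "*2": 0.30
n_callers: 4
caller_error: 0.02
caller_no_call: 0.05
opioid_mix:
  hydrocodone: 0.45
  tramadol: 0.25
  oxycodone: 0.25
  codeine: 0.05
n_rx_probs: [0.5, 0.3, 0.15, 0.05]
quantities: [28, 56, 120, 12]
quantity_probs: [0.55, 0.30, 0.13, 0.02]
short_gap_prob: 0.8
short_gap_range: [0, 10]
long_gap_range: [14, 30]
inhibitor_prob: 0.15
strong_fraction: 0.6
overlap_mix:
  concomitant: 0.75
  short: 0.15
  washout_only: 0.10
inhibitor_supply_range: [30, 90]
effect_basis: inhibitor
target_marginal_or: 1.49
reference_event_rate: 0.018
confounders:
  - {name: depression, kind: binary, p_comparison: 0.13, p_exposed: 0.35, beta: 0.2624}
  - {name: anxiety, kind: binary, p_comparison: 0.11, p_exposed: 0.25, beta: 0.1823}
  - {name: benzodiazepine, kind: binary, p_comparison: 0.30, p_exposed: 0.42, beta: 0.1398}
  - {name: back_pain, kind: binary, p_comparison: 0.129, p_exposed: 0.157, beta: 0.1823}
  - {name: age, kind: normal, mean_comparison: 50.6, mean_exposed: 51.6, sd: 15.35, beta: -0.01}
cancer_prob: 0.01
distractor_prob: 0.05
epoch: "2018-01-01"
opioid_start_range: [200, 560]
study_end_offset: 1000
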