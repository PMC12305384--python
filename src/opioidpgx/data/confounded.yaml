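# Strong-confounding variant of the headline scenario, for demonstrating and
# testing confounding control: the same five confounders carry much larger
# arm imbalances and outcome effects, all in the same direction, so the crude
# OR is markedly biased upward while the true marginal OR stays at 1.19.
name: confounded
n_persons: 30000
allele_frequencies:
  "*1": 0.40
  "*2": 0.15
  "*35": 0.02
  "*1x2": 0.02
  "*41": 0.10
  "*17": 0.03
  "*9": 0.01
  "*10": 0.05
  "*4": 0.15
  "*5": 0.05
  "*3": 0.02
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
effect_basis: phenoconversion
target_marginal_or: 1.19
reference_event_rate: 0.018
confounders:
  - {name: depression, kind: binary, p_comparison: 0.10, p_exposed: 0.30, beta: 0.6931}
  - {name: anxiety, kind: binary, p_comparison: 0.08, p_exposed: 0.25, beta: 0.6931}
  - {name: benzodiazepine, kind: binary, p_comparison: 0.25, p_exposed: 0.45, beta: 0.5878}
  - {name: back_pain, kind: binary, p_comparison: 0.10, p_exposed: 0.22, beta: 0.5878}
  - {name: age, kind: normal, mean_comparison: 48.0, mean_exposed: 54.0, sd: 15.0, beta: 0.02}
cancer_prob: 0.01
distractor_prob: 0.05
epoch: "2018-01-01"
opioid_start_range: [200, 560]
study_end_offset: 1000
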