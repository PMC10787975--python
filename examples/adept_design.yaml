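# Default six-dose design: two candidate orderings (2a vs 2b unresolved),
# published skeleton, target TD25.  All omitted fields take their defaults.
dose_labels: ["-1", "0", "1", "2a", "2b", "3"]
theta: 0.25
skeleton: [0.01, 0.04, 0.08, 0.16, 0.25, 0.35]
# equivalently, derive the skeleton from the indifference interval:
# calibration: {theta: 0.25, delta: 0.05, nu: 5}
orderings:
  - { doses: ["-1", "0", "1", "2a", "2b", "3"], prior: 0.5 }
  - { doses: ["-1", "0", "1", "2b", "2a", "3"], prior: 0.5 }
cohort_size: 3
max_n: 60
start_dose: "0"
stage1_path: ["0", "1", "2a", "2b", "3"]
success_rule_n: 15
safety: { threshold: 0.35, confidence: 0.80, min_patients_lowest: 3 }
followup: { min_days: 56, treatment_days: 49 }
weights: { t1: 56, t2: 84, t3: 364, w_floor: 0.6, w_mid: 0.8 }
prior_beta: { mean: 0.0, variance: 1.34 }
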