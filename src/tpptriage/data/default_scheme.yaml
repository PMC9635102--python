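# Default scoring scheme: level scores 0/1/2/3 (unknown scores 0 but is
# tracked through the completeness fraction), efficacy and safety weighted
# double, and identical rank cutoffs at every clinical phase. All values
# are replaceable; loading validates monotone level scores, the
# efficacy/safety up-weighting and cutoff ordering.
criteria:
  - {id: setting, name: Setting, weight: 1}
  - {id: efficacy, name: Efficacy, weight: 2}
  - {id: companion_diagnostic, name: Need for a companion diagnostic test, weight: 1}
  - {id: clinical_monitoring, name: Need for clinical monitoring, weight: 1}
  - {id: safety, name: Safety, weight: 2}
  - {id: mode_of_administration, name: Mode of administration, weight: 1}
  - {id: treatment_adherence, name: Treatment adherence, weight: 1}
  - {id: stability, name: Stability, weight: 1}
  - {id: who_eml, name: WHO Essential Medicines List, weight: 1}
level_scores:
  met_preferred: 3
  met_minimum: 2
  partially_met: 1
  not_met: 0
  unknown: 0
thresholds:
  I: {high: 0.60, medium: 0.40}
  II: {high: 0.60, medium: 0.40}
  III: {high: 0.60, medium: 0.40}
  IV: {high: 0.60, medium: 0.40}
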