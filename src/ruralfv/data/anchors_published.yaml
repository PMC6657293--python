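# Published anchor targets for the rural community.
# Baseline: 43.7% of the population meets the 2-servings threshold at an
# effective nearest-FV driving distance of 5 miles. Relative changes are
# percent of baseline. The largest marginal step of the response curve sits
# between 3.5 and 3 miles.
# Weights are the inverse squares of each anchor's reproduction tolerance
# on its own scale (1.5 pp, 2 and 3 relative points respectively),
# normalized to the loosest anchor.
anchors:
  - {delta_miles: 0.0, target_value: 43.7, target_type: baseline_pct, weight: 4.0}
  - {delta_miles: 1.0, target_value: 8.9, target_type: relative_change_pct, weight: 2.25}
  - {delta_miles: 5.0, target_value: 25.0, target_type: relative_change_pct, weight: 1.0}
peak_step: [3.5, 3.0]
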