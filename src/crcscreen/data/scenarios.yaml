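# Screening-participation scenarios: 1 perfect adherence, 2 adherence as
# currently observed in Germany, 3 high uptake as achieved by organized
# Dutch/Basque programmes (advance notification plus reminder letters).
# All rates are per-offer participation probabilities unless the adherence
# mode is switched to "persistent".
scenarios:
  - id: 1
    label: perfect adherence
    fit_annual: {male: 1.0, female: 1.0}
    fit_biennial: {male: 1.0, female: 1.0}
    fit_positive_col: 1.0
    screening_col: {male: 1.0, female: 1.0}
    surveillance_col: 1.0
    reminders: false
  - id: 2
    label: current adherence
    fit_annual: {male: 0.07, female: 0.25}
    fit_biennial: {male: 0.16, female: 0.24}
    fit_positive_col: 0.64
    screening_col: {male: 0.23, female: 0.24}
    surveillance_col: 0.63
    reminders: false
  - id: 3
    label: high adherence
    fit_annual: {male: 0.71, female: 0.75}
    fit_biennial: {male: 0.71, female: 0.75}
    fit_positive_col: 0.83
    screening_col: {male: 0.42, female: 0.42}
    surveillance_col: 0.63
    reminders: true
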