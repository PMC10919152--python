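# Screening strategies compared in the German organized-programme evaluation.
# "current" is the standing offer (men: two screening colonoscopies at 50/60;
# women: annual FIT at 50-54 then colonoscopies at 55/65); the four
# alternatives all start screening at age 45.
#
# Offer blocks: either {test: colonoscopy, ages: [..]} or
# {test: fit, start, stop, interval} (FIT offered at start, start+interval,
# ..., up to and including stop).
strategies:
  - name: current
    label: mCOL50/fFIT50+COL55
    male:
      - {test: colonoscopy, ages: [50, 60]}
    female:
      - {test: fit, start: 50, stop: 54, interval: 1}
      - {test: colonoscopy, ages: [55, 65]}
  - name: FIT1y45+COL10y50
    label: FIT1y45+COL10y50
    male:
      - {test: fit, start: 45, stop: 49, interval: 1}
      - {test: colonoscopy, ages: [50, 60]}
    female:
      - {test: fit, start: 45, stop: 49, interval: 1}
      - {test: colonoscopy, ages: [50, 60]}
  - name: FIT1y45+COL10y50-3X
    label: FIT1y45+COL10y50-3X
    male:
      - {test: fit, start: 45, stop: 49, interval: 1}
      - {test: colonoscopy, ages: [50, 60, 70]}
    female:
      - {test: fit, start: 45, stop: 49, interval: 1}
      - {test: colonoscopy, ages: [50, 60, 70]}
  - name: FIT2y45
    label: FIT2y45
    male:
      - {test: fit, start: 45, stop: 75, interval: 2}
    female:
      - {test: fit, start: 45, stop: 75, interval: 2}
  - name: COL10y45-3X
    label: COL10y45-3X
    male:
      - {test: colonoscopy, ages: [45, 55, 65]}
    female:
      - {test: colonoscopy, ages: [45, 55, 65]}
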