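# crcscreen

Individual-level discrete-event simulation of colorectal-cancer (CRC)
screening strategies, with a full cost-effectiveness pipeline.  The package
is aimed at health-economic modellers and screening epidemiologists who want
a transparent, fully reproducible microsimulation of the German organized
CRC screening programme and of alternative strategies that start screening
at age 45 instead of 50.

## What it models

Each simulated person is followed from age 20 to 90 or death:

- **Natural history.** Precursor lesions arise from a non-homogeneous
  Poisson process (piecewise-constant, age-increasing baseline hazard ×
  log-normal individual frailty × a calibrated scale).  Each lesion follows
  the **adenoma pathway** (non-advanced adenoma → advanced adenoma (AA) →
  preclinical carcinoma) or the rarer, slower **serrated pathway**
  (non-crSP → crSP → preclinical carcinoma), with exponential dwell times
  and pathway-specific progression fractions.  Preclinical cancer surfaces
  symptomatically after an exponential sojourn; stage at diagnosis is drawn
  from a four-way distribution; CRC death competes with life-table
  mortality through stage-specific excess hazards.
- **Screening.** Five strategies combining FIT (fecal immunochemical test)
  and colonoscopy, three participation scenarios (perfect, currently
  observed in Germany, high European uptake), state-specific test
  sensitivities, per-person FIT positivity via the most advanced lesion
  present, polypectomy with S3-style surveillance intervals, FIT-positive
  follow-up colonoscopy, and colonoscopy complications.
- **Economics.** Discounted (3%/year from age 40) lifetime costs in 2023 €
  (screening, complication and stage×phase treatment costs) and QALYs
  (baseline and phase-specific utilities minus per-event utility losses).
- **Decision analysis.** Per-1,000-40-year-olds results, incremental
  cost-effectiveness ratios ICER = ΔC/ΔE against the current strategy,
  efficiency frontier with extended dominance, net health benefit
  NHB = E − C/λ, cost-effectiveness acceptability curves over λ ∈
  [€0, €100,000], and Monte-Carlo ICER clouds.

Strategy arms share person-level random streams (common random numbers),
so paired differences between arms are pure screening effects and a
zero-participation arm reproduces the no-screening arm *exactly*.

The calibrated natural-history posterior behind the published German
evaluation is not publicly deposited; this package declares a plausible
central parameter set, calibrates its lesion-onset scale by bisection to
the published no-screening lifetime incidence (57.92 per 1,000
40-year-olds), and emulates posterior uncertainty by log-normal jitter.
See `docs/methods.md` for every declared value and its rationale.

## Worked example

```python
from crcscreen.experiment import RunConfig, run_experiment

bundle = run_experiment(
    RunConfig(cohort_size=20_000, n_draws=10, scenarios=(1,), seed=42)
)
print(bundle["results"].round(2).to_string(index=False))
print(bundle["cea"][1].to_string(index=False))
```

prints (perfect-adherence scenario, 20,000 persons × 10 posterior-style
draws):

```
 scenario            strategy  incidence  mortality  colonoscopies  complications      cost    qalys
        1        no_screening      56.41      27.21           0.00           0.00 939806.22 19040.67
        1             current      31.37      13.77        2053.32           1.73 792672.83 19085.08
        1    FIT1y45+COL10y50      33.03      14.21        2079.11           1.66 844705.63 19088.52
        1 FIT1y45+COL10y50-3X      24.05      10.66        2906.39           2.37 807079.65 19093.68
        1             FIT2y45      35.06      14.86        1040.91           0.75 763758.35 19073.30
        1         COL10y45-3X      25.97      11.15        3001.29           2.41 822308.11 19102.99

           strategy  d_cost  d_qalys  icer status  d_colonoscopies  incidence_reduction  mortality_reduction
   FIT1y45+COL10y50   52033     3.44 15128   icer               26                -1.67                -0.44
FIT1y45+COL10y50-3X   14407     8.60  1675   icer              853                 7.31                 3.11
            FIT2y45  -28914   -11.78  2455   icer            -1012                -3.70                -1.10
        COL10y45-3X   29635    17.91  1655   icer              948                 5.39                 2.61
```

Reading: the no-screening arm produces 56.4 lifetime CRC cases and 27.2 CRC
deaths per 1,000 persons alive and cancer-free at 40.  Screening cuts both
roughly in half under perfect adherence, at the cost of 1,000–3,000
colonoscopies per 1,000 persons.  The incremental table compares each
45-start strategy with the current German offer: the three-colonoscopy
strategy starting at 45 (`COL10y45-3X`) buys the largest QALY gain at about
€1,700 per QALY.  (All numbers per 1,000 persons; this desk-scale run
carries Monte-Carlo noise — the full published scale is 100,000 persons ×
1,000 draws.)

The same pipeline is scriptable from the shell:

```bash
crcscreen simulate --seed 42 --cohort-size 20000 --n-draws 10 --out results/
crcscreen cea  --results results/ --comparator current
crcscreen ceac --results results/ --wtp-max 100000 --wtp-step 5000
```

## Layout

```
src/crcscreen/
  config.py           declared constants: hazards, costs, utilities, PSA ranges
  params.py           parameter draws, PSA draws, onset-scale calibration
  natural_history.py  latent disease-course sampling, no-screening cohorts
  screening.py        strategies, adherence, FIT/colonoscopy, surveillance
  economics.py        discounting, phase decomposition, cost/QALY accrual
  cea.py              ICERs, frontier, NHB, CEAC, Monte-Carlo ICER cloud
  experiment.py       run grid, common random numbers, CSV/JSON output
  cli.py              `crcscreen` command-line interface
  data/               strategies.yaml, scenarios.yaml, life_table.csv
docs/methods.md       model description, declared defaults, limitations
```
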