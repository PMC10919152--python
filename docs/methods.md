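# Methods

This note documents the model implemented in `crcscreen`: its structure,
every declared parameter with units and rationale, the numerical
conventions, what the synthetic inputs do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Natural history

Each person is simulated from age 20 to 90 or death.  The entire latent
disease course is sampled up front into flat arrays (`LatentCohort`);
screening later only *intercepts* these latent timelines.  This design
makes common-random-number comparisons across strategy arms exact and keeps
the no-screening summary fully vectorised (a 100,000-person cohort samples
in well under a second, which is what makes bisection calibration cheap).

**Lesion onsets.** A non-homogeneous Poisson process with piecewise-constant
baseline hazard in 10-year age bands (per person-year, ages 20–90):

| band | 20s | 30s | 40s | 50s | 60s | 70s | 80s |
|------|-----|-----|-----|-----|-----|-----|-----|
| hazard | 0.0010 | 0.0025 | 0.0060 | 0.0110 | 0.0160 | 0.0190 | 0.0200 |

The piecewise-constant form gives the qualitative age gradient any CRC
model needs while keeping the intensity integral analytic — the unit-test
oracle for mean onset counts is literally `scale × Σ hazard × width`.  The
hazard is multiplied by a person-level log-normal frailty (σ = 0.6, mean 1)
and by `onset_rate_scale`, the single calibrated parameter (§3).

**Pathways.** Each lesion joins the adenoma pathway with probability
`adenoma_fraction = 0.85`, otherwise the serrated pathway.  Progression is
two-step (non-advanced → advanced → preclinical carcinoma).  Only a
fraction of lesions ever progresses out of each state (adenoma: 0.30 then
0.50; serrated: 0.25 then 0.50); dwell times for those that do are
exponential with means

| transition | adenoma | serrated |
|---|---|---|
| non-advanced → advanced | 12 y | 18 y |
| advanced → preclinical CRC | 8 y | 12 y |

Serrated dwell means are held at 1.5× the adenoma means, encoding the
slower serrated kinetics; an invariant enforces serrated ≥ adenoma for
every parameter draw.  Exponential dwell distributions were chosen because
they give closed-form oracles for all distribution tests; the forms are
configurable points in `config.py`.

**Sojourn and stage.** Preclinical cancer surfaces symptomatically after an
exponential sojourn (mean 4 y).  Stage at symptomatic diagnosis is drawn
from (0.18, 0.28, 0.31, 0.23) over stages 1–4; screen-detected cancers use
the earlier-shifted (0.45, 0.30, 0.17, 0.08), reflecting the stage shift
any screen-detection channel must produce.

**Death.** Other-cause death is inverse-transform sampled from a bundled
synthetic Gompertz life table by sex (CSV-swappable; columns age, sex,
annual death probability, ages 20–89).  After a CRC diagnosis an
exponential excess hazard by stage (0.010, 0.030, 0.080, 0.450 per year)
competes with other-cause death; survivors are censored at 90.  The
survival uniforms are pre-drawn per lesion, so a screen-detected and a
symptomatically detected cancer in paired arms share survival randomness.

Multiple simultaneous lesions are allowed; the person-level diagnosis is
triggered by the earliest lesion to surface clinically.  Persons dead or
diagnosed before age 40 are excluded from all per-1,000 denominators
(results are reported per 1,000 persons alive and CRC-free at 40).

## 2. What the synthetic parameters emulate — and what not

The Bayesian-calibrated natural-history posterior behind the published
German evaluation is not publicly deposited.  The central parameter set
above is therefore a *declared stand-in*, not a reconstruction: it is
chosen to be biologically plausible and then calibrated (§3) so the
no-screening arm reproduces the published lifetime incidence.  Posterior
uncertainty is emulated by independent log-normal jitter (CV 0.10, mean-1
factors) on the positive-real parameters; stage distributions and the
adenoma fraction stay at their central values.  No posterior correlation
structure is emulated — none is published.  Consequently, passing tests
show that the *pipeline* (simulation → economics → decision analysis) is
correct and internally consistent at the published marginal incidence; they
do not validate the stand-in dwell times or stage-specific survival against
German registry data, and simulated strategy effects are expected to differ
quantitatively from the published ones (the model intercepts somewhat fewer
cancers per colonoscopy than the published model).

## 3. Calibration

`calibrate_onset_scale` bisects `onset_rate_scale` until the simulated
no-screening lifetime CRC incidence hits a target (default 57.92 per 1,000
40-year-olds).  Every objective evaluation reuses the same cohort seed, so
the objective is a monotone step function and bisection is well posed;
bracketing uses doubling/halving with a cap of 12, iterations cap at 40,
and the convergence tolerance is relative (default 2%, bounded below by
Monte-Carlo granularity at the chosen cohort size).  The frozen central
value `onset_rate_scale = 2.0122` is the output of this calibration at
100,000 persons.  Calibration matches incidence only; mortality follows
from the declared stage distribution and survival hazards and is reported,
not matched (it lands near the published 27.05 per 1,000).

## 4. Screening mechanics

- **Offer schedules** come from `data/strategies.yaml` (five strategies,
  per-sex blocks).  FIT blocks expand to offers at `start, start+interval,
  …, stop`; the current German strategy gives men colonoscopies at 50/60
  and women annual FIT 50–54 plus colonoscopies at 55/65.
- **Adherence** (`data/scenarios.yaml`) is per-offer Bernoulli by modality
  and sex (annual FIT, biennial FIT, FIT-positive colonoscopy, 10-yearly
  colonoscopy, surveillance).  A `persistent` mode (one decision per
  modality per person, reused) is available because the choice materially
  changes cumulative uptake; per-offer is the default since the published
  participation rates read as per-round figures.  Follow-up and
  surveillance decisions are always per event.
- **FIT positivity** uses the sensitivity of the most advanced state
  present (cancer 0.77 > AA 0.26 > crSP 0.11 > non-AA 0.08 > non-crSP
  0.07); a lesion-free test is positive with 1 − specificity = 0.05.  The
  per-person rule (rather than per-lesion independent bleeding) matches how
  state-specific FIT sensitivities are defined.
- **Colonoscopy** detects each lesion independently (non-AA 0.76, AA 0.91,
  non-crSP 0.73, crSP 0.76, cancer 0.95; specificity 1).  Detected
  precursors are removed and their scheduled progression events cancelled;
  a detected preclinical cancer becomes a screen diagnosis.  Each
  colonoscopy carries a 0.0004 complication risk (instantaneous event with
  cost and disutility; no complication mortality is modelled because no
  fatality rate is published).
- **Surveillance** (declared stand-in for the German S3 interval table):
  ≥1 advanced lesion removed or ≥3 removals → 3 years; 1–2 non-advanced →
  5 years; clean exam → routine schedule.  A declined surveillance offer
  returns the person to the routine schedule.
- **10-year suppression:** any routine offer (FIT or colonoscopy) within 10
  years of any colonoscopy is skipped, mirroring the programme rule that
  FIT is offered only without a recent screening colonoscopy.  Suppressed
  offers generate no invitation letter.
- A diagnosed person exits screening permanently.

## 5. Economics

All values in 2023 €; discount rate 3%/year from reference age 40.  Point
events are discounted by `(1+r)^-(age-40)`; continuous flows (utility
accrual, annualised phase costs) by the exact closed-form integral of that
factor over the interval — simpler than year-by-year midpoint factors and
identical in the limit.  Events before age 40 accrue nothing.

Costs: notification letter €0.85 per presented routine offer (plus one
reminder per FIT offer in the high-adherence scenario, which is built on
reminder mailings); consultation €13.41 once at first attended screening
contact; FIT kit €8.67 + processing €6.59 per test; colonoscopy €204.13,
or €234.08 with polypectomy, plus pathology €15.15 per biopsied finding;
complication treatment €5,170.  Treatment costs are annual stage-group ×
phase figures (stages 1&2 share a row; the stage-1&2 continuing entry is a
net offset of −€1,006/yr) multiplied by fractional phase durations.

Phases: initial = first 12 months after diagnosis; terminal = last 12
months before death *if* the death is from CRC; continuing = remainder;
when survival < 24 months the phases truncate in the order terminal >
initial.  Non-CRC deaths and censoring have no terminal phase.

Utilities: baseline 0.85 from 40 until diagnosis; initial phase 0.76;
continuing 0.84 (stages 1–3) / 0.82 (stage 4); terminal 0.64.  Per-event
losses: colonoscopy 0.0005, FIT-result wait 0.0013, polypectomy-result wait
0.0009 (per colonoscopy with polypectomy), complication 0.0055.  Negative
person-level QALY totals are flagged, never clipped.

## 6. Decision analysis

ICER = Δcost/ΔQALY against the chosen comparator (default: the current
strategy); dominant strategies (cheaper, more effective) are reported with
their negative ICER *and* a `dominant` flag — consumers should read the
flag.  Reporting rounds costs to €1, QALYs and rates to 0.01.  The
efficiency frontier removes strictly dominated strategies, then extendedly
dominated ones via a lower-convex-hull walk, leaving strictly increasing
ICERs.  The frontier is computed over whatever result set the caller
passes, so including or excluding the no-screening arm is the caller's
choice (the bundled pipeline computes it over the screened strategies).
CEACs use net health benefit with exact ties split equally (this keeps
column sums exactly 1); WTP 0 is treated as the cost-minimisation limit.
The Monte-Carlo ICER cloud draws uniformly and independently within the
supplied 95% CIs — the published description ("samples within the CI")
gives no distributional form, and uniform needs no unpublished standard
errors.

## 7. Probabilistic sensitivity analysis

Each experiment draw pairs one natural-history parameter draw with one PSA
row: independent uniforms within the published range for every varied input
(test sensitivities/specificity, complication probability, utilities,
utility losses, complication treatment cost, nine stage×phase treatment
costs).  Screening unit costs are never varied.  The stage-1&2 continuing
range is interpreted as [−1,263, −645] (the published range omits the minus
signs implied by its mean).

## 8. Randomness and reproducibility

All streams are counter-based (numpy Philox keyed by small-integer
`SeedSequence` entropy): the latent cohort uses `(seed, draw)`, person
*i*'s screening stream uses `(seed, draw, i)` via a deterministic SHA-seeded
generator, independent of strategy.  Hence (a) identical configs give
byte-identical outputs, (b) all arms within a draw share natural histories
and person-level screening randomness, and (c) a zero-participation arm
consumes no outcome-relevant randomness and equals the no-screening arm
exactly.  Person-level reproducibility is defined at fixed cohort ordering:
person *i*'s history is a deterministic function of `(seed, draw, n, i)`.

## 9. Problem sizes

Desk-scale defaults are 10,000 persons × 50 draws (minutes on one core);
the published scale (100,000 × 1,000) is a configuration flag away and
scales linearly.  The test suite and the acceptance script use 20,000–
50,000-person cohorts — chosen as the package's own accuracy/runtime
trade-off: at 50,000 persons the Monte-Carlo standard error on a
57.92/1,000 incidence is about ±1.1, sufficient for every property checked.

## 10. Known limitations

- All natural-history values other than the calibrated onset scale are
  declared stand-ins (§2); strategy-level effect sizes should be read as
  internally consistent, not as re-estimates of the published ones.
- Single colorectal site: no tumour location/sidedness or subsite
  stratification.
- No complication mortality; complications are instantaneous cost/utility
  events.
- Post-treatment oncologic follow-up is represented only through phase
  costs/utilities; diagnosed persons leave the screening system.
- The biennial-FIT-from-55 option for women in the pre-2019 German offer is
  not simulated; the current-strategy definition follows the organized
  programme comparison (annual FIT 50–54, colonoscopies 55/65).
- The synthetic life table is Gompertz by sex, standing in for official
  period tables; any table with the same CSV schema can be swapped in.
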