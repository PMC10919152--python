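"""Declared model constants: natural-history defaults, screening test
characteristics, unit costs, utilities, strategies, adherence scenarios,
and the synthetic life table.

The natural-history values are declared stand-ins: the calibrated posterior
behind the published German evaluation is not publicly deposited, so a
plausible central parameter set is fixed here and its overall lesion-onset
scale is calibrated (see :func:`crcscreen.params.calibrate_onset_scale`) to
the published no-screening lifetime incidence of 57.92 per 1,000
40-year-olds.  Everything a user might reasonably want to swap lives in this
module or in the YAML/CSV files under ``crcscreen/data``.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger("crcscreen")

# --------------------------------------------------------------------------
# Lesion states.  The adenoma pathway runs non-advanced adenoma (non-AA) ->
# advanced adenoma (AA) -> preclinical carcinoma; the serrated pathway runs
# non-clinically-relevant serrated polyp (non-crSP) -> clinically relevant
# serrated polyp (crSP) -> preclinical carcinoma.
# --------------------------------------------------------------------------
ADENOMA = 0
SERRATED = 1

STATE_NON_ADV = "non_advanced"
STATE_ADV = "advanced"
STATE_PRECLINICAL = "preclinical_crc"

MALE = 0
FEMALE = 1

START_AGE = 20.0
END_AGE = 90.0
REFERENCE_AGE = 40.0  # costs/QALYs discounted from here; per-1,000 denominators

# --------------------------------------------------------------------------
# Baseline lesion-onset hazard: piecewise constant in 10-year age bands,
# increasing with age (new lesions per person-year, before frailty and the
# calibrated scale factor are applied).
# --------------------------------------------------------------------------
ONSET_AGE_BANDS = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0])
BASE_ONSET_HAZARD = np.array([0.0010, 0.0025, 0.0060, 0.0110, 0.0160, 0.0190, 0.0200])

# Fraction of lesions that ever progress out of each precursor state, by
# pathway.  Serrated lesions are rarer (adenoma_fraction) and slower
# (longer dwell means); they are not assumed more likely to progress.
PROGRESS_PROB_NONADV = {ADENOMA: 0.30, SERRATED: 0.25}
PROGRESS_PROB_ADV = {ADENOMA: 0.50, SERRATED: 0.50}

# Central natural-history parameter values (declared stand-ins, see module
# docstring).  Dwell means in years; serrated dwell = 1.5x adenoma dwell.
CENTRAL_PARAM_VALUES = dict(
    onset_rate_scale=2.0122,  # calibrated: no-screening incidence 57.92/1,000
    frailty_sd=0.6,
    adenoma_fraction=0.85,
    mean_dwell_nonadv_to_adv_adenoma=12.0,
    mean_dwell_adv_adenoma_to_crc=8.0,
    mean_dwell_noncr_to_cr_sp=18.0,
    mean_dwell_cr_sp_to_crc=12.0,
    mean_sojourn=4.0,
    stage_dist_symptomatic=(0.18, 0.28, 0.31, 0.23),
    stage_dist_screen=(0.45, 0.30, 0.17, 0.08),
    survival_hazard_by_stage=(0.010, 0.030, 0.080, 0.450),
)

#: Default coefficient of variation of the log-normal jitter used to emulate
#: posterior parameter draws.
POSTERIOR_JITTER_CV = 0.10

# --------------------------------------------------------------------------
# Synthetic life table: Gompertz all-cause mortality by sex, annual death
# probabilities for ages 20..89.  Stands in for official period life tables
# (swappable via CSV with columns age, sex, qx).
# --------------------------------------------------------------------------
_GOMPERTZ = {MALE: (2.9e-4, 0.092), FEMALE: (1.7e-4, 0.094)}


def synthetic_life_table() -> pd.DataFrame:
    """Annual death probabilities ``qx`` for ages 20-89, sexes 'male'/'female'."""
    rows = []
    ages = np.arange(20, 90)
    for sex, label in ((MALE, "male"), (FEMALE, "female")):
        a0, b = _GOMPERTZ[sex]
        hazard = a0 * np.exp(b * (ages - 20.0))
        qx = 1.0 - np.exp(-hazard)
        rows.append(pd.DataFrame({"age": ages, "sex": label, "qx": qx}))
    return pd.concat(rows, ignore_index=True)


def load_life_table(path=None) -> pd.DataFrame:
    """Load a life table CSV (columns age, sex, qx); default: bundled table."""
    if path is None:
        ref = resources.files("crcscreen.data").joinpath("life_table.csv")
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    missing = {"age", "sex", "qx"} - set(table.columns)
    if missing:
        raise ValueError(f"life table missing columns: {sorted(missing)}")
    for label in ("male", "female"):
        sub = table[table.sex == label]
        have = set(sub.age.astype(int))
        need = set(range(20, 90))
        if not need <= have:
            raise ValueError(
                f"life table gap for sex={label}: missing ages "
                f"{sorted(need - have)[:5]}..."
            )
    return table


# --------------------------------------------------------------------------
# Screening test operating characteristics (point values and PSA ranges).
# FIT = fecal immunochemical test at 20 ug hemoglobin/g stool.
# --------------------------------------------------------------------------
FIT_SENSITIVITY = {
    "non_aa": 0.08,
    "aa": 0.26,
    "non_crsp": 0.07,
    "crsp": 0.11,
    "cancer": 0.77,
}
FIT_SPECIFICITY = 0.95
COL_SENSITIVITY = {
    "non_aa": 0.76,
    "aa": 0.91,
    "non_crsp": 0.73,
    "crsp": 0.76,
    "cancer": 0.95,
}
COL_SPECIFICITY = 1.0
COL_COMPLICATION_PROB = 0.0004  # major bleeding & perforation per colonoscopy

# --------------------------------------------------------------------------
# Costs (2023 euro) and utilities.
# --------------------------------------------------------------------------
UNIT_COSTS = dict(
    notification=0.85,
    consultation=13.41,  # one-off at first screening contact
    fit_kit=8.67,
    fit_processing=6.59,
    colonoscopy=204.13,
    colonoscopy_polypectomy=234.08,
    pathology=15.15,
    complication=5170.0,
)

# Annual CRC treatment costs by stage group x phase.  Stages 1 and 2 share a
# row; the continuing-phase entry for stages 1 & 2 is a negative offset.
TREATMENT_COSTS = {
    "stage12": dict(initial=16597.0, continuing=-1006.0, terminal=31007.0),
    "stage3": dict(initial=38085.0, continuing=2038.0, terminal=24266.0),
    "stage4": dict(initial=64187.0, continuing=14657.0, terminal=34206.0),
}

UTILITIES = dict(
    baseline=0.85,
    initial=0.76,  # any stage, first year after diagnosis
    continuing_stage13=0.84,
    continuing_stage4=0.82,
    terminal=0.64,  # last year before CRC death
)

UTILITY_LOSSES = dict(
    colonoscopy=0.0005,
    fit_wait=0.0013,
    polypectomy_wait=0.0009,
    complication=0.0055,
)

DISCOUNT_RATE = 0.03

# --------------------------------------------------------------------------
# PSA ranges (uniform) for every input that is varied.  Screening unit costs
# are deliberately NOT varied.
# --------------------------------------------------------------------------
PSA_RANGES = {
    "fit_sens_non_aa": (0.07, 0.09),
    "fit_sens_aa": (0.20, 0.32),
    "fit_sens_non_crsp": (0.03, 0.15),
    "fit_sens_crsp": (0.04, 0.25),
    "fit_sens_cancer": (0.66, 0.85),
    "fit_specificity": (0.92, 0.96),
    "col_sens_non_aa": (0.70, 0.77),
    "col_sens_aa": (0.84, 0.96),
    "col_sens_non_crsp": (0.60, 0.84),
    "col_sens_crsp": (0.63, 0.87),
    "col_sens_cancer": (0.86, 1.00),
    "complication_prob": (0.0002, 0.0024),
    "utility_baseline": (0.83, 0.88),
    "utility_initial": (0.70, 0.82),
    "utility_continuing_stage13": (0.78, 0.88),
    "utility_continuing_stage4": (0.78, 0.86),
    "utility_terminal": (0.55, 0.75),
    "loss_colonoscopy": (0.0004, 0.0006),
    "loss_fit_wait": (0.0010, 0.0016),
    "loss_polypectomy_wait": (0.0007, 0.0011),
    "loss_complication": (0.0044, 0.0066),
    "cost_complication": (5117.0, 5299.0),
    "cost_stage12_initial": (14433.0, 18761.0),
    "cost_stage12_continuing": (-1263.0, -645.0),
    "cost_stage12_terminal": (23406.0, 38610.0),
    "cost_stage3_initial": (34688.0, 41480.0),
    "cost_stage3_continuing": (918.0, 3156.0),
    "cost_stage3_terminal": (19719.0, 28812.0),
    "cost_stage4_initial": (58185.0, 70187.0),
    "cost_stage4_continuing": (12042.0, 17275.0),
    "cost_stage4_terminal": (29089.0, 39324.0),
}

# Surveillance after polypectomy (declared default policy standing in for the
# German S3 guideline interval table): >=1 advanced lesion removed or >=3
# lesions removed -> 3 years; 1-2 non-advanced -> 5 years; clean -> routine.
SURVEILLANCE_INTERVAL_ADVANCED = 3.0
SURVEILLANCE_INTERVAL_NONADV = 5.0
FIT_SUPPRESSION_YEARS = 10.0  # no FIT offer within 10y of any colonoscopy

# --------------------------------------------------------------------------
# Published per-1,000-40-year-olds strategy means from the German evaluation
# (discounted cost in 2023 euro, discounted QALYs, lifetime CRC incidence and
# mortality).  Used as *inputs* to verify the incremental-analysis and
# frontier arithmetic; the simulation does not read them.
# --------------------------------------------------------------------------
REFERENCE_NO_SCREENING = dict(
    incidence=57.92, mortality=27.05, qalys=19107.18, cost=1_084_554.0
)

REFERENCE_STRATEGY_MEANS = {
    1: {
        "current": dict(incidence=20.83, mortality=7.56, qalys=19177.80, cost=754_393.0),
        "FIT1y45+COL10y50": dict(incidence=19.65, mortality=6.78, qalys=19185.90, cost=793_408.0),
        "FIT1y45+COL10y50-3X": dict(incidence=18.58, mortality=6.37, qalys=19185.15, cost=826_152.0),
        "FIT2y45": dict(incidence=35.77, mortality=11.34, qalys=19156.33, cost=847_507.0),
        "COL10y45-3X": dict(incidence=15.15, mortality=5.53, qalys=19205.36, cost=782_753.0),
    },
    2: {
        "current": dict(incidence=49.01, mortality=19.90, qalys=19134.57, cost=895_412.0),
        "FIT1y45+COL10y50": dict(incidence=48.46, mortality=19.67, qalys=19136.28, cost=896_663.0),
        "FIT1y45+COL10y50-3X": dict(incidence=47.74, mortality=19.42, qalys=19137.16, cost=901_810.0),
        "FIT2y45": dict(incidence=55.65, mortality=22.49, qalys=19121.85, cost=948_385.0),
        "COL10y45-3X": dict(incidence=48.13, mortality=19.64, qalys=19139.77, cost=906_330.0),
    },
    3: {
        "current": dict(incidence=41.27, mortality=16.35, qalys=19145.96, cost=883_574.0),
        "FIT1y45+COL10y50": dict(incidence=38.57, mortality=14.99, qalys=19156.37, cost=914_639.0),
        "FIT1y45+COL10y50-3X": dict(incidence=37.47, mortality=14.58, qalys=19156.05, cost=925_344.0),
        "FIT2y45": dict(incidence=45.88, mortality=16.72, qalys=19137.78, cost=1_032_285.0),
        "COL10y45-3X": dict(incidence=40.38, mortality=16.30, qalys=19155.10, cost=875_290.0),
    },
}

#: The no-screening lifetime incidence target (per 1,000 alive and CRC-free
#: at 40) the central parameter set is calibrated against.
INCIDENCE_TARGET = REFERENCE_NO_SCREENING["incidence"]
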