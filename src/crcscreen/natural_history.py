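"""Discrete-event natural history of colorectal cancer.

Each person is followed from age 20 to 90 or death.  Precursor lesions arise
from a non-homogeneous Poisson process whose piecewise-constant baseline
hazard increases in 10-year age bands and is multiplied by a person-level
log-normal frailty and a calibrated scale.  Each lesion follows either the
adenoma pathway (non-advanced adenoma -> advanced adenoma -> preclinical
carcinoma) or the serrated pathway (non-crSP -> crSP -> preclinical
carcinoma); only a pathway-specific fraction of lesions ever leaves each
precursor state, and dwell times are exponential with pathway-specific
means, serrated slower than adenoma.  Preclinical cancer becomes symptomatic
after an exponential sojourn; the stage at symptomatic diagnosis is drawn
from a four-way stage distribution, and CRC death then competes with
other-cause (life-table) death through a stage-specific excess hazard.

The entire latent course of every person — lesion onsets, scheduled
transitions, sojourn, stage variates, survival variates and other-cause
death age — is sampled up front into flat arrays (:class:`LatentCohort`).
Screening overlays (:mod:`crcscreen.screening`) then merely intercept these
latent timelines, which makes common-random-number comparisons across
strategy arms exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .params import NaturalHistoryParams

__all__ = [
    "LatentCohort",
    "LifeHistory",
    "sample_lesion_onsets",
    "progress_lesion",
    "diagnose_symptomatic",
    "sample_deaths",
    "sample_latent_histories",
    "simulate_cohort_no_screening",
]


def _cohort_rng(seed: int, draw: int = 0) -> np.random.Generator:
    """Counter-based stream for the vectorised latent-cohort sampling."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([int(seed), int(draw), 11]))
    )


@dataclass
class LatentCohort:
    """Flat-array representation of every person's latent disease course.

    Lesion arrays are sorted by person; ``offsets[i]:offsets[i+1]`` slices
    person ``i``'s lesions.  ``t_adv``/``t_precl``/``t_clin`` are ``inf`` for
    transitions that never happen; ``death_other`` is ``inf`` for persons
    surviving to the age-90 censoring horizon.
    """

    n: int
    sex: np.ndarray  # 0 male, 1 female
    frailty: np.ndarray
    death_other: np.ndarray
    offsets: np.ndarray  # len n+1
    lesion_person: np.ndarray
    onset: np.ndarray
    pathway: np.ndarray  # 0 adenoma, 1 serrated
    t_adv: np.ndarray  # age lesion becomes advanced
    t_precl: np.ndarray  # age lesion becomes preclinical carcinoma
    t_clin: np.ndarray  # age that carcinoma would surface symptomatically
    stage_sympt: np.ndarray  # 1..4
    u_stage_screen: np.ndarray  # uniform, maps to screen-detected stage
    u_surv: np.ndarray  # uniform, maps to post-diagnosis survival

    @property
    def n_lesions(self) -> int:
        return self.onset.shape[0]


@dataclass
class LifeHistory:
    """One person's dated event sequence, with or without screening events.

    ``death_cause`` is ``"crc"``, ``"other"`` or ``"censored"`` (alive at 90);
    ``dx_mode`` is ``"symptomatic"``, ``"screen"`` or ``None``.  Event lists
    are empty for a person never screened.  ``eligible`` marks persons alive
    and CRC-free at age 40 (the reporting denominator).
    """

    person: int
    sex: int
    death_age: float
    death_cause: str
    dx_age: float | None = None
    dx_stage: int = 0
    dx_mode: str | None = None
    fit_ages: list = None
    colonoscopies: list = None  # (age, kind, polypectomy, n_findings, complication)
    notifications: list = None  # invitation/reminder letter mail ages
    first_contact_age: float | None = None
    eligible: bool = True

    def __post_init__(self):
        if self.fit_ages is None:
            self.fit_ages = []
        if self.colonoscopies is None:
            self.colonoscopies = []
        if self.notifications is None:
            self.notifications = []
        if self.death_age < config.START_AGE:
            raise ValueError("death before the start of follow-up")
        if self.dx_age is not None:
            if self.dx_stage not in (1, 2, 3, 4):
                raise ValueError("diagnosis stage must be 1..4")
            if self.dx_age > self.death_age:
                raise ValueError("diagnosis after death")
        elif self.death_cause == "crc":
            raise ValueError("CRC death requires a diagnosis")


# --------------------------------------------------------------------------
# Elementary sampling operations (scalar/person-level surface; the cohort
# sampler below vectorises the same constructions)
# --------------------------------------------------------------------------

def sample_lesion_onsets(
    person_frailty: float,
    params: NaturalHistoryParams,
    sex: int,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """Sample one person's lesion onsets: ``[(onset_age, pathway), ...]``.

    Non-homogeneous Poisson process with intensity
    ``base_hazard(age) * onset_rate_scale * frailty``; each onset joins the
    adenoma pathway with probability ``adenoma_fraction``.
    """
    if person_frailty <= 0:
        raise ValueError("frailty must be positive")
    onsets = []
    for lo, hi, rate in zip(
        config.ONSET_AGE_BANDS[:-1], config.ONSET_AGE_BANDS[1:], config.BASE_ONSET_HAZARD
    ):
        lam = rate * params.onset_rate_scale * person_frailty * (hi - lo)
        count = rng.poisson(lam)
        for age in lo + (hi - lo) * rng.random(count):
            pathway = (
                config.ADENOMA
                if rng.random() < params.adenoma_fraction
                else config.SERRATED
            )
            onsets.append((float(age), pathway))
    onsets.sort()
    return onsets


def progress_lesion(
    onset_age: float,
    pathway: int,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Schedule one lesion's transitions; returns ``(t_advanced, t_preclinical)``.

    Each transition happens only with the pathway's progression probability;
    dwell times are exponential with the pathway-specific mean.  ``inf``
    marks a transition that never occurs.
    """
    if pathway == config.ADENOMA:
        mean1 = params.mean_dwell_nonadv_to_adv_adenoma
        mean2 = params.mean_dwell_adv_adenoma_to_crc
    else:
        mean1 = params.mean_dwell_noncr_to_cr_sp
        mean2 = params.mean_dwell_cr_sp_to_crc
    if rng.random() >= config.PROGRESS_PROB_NONADV[pathway]:
        return np.inf, np.inf
    t_adv = onset_age + rng.exponential(mean1)
    if rng.random() >= config.PROGRESS_PROB_ADV[pathway]:
        return t_adv, np.inf
    return t_adv, t_adv + rng.exponential(mean2)


def diagnose_symptomatic(
    preclinical_onset_age: float,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Symptomatic surfacing of a preclinical carcinoma: ``(age, stage)``."""
    age = preclinical_onset_age + rng.exponential(params.mean_sojourn)
    stage = 1 + int(
        np.searchsorted(
            np.cumsum(params.stage_dist_symptomatic[:-1]), rng.random(), side="right"
        )
    )
    return age, stage


def _life_table_cumhaz(life_table: pd.DataFrame) -> dict[int, np.ndarray]:
    """Cumulative all-cause hazard from age 20 by sex (grid at integer ages)."""
    out = {}
    for sex, label in ((config.MALE, "male"), (config.FEMALE, "female")):
        sub = life_table[life_table.sex == label].sort_values("age")
        sub = sub[(sub.age >= 20) & (sub.age < 90)]
        hazard = -np.log1p(-sub.qx.to_numpy(dtype=float))
        out[sex] = np.concatenate([[0.0], np.cumsum(hazard)])
    return out


def sample_deaths(
    n: int,
    sex: np.ndarray,
    life_table: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Other-cause death ages from the life table (``inf`` = survives to 90).

    Inverse-transform sampling on the cumulative hazard, uniform within the
    year of death.
    """
    cumhaz = _life_table_cumhaz(life_table)
    exp_draw = rng.exponential(1.0, size=n)
    frac = rng.random(n)
    death = np.full(n, np.inf)
    for s in (config.MALE, config.FEMALE):
        mask = sex == s
        ch = cumhaz[s]
        e = exp_draw[mask]
        year = np.searchsorted(ch, e, side="left")  # death during year-1
        d = np.full(mask.sum(), np.inf)
        dies = year <= len(ch) - 1
        dies &= e <= ch[-1]
        yi = np.clip(year[dies], 1, len(ch) - 1)
        d[dies] = 20.0 + (yi - 1) + frac[mask][dies]
        death[mask] = d
    return death


# --------------------------------------------------------------------------
# Vectorised cohort sampling
# --------------------------------------------------------------------------

def sample_latent_histories(
    n: int,
    params: NaturalHistoryParams,
    life_table: pd.DataFrame,
    seed: int,
    draw: int = 0,
) -> LatentCohort:
    """Sample the full latent disease course for ``n`` persons."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _cohort_rng(seed, draw)

    sex = (rng.random(n) < 0.5).astype(np.int8)
    sigma = params.frailty_sd
    frailty = rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    death_other = sample_deaths(n, sex, life_table, rng)

    # Lesion counts per person per age band (NHPP with piecewise-constant
    # intensity => independent Poisson counts per band, uniform onset within)
    band_widths = np.diff(config.ONSET_AGE_BANDS)
    lam = (
        config.BASE_ONSET_HAZARD[None, :]
        * band_widths[None, :]
        * params.onset_rate_scale
        * frailty[:, None]
    )
    counts = rng.poisson(lam)  # (n, n_bands)
    per_person = counts.sum(axis=1)
    offsets = np.concatenate([[0], np.cumsum(per_person)])
    total = int(offsets[-1])

    lesion_person = np.repeat(np.arange(n), per_person)
    onset = np.empty(total)
    # fill onsets band by band, then sort within each person by onset age
    starts = offsets[:-1].copy()
    for b in range(counts.shape[1]):
        cb = counts[:, b]
        if cb.sum() == 0:
            continue
        ages = config.ONSET_AGE_BANDS[b] + band_widths[b] * rng.random(int(cb.sum()))
        idx = np.repeat(starts, cb) + _within_offsets(cb)
        onset[idx] = ages
        starts = starts + cb
    order = np.lexsort((onset, lesion_person))
    onset = onset[order]

    pathway = (rng.random(total) >= params.adenoma_fraction).astype(np.int8)

    mean1 = np.where(
        pathway == config.ADENOMA,
        params.mean_dwell_nonadv_to_adv_adenoma,
        params.mean_dwell_noncr_to_cr_sp,
    )
    mean2 = np.where(
        pathway == config.ADENOMA,
        params.mean_dwell_adv_adenoma_to_crc,
        params.mean_dwell_cr_sp_to_crc,
    )
    p1 = np.where(
        pathway == config.ADENOMA,
        config.PROGRESS_PROB_NONADV[config.ADENOMA],
        config.PROGRESS_PROB_NONADV[config.SERRATED],
    )
    p2 = np.where(
        pathway == config.ADENOMA,
        config.PROGRESS_PROB_ADV[config.ADENOMA],
        config.PROGRESS_PROB_ADV[config.SERRATED],
    )
    progresses1 = rng.random(total) < p1
    dwell1 = rng.exponential(1.0, size=total) * mean1
    t_adv = np.where(progresses1, onset + dwell1, np.inf)
    progresses2 = (rng.random(total) < p2) & progresses1
    dwell2 = rng.exponential(1.0, size=total) * mean2
    t_precl = np.where(progresses2, t_adv + dwell2, np.inf)
    sojourn = rng.exponential(params.mean_sojourn, size=total)
    t_clin = np.where(progresses2, t_precl + sojourn, np.inf)

    stage_cum = np.cumsum(params.stage_dist_symptomatic)
    stage_sympt = (
        1 + np.searchsorted(stage_cum[:-1], rng.random(total), side="right")
    ).astype(np.int8)
    u_stage_screen = rng.random(total)
    u_surv = rng.random(total)

    return LatentCohort(
        n=n,
        sex=sex,
        frailty=frailty,
        death_other=death_other,
        offsets=offsets,
        lesion_person=lesion_person,
        onset=onset,
        pathway=pathway,
        t_adv=t_adv,
        t_precl=t_precl,
        t_clin=t_clin,
        stage_sympt=stage_sympt,
        u_stage_screen=u_stage_screen,
        u_surv=u_surv,
    )


def _within_offsets(counts: np.ndarray) -> np.ndarray:
    """0..c_i-1 runs for each count c_i, concatenated."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    out = np.arange(total) - np.repeat(ends - counts, counts)
    return out


# --------------------------------------------------------------------------
# No-screening cohort summary (fully vectorised; exact same event rules as
# the per-person screening loop with no attended offers)
# --------------------------------------------------------------------------

def _first_clinical(cohort: LatentCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per person: earliest symptomatic surfacing age, its stage, its u_surv."""
    n = cohort.n
    dx_age = np.full(n, np.inf)
    dx_stage = np.zeros(n, dtype=np.int8)
    dx_usurv = np.full(n, np.nan)
    per_person = np.diff(cohort.offsets)
    has = per_person > 0
    if not has.any():
        return dx_age, dx_stage, dx_usurv
    starts = cohort.offsets[:-1][has]
    # lesions are sorted by person; reduceat segments end at the next start,
    # empty persons contribute no elements
    dx_age[has] = np.minimum.reduceat(cohort.t_clin, starts)
    # index of the min-t_clin lesion per non-empty person: after lexsort by
    # (person, t_clin) the first row of each person's block is the argmin
    order = np.lexsort((cohort.t_clin, cohort.lesion_person))
    sorted_first = order[starts]
    dx_stage[has] = cohort.stage_sympt[sorted_first]
    dx_usurv[has] = cohort.u_surv[sorted_first]
    return dx_age, dx_stage, dx_usurv


def crc_death_age(
    dx_age: np.ndarray,
    dx_stage: np.ndarray,
    dx_usurv: np.ndarray,
    params: NaturalHistoryParams,
) -> np.ndarray:
    """Potential CRC death age: exponential excess hazard by stage at diagnosis."""
    hazards = np.asarray(params.survival_hazard_by_stage)
    out = np.full_like(dx_age, np.inf)
    mask = np.isfinite(dx_age)
    if mask.any():
        h = hazards[dx_stage[mask] - 1]
        out[mask] = dx_age[mask] - np.log(dx_usurv[mask]) / h
    return out


def summarize_outcomes(
    dx_age: np.ndarray,
    dx_stage: np.ndarray,
    death_crc: np.ndarray,
    death_other: np.ndarray,
) -> dict:
    """Per-1,000 incidence/mortality among persons alive and CRC-free at 40."""
    diagnosed = (dx_age < death_other) & (dx_age < config.END_AGE)
    crc_death = np.where(diagnosed, death_crc, np.inf)
    died_crc = diagnosed & (crc_death < death_other) & (crc_death < config.END_AGE)
    actual_death = np.minimum(death_other, crc_death)
    alive40 = actual_death > config.REFERENCE_AGE
    crc_free40 = ~(diagnosed & (dx_age <= config.REFERENCE_AGE))
    eligible = alive40 & crc_free40
    n_eligible = int(eligible.sum())
    scale = 1000.0 / n_eligible if n_eligible else np.nan
    return {
        "n_eligible": n_eligible,
        "incidence": float((diagnosed & eligible).sum() * scale),
        "mortality": float((died_crc & eligible).sum() * scale),
        "eligible_mask": eligible,
        "diagnosed_mask": diagnosed & eligible,
        "crc_death_mask": died_crc & eligible,
    }


def simulate_cohort_no_screening(
    n: int,
    params: NaturalHistoryParams,
    life_table: pd.DataFrame,
    seed: int,
    draw: int = 0,
    histories: bool = True,
):
    """Simulate ``n`` persons without screening.

    Returns ``(life_histories, summary)`` where the summary holds lifetime
    CRC incidence and mortality per 1,000 persons alive and CRC-free at 40.
    ``histories=False`` skips building per-person event logs (used by the
    calibration loop).
    """
    cohort = sample_latent_histories(n, params, life_table, seed, draw)
    dx_age, dx_stage, dx_usurv = _first_clinical(cohort)
    death_crc = crc_death_age(dx_age, dx_stage, dx_usurv, params)
    summary = summarize_outcomes(dx_age, dx_stage, death_crc, cohort.death_other)
    summary = {k: v for k, v in summary.items() if not k.endswith("_mask")} | {
        "n": n,
        "seed": seed,
    }
    if not histories:
        return None, summary

    diagnosed = (dx_age < cohort.death_other) & (dx_age < config.END_AGE)
    crc_death = np.where(diagnosed, death_crc, np.inf)
    records = []
    for i in range(n):
        dxa = dx_age[i] if diagnosed[i] else None
        death = min(cohort.death_other[i], crc_death[i])
        if death >= config.END_AGE:
            death_age, cause = config.END_AGE, "censored"
        elif crc_death[i] < cohort.death_other[i]:
            death_age, cause = float(crc_death[i]), "crc"
        else:
            death_age, cause = float(cohort.death_other[i]), "other"
        eligible = death_age > config.REFERENCE_AGE and not (
            diagnosed[i] and dx_age[i] <= config.REFERENCE_AGE
        )
        records.append(
            LifeHistory(
                person=i,
                sex=int(cohort.sex[i]),
                death_age=death_age,
                death_cause=cause,
                dx_age=float(dxa) if dxa is not None else None,
                dx_stage=int(dx_stage[i]) if diagnosed[i] else 0,
                dx_mode="symptomatic" if diagnosed[i] else None,
                eligible=bool(eligible),
            )
        )
    return records, summary


def histories_to_frame(histories) -> pd.DataFrame:
    """Tidy event log: one row per event (person, age, event, detail)."""
    rows = []
    for h in histories:
        for age in h.notifications:
            rows.append((h.person, age, "notification", ""))
        for age in h.fit_ages:
            rows.append((h.person, age, "fit", ""))
        for age, kind, polyp, nfind, compl in h.colonoscopies:
            rows.append((h.person, age, "colonoscopy", f"{kind};findings={nfind}"))
            if compl:
                rows.append((h.person, age, "complication", ""))
        if h.dx_age is not None:
            rows.append((h.person, h.dx_age, "diagnosis", f"stage={h.dx_stage};{h.dx_mode}"))
        rows.append((h.person, h.death_age, h.death_cause, ""))
    frame = pd.DataFrame(rows, columns=["person", "age", "event", "detail"])
    return frame.sort_values(["person", "age"], kind="stable").reset_index(drop=True)
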