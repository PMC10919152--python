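"""Screening overlay: strategy schedules, adherence, FIT and colonoscopy
outcomes, polypectomy, follow-up and surveillance, complications.

Test operating characteristics are state specific (non-advanced adenoma,
advanced adenoma, non-clinically-relevant and clinically relevant serrated
polyp, preclinical cancer).  A FIT is positive with the sensitivity of the
most advanced lesion present (cancer > AA > crSP > non-AA > non-crSP), or
``1 - specificity`` if the colorectum is clean.  A colonoscopy detects every
lesion independently with its state-specific sensitivity; detected
precursors are removed (polypectomy), which cancels all of that lesion's
scheduled progression events; a detected preclinical cancer becomes a
screen diagnosis with an early-shifted stage distribution.  Surveillance
after polypectomy follows a declared interval policy (3 years after an
advanced lesion or >=3 removals, 5 years after 1-2 non-advanced removals).

``run_strategy_arm`` replays the *same* latent natural histories that the
no-screening arm uses (common random numbers keyed by the cohort seed), so
paired differences between arms are pure screening effects, and an arm with
zero participation reproduces the no-screening summary exactly.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import config
from .natural_history import (
    LatentCohort,
    LifeHistory,
    sample_latent_histories,
)
from .params import NaturalHistoryParams

__all__ = [
    "Strategy",
    "AdherenceScenario",
    "TestPerformance",
    "load_strategies",
    "load_scenarios",
    "schedule_offers",
    "fit_test",
    "colonoscopy_exam",
    "adherence_decision",
    "surveillance_policy",
    "run_strategy_arm",
]

# Severity ranking used for the per-person FIT positivity rule.
_SEVERITY = {"non_crsp": 0, "non_aa": 1, "crsp": 2, "aa": 3, "cancer": 4}


class ConfigurationError(ValueError):
    """Malformed strategy/scenario/performance configuration."""


@dataclass(frozen=True)
class TestPerformance:
    """State-specific sensitivities, specificities and complication risk."""

    fit_sens: dict
    fit_specificity: float
    col_sens: dict
    col_specificity: float
    complication_prob: float

    def __post_init__(self):
        values = [self.fit_specificity, self.col_specificity, self.complication_prob]
        values += list(self.fit_sens.values()) + list(self.col_sens.values())
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ConfigurationError("test characteristics must be probabilities")

    @classmethod
    def default(cls) -> "TestPerformance":
        return cls(
            fit_sens=dict(config.FIT_SENSITIVITY),
            fit_specificity=config.FIT_SPECIFICITY,
            col_sens=dict(config.COL_SENSITIVITY),
            col_specificity=config.COL_SPECIFICITY,
            complication_prob=config.COL_COMPLICATION_PROB,
        )

    @classmethod
    def from_psa_row(cls, row) -> "TestPerformance":
        """Build from one probabilistic-sensitivity draw (see draw_psa_inputs)."""
        return cls(
            fit_sens={
                "non_aa": row["fit_sens_non_aa"],
                "aa": row["fit_sens_aa"],
                "non_crsp": row["fit_sens_non_crsp"],
                "crsp": row["fit_sens_crsp"],
                "cancer": row["fit_sens_cancer"],
            },
            fit_specificity=row["fit_specificity"],
            col_sens={
                "non_aa": row["col_sens_non_aa"],
                "aa": row["col_sens_aa"],
                "non_crsp": row["col_sens_non_crsp"],
                "crsp": row["col_sens_crsp"],
                "cancer": row["col_sens_cancer"],
            },
            col_specificity=config.COL_SPECIFICITY,
            complication_prob=row["complication_prob"],
        )


@dataclass(frozen=True)
class Strategy:
    """A named per-sex schedule of screening offers."""

    name: str
    label: str
    blocks: dict  # {"male": [block, ...], "female": [...]}

    def __post_init__(self):
        for sex_label in ("male", "female"):
            if sex_label not in self.blocks:
                raise ConfigurationError(
                    f"strategy {self.name!r}: missing offer list for {sex_label!r}"
                )
            for block in self.blocks[sex_label]:
                test = block.get("test")
                if test == "colonoscopy":
                    ages = block.get("ages")
                    if not ages or any(
                        not config.START_AGE <= a <= config.END_AGE for a in ages
                    ):
                        raise ConfigurationError(
                            f"strategy {self.name!r}: colonoscopy ages must lie in "
                            f"[20, 90], got {ages!r}"
                        )
                elif test == "fit":
                    for key in ("start", "stop", "interval"):
                        if key not in block:
                            raise ConfigurationError(
                                f"strategy {self.name!r}: FIT block missing {key!r}"
                            )
                    if block["interval"] <= 0:
                        raise ConfigurationError(
                            f"strategy {self.name!r}: FIT interval must be > 0"
                        )
                    if not (
                        config.START_AGE <= block["start"] <= block["stop"] <= config.END_AGE
                    ):
                        raise ConfigurationError(
                            f"strategy {self.name!r}: FIT ages out of range"
                        )
                else:
                    raise ConfigurationError(
                        f"strategy {self.name!r}: unknown test {test!r}"
                    )


@dataclass(frozen=True)
class AdherenceScenario:
    """Per-sex participation probabilities by screening modality.

    ``mode`` is ``"per_offer"`` (independent Bernoulli at each offer) or
    ``"persistent"`` (one Bernoulli per modality per person, reused at every
    offer).  Follow-up and surveillance decisions are always per event.
    """

    scenario_id: int
    label: str
    fit_annual: dict
    fit_biennial: dict
    fit_positive_col: float
    screening_col: dict
    surveillance_col: float
    reminders: bool = False
    mode: str = "per_offer"

    def __post_init__(self):
        probs = (
            list(self.fit_annual.values())
            + list(self.fit_biennial.values())
            + list(self.screening_col.values())
            + [self.fit_positive_col, self.surveillance_col]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("participation rates must lie in [0, 1]")
        if self.mode not in ("per_offer", "persistent"):
            raise ConfigurationError(f"unknown adherence mode {self.mode!r}")

    def rate(self, modality: str, sex: int) -> float:
        label = "male" if sex == config.MALE else "female"
        if modality == "fit_annual":
            return self.fit_annual[label]
        if modality == "fit_biennial":
            return self.fit_biennial[label]
        if modality == "screening_col":
            return self.screening_col[label]
        raise KeyError(modality)


def _read_yaml(path, default_name):
    if path is None:
        ref = resources.files("crcscreen.data").joinpath(default_name)
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_strategies(path=None) -> dict[str, Strategy]:
    """Parse the strategy file (default: bundled Table-2 fixture)."""
    raw = _read_yaml(path, "strategies.yaml")
    out = {}
    for entry in raw["strategies"]:
        if "name" not in entry:
            raise ConfigurationError("strategy entry missing 'name'")
        strategy = Strategy(
            name=entry["name"],
            label=entry.get("label", entry["name"]),
            blocks={
                "male": entry.get("male", []),
                "female": entry.get("female", []),
            },
        )
        if strategy.name in out:
            raise ConfigurationError(f"duplicate strategy name {strategy.name!r}")
        out[strategy.name] = strategy
    return out


def load_scenarios(path=None, mode: str = "per_offer") -> dict[int, AdherenceScenario]:
    """Parse the adherence-scenario file (default: bundled Table-3 fixture)."""
    raw = _read_yaml(path, "scenarios.yaml")
    out = {}
    for entry in raw["scenarios"]:
        for key in (
            "id",
            "fit_annual",
            "fit_biennial",
            "fit_positive_col",
            "screening_col",
            "surveillance_col",
        ):
            if key not in entry:
                raise ConfigurationError(f"scenario entry missing field {key!r}")
        out[entry["id"]] = AdherenceScenario(
            scenario_id=entry["id"],
            label=entry.get("label", str(entry["id"])),
            fit_annual=entry["fit_annual"],
            fit_biennial=entry["fit_biennial"],
            fit_positive_col=entry["fit_positive_col"],
            screening_col=entry["screening_col"],
            surveillance_col=entry["surveillance_col"],
            reminders=bool(entry.get("reminders", False)),
            mode=mode,
        )
    return out


# --------------------------------------------------------------------------
# Elementary operations
# --------------------------------------------------------------------------

def schedule_offers(strategy: Strategy, sex: int) -> list[tuple[float, str, str]]:
    """Ordered offer timeline for one sex: ``[(age, test, modality), ...]``.

    ``modality`` is the participation-rate channel: ``fit_annual``,
    ``fit_biennial`` or ``screening_col``.
    """
    label = "male" if sex == config.MALE else "female"
    offers = []
    for block in strategy.blocks[label]:
        if block["test"] == "colonoscopy":
            offers.extend(
                (float(age), "colonoscopy", "screening_col") for age in block["ages"]
            )
        else:
            interval = block["interval"]
            modality = "fit_annual" if interval == 1 else "fit_biennial"
            age = block["start"]
            while age <= block["stop"]:
                offers.append((float(age), "fit", modality))
                age += interval
    offers.sort()
    return offers


def fit_test(
    states: list[str], perf: TestPerformance, rng
) -> bool:
    """One FIT result. ``states`` lists the person's current lesion states.

    Positivity probability is the FIT sensitivity of the most advanced state
    present; with no lesions it is ``1 - specificity``.
    """
    if states:
        worst = max(states, key=_SEVERITY.__getitem__)
        p = perf.fit_sens[worst]
    else:
        p = 1.0 - perf.fit_specificity
    return rng.random() < p


def colonoscopy_exam(
    states: list[str], perf: TestPerformance, rng
) -> tuple[list[int], bool, bool]:
    """One colonoscopy: ``(detected lesion indices, cancer_found, complication)``.

    Every lesion is detected independently with its state-specific
    sensitivity; specificity 1 means a clean colorectum never yields a
    false finding.
    """
    detected = [
        i for i, s in enumerate(states) if rng.random() < perf.col_sens[s]
    ]
    cancer_found = any(states[i] == "cancer" for i in detected)
    complication = rng.random() < perf.complication_prob
    return detected, cancer_found, complication


def adherence_decision(
    modality: str,
    sex: int,
    scenario: AdherenceScenario,
    rng,
    persistent_cache: dict | None = None,
) -> bool:
    """Attend/decline one screening offer.

    In ``per_offer`` mode each offer is an independent Bernoulli draw; in
    ``persistent`` mode the first decision for a modality is reused for all
    later offers of that modality (``persistent_cache`` carries it).
    """
    rate = scenario.rate(modality, sex)
    if scenario.mode == "persistent" and persistent_cache is not None:
        if modality not in persistent_cache:
            persistent_cache[modality] = rng.random() < rate
        return persistent_cache[modality]
    return rng.random() < rate


def surveillance_policy(n_advanced_removed: int, n_removed: int) -> float | None:
    """Years until surveillance colonoscopy after a polypectomy, or ``None``.

    Declared default standing in for the German S3 interval table: any
    advanced lesion (AA/crSP) or >=3 removed lesions -> 3 years; 1-2
    non-advanced lesions -> 5 years; clean exam -> routine schedule.
    """
    if n_removed <= 0:
        return None
    if n_advanced_removed >= 1 or n_removed >= 3:
        return config.SURVEILLANCE_INTERVAL_ADVANCED
    return config.SURVEILLANCE_INTERVAL_NONADV


# --------------------------------------------------------------------------
# Full strategy arm
# --------------------------------------------------------------------------

def _person_rng(seed: int, draw: int, person: int) -> _pyrandom.Random:
    # CPython seeds str via SHA-512: deterministic across processes, and the
    # stream is strategy independent so arms share person-level randomness.
    return _pyrandom.Random(f"crcscreen:{seed}:{draw}:{person}")


def run_strategy_arm(
    n: int,
    params: NaturalHistoryParams,
    strategy: Strategy | None,
    scenario: AdherenceScenario,
    perf: TestPerformance,
    life_table: pd.DataFrame,
    seed: int,
    draw: int = 0,
    latent: LatentCohort | None = None,
    histories: bool = True,
):
    """Simulate one (strategy, scenario) arm over ``n`` persons.

    The latent natural histories are regenerated from ``(seed, draw)`` — or
    reused via ``latent`` — so every arm at the same seed shares person-level
    randomness with the no-screening arm.  ``strategy=None`` runs the
    no-screening arm through the identical code path.

    Returns ``(life_histories, summary)``; ``summary`` reports per-1,000
    (alive and CRC-free at 40) lifetime CRC incidence and mortality, total
    colonoscopies split by purpose (screening / FIT-positive follow-up /
    surveillance), complications, and FIT false-positive diagnostics.
    """
    if latent is None:
        latent = sample_latent_histories(n, params, life_table, seed, draw)
    elif latent.n != n:
        raise ValueError("latent cohort size does not match n")

    offers_by_sex = (
        {s: schedule_offers(strategy, s) for s in (config.MALE, config.FEMALE)}
        if strategy is not None
        else {config.MALE: [], config.FEMALE: []}
    )

    # flat python lists: scalar indexing is much faster than ndarray item access
    onset_l = latent.onset.tolist()
    pathway_l = latent.pathway.tolist()
    t_adv_l = latent.t_adv.tolist()
    t_precl_l = latent.t_precl.tolist()
    t_clin_l = latent.t_clin.tolist()
    stage_sympt_l = latent.stage_sympt.tolist()
    u_stage_screen_l = latent.u_stage_screen.tolist()
    u_surv_l = latent.u_surv.tolist()
    death_other_l = latent.death_other.tolist()
    sex_l = latent.sex.tolist()
    offsets = latent.offsets

    fs = perf.fit_sens
    fit_sens_by_rank = (
        fs["non_crsp"], fs["non_aa"], fs["crsp"], fs["aa"], fs["cancer"]
    )
    fit_fp_rate = 1.0 - perf.fit_specificity
    cs = perf.col_sens
    col_sens_nonadv = (cs["non_aa"], cs["non_crsp"])  # by pathway
    col_sens_adv = (cs["aa"], cs["crsp"])
    col_sens_cancer = cs["cancer"]
    compl_prob = perf.complication_prob
    hazards = tuple(params.survival_hazard_by_stage)
    screen_cum = tuple(np.cumsum(params.stage_dist_screen).tolist())
    suppress = config.FIT_SUPPRESSION_YEARS
    end_cap = config.END_AGE
    ref_age = config.REFERENCE_AGE
    surv_rate = scenario.surveillance_col
    fu_rate = scenario.fit_positive_col
    reminders = scenario.reminders
    per_offer = scenario.mode == "per_offer"
    ADEN = config.ADENOMA
    inf = math.inf

    records = [] if histories else None
    n_elig = 0
    n_dx = n_crc_death = 0
    col_counts = {"screening": 0, "followup": 0, "surveillance": 0}
    n_compl = 0
    n_fit = 0
    n_fit_clean = 0  # FIT tests performed on lesion-free persons
    n_fit_clean_pos = 0
    n_polypectomy = 0

    for i in range(n):
        s, e = offsets[i], offsets[i + 1]
        death_o = death_other_l[i]
        end = death_o if death_o < end_cap else end_cap
        sexi = sex_l[i]
        offers = offers_by_sex[sexi]

        removed = set()
        # earliest symptomatic surfacing among non-removed lesions
        min_clin = inf
        min_arg = -1
        for j in range(s, e):
            v = t_clin_l[j]
            if v < min_clin:
                min_clin = v
                min_arg = j

        dx_age = None
        dx_stage = 0
        dx_mode = None
        dx_usurv = 1.0
        fits = []
        cols = []
        notifications = []
        first_contact = None
        pending_surv = inf
        last_col = -inf
        cache = {} if not per_offer else None
        rng = _person_rng(seed, draw, i) if offers else None

        oi = 0
        n_offers = len(offers)
        while True:
            t_offer = offers[oi][0] if oi < n_offers else inf
            t_event = pending_surv if pending_surv < t_offer else t_offer
            if t_event == inf:
                break
            if min_clin <= t_event or t_event >= end:
                break

            if pending_surv < t_offer:
                t = pending_surv
                pending_surv = inf
                if rng is None:
                    rng = _person_rng(seed, draw, i)
                if rng.random() >= surv_rate:
                    continue  # declined: back to the routine schedule
                kind = "surveillance"
            else:
                oi += 1
                t, test, modality = offers[oi - 1]
                if t - last_col < suppress:
                    continue  # colonoscopy within the last 10 years
                notifications.append(t)
                if test == "fit" and reminders:
                    notifications.append(t)  # reminder letter, scenario 3
                if per_offer:
                    attend = rng.random() < scenario.rate(modality, sexi)
                else:
                    if modality not in cache:
                        cache[modality] = rng.random() < scenario.rate(modality, sexi)
                    attend = cache[modality]
                if not attend:
                    continue
                if first_contact is None:
                    first_contact = t
                if test == "fit":
                    fits.append(t)
                    n_fit += 1
                    best = -1
                    for j in range(s, e):
                        if j in removed or onset_l[j] > t:
                            continue
                        if t_precl_l[j] <= t:
                            best = 4
                            break
                        if t_adv_l[j] <= t:
                            rank = 3 if pathway_l[j] == ADEN else 2
                        else:
                            rank = 1 if pathway_l[j] == ADEN else 0
                        if rank > best:
                            best = rank
                    if best < 0:
                        n_fit_clean += 1
                        positive = rng.random() < fit_fp_rate
                        if positive:
                            n_fit_clean_pos += 1
                    else:
                        positive = rng.random() < fit_sens_by_rank[best]
                    if not positive:
                        continue
                    if rng.random() >= fu_rate:
                        continue  # FIT positive but follow-up declined
                    kind = "followup"
                else:
                    kind = "screening"

            # ---- colonoscopy at age t (kind set above) ----
            col_counts[kind] += 1
            complication = rng.random() < compl_prob
            if complication:
                n_compl += 1
            n_rem = 0
            n_adv_rem = 0
            cancer_j = -1
            cancer_t = inf
            for j in range(s, e):
                if j in removed or onset_l[j] > t:
                    continue
                tp = t_precl_l[j]
                if tp <= t:
                    if rng.random() < col_sens_cancer and tp < cancer_t:
                        cancer_j = j
                        cancer_t = tp
                elif t_adv_l[j] <= t:
                    if rng.random() < col_sens_adv[pathway_l[j]]:
                        removed.add(j)
                        n_rem += 1
                        n_adv_rem += 1
                else:
                    if rng.random() < col_sens_nonadv[pathway_l[j]]:
                        removed.add(j)
                        n_rem += 1
            last_col = t
            n_findings = n_rem + (1 if cancer_j >= 0 else 0)
            cols.append((t, kind, n_rem > 0, n_findings, complication))
            if n_rem:
                n_polypectomy += 1
            if cancer_j >= 0:
                u = u_stage_screen_l[cancer_j]
                stage = 1
                while stage < 4 and u >= screen_cum[stage - 1]:
                    stage += 1
                dx_age = t
                dx_stage = stage
                dx_mode = "screen"
                dx_usurv = u_surv_l[cancer_j]
                break
            if n_rem:
                # removal cancels the lesion's scheduled progression
                min_clin = inf
                min_arg = -1
                for j in range(s, e):
                    if j in removed:
                        continue
                    v = t_clin_l[j]
                    if v < min_clin:
                        min_clin = v
                        min_arg = j
                interval = surveillance_policy(n_adv_rem, n_rem)
                if interval is not None:
                    pending_surv = t + interval

        # ---- resolve diagnosis and death ----
        if dx_age is None and min_clin < end:
            dx_age = min_clin
            dx_stage = stage_sympt_l[min_arg]
            dx_mode = "symptomatic"
            dx_usurv = u_surv_l[min_arg]
        if dx_age is not None:
            death_crc = dx_age - math.log(dx_usurv) / hazards[dx_stage - 1]
        else:
            death_crc = inf
        death = death_crc if death_crc < death_o else death_o
        if death >= end_cap:
            death_age, cause = end_cap, "censored"
        elif death_crc < death_o:
            death_age, cause = death_crc, "crc"
        else:
            death_age, cause = death_o, "other"

        eligible = death_age > ref_age and not (
            dx_age is not None and dx_age <= ref_age
        )
        if eligible:
            n_elig += 1
            if dx_age is not None:
                n_dx += 1
            if cause == "crc":
                n_crc_death += 1

        if histories:
            records.append(
                LifeHistory(
                    person=i,
                    sex=sexi,
                    death_age=death_age,
                    death_cause=cause,
                    dx_age=dx_age,
                    dx_stage=dx_stage,
                    dx_mode=dx_mode,
                    fit_ages=fits,
                    colonoscopies=cols,
                    notifications=notifications,
                    first_contact_age=first_contact,
                    eligible=eligible,
                )
            )

    scale = 1000.0 / n_elig if n_elig else float("nan")
    total_cols = sum(col_counts.values())
    summary = {
        "strategy": strategy.name if strategy is not None else "no_screening",
        "scenario": scenario.scenario_id,
        "n": n,
        "seed": seed,
        "n_eligible": n_elig,
        "incidence": n_dx * scale,
        "mortality": n_crc_death * scale,
        "colonoscopies": total_cols * scale,
        "colonoscopies_screening": col_counts["screening"] * scale,
        "colonoscopies_followup": col_counts["followup"] * scale,
        "colonoscopies_surveillance": col_counts["surveillance"] * scale,
        "complications": n_compl * scale,
        "complications_per_colonoscopy": (n_compl / total_cols) if total_cols else 0.0,
        "fit_tests": n_fit * scale,
        "fit_tests_lesion_free": n_fit_clean,
        "fit_positives_lesion_free": n_fit_clean_pos,
        "polypectomies": n_polypectomy * scale,
    }
    return records, summary


def null_scenario() -> AdherenceScenario:
    """A zero-participation scenario (useful for null-equivalence checks)."""
    zero = {"male": 0.0, "female": 0.0}
    return AdherenceScenario(
        scenario_id=0,
        label="no participation",
        fit_annual=dict(zero),
        fit_biennial=dict(zero),
        fit_positive_col=0.0,
        screening_col=dict(zero),
        surveillance_col=0.0,
    )
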