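"""Natural-history parameter sets, posterior-style draws, PSA input draws,
and the 1-D incidence calibration.

The published model ran every screening strategy under 1,000 posterior
parameter sets from a Bayesian calibration that is not publicly deposited.
This module emulates that uncertainty: a declared central parameter set is
jittered by independent log-normal perturbations (default CV 0.10), and its
overall lesion-onset scale is calibrated by bisection so the no-screening
arm reproduces the published lifetime CRC incidence of 57.92 per 1,000
40-year-olds.  No posterior correlation structure is emulated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config

logger = logging.getLogger("crcscreen")

__all__ = [
    "NaturalHistoryParams",
    "CalibrationError",
    "central_params",
    "generate_posterior_draws",
    "calibrate_onset_scale",
    "draw_psa_inputs",
    "write_draws",
    "read_draws",
]


class CalibrationError(RuntimeError):
    """Raised when the onset-scale bisection cannot bracket the target."""


# Fields perturbed by the posterior-style jitter (positive reals only; the
# pathway dwell-time ordering is re-imposed after jitter).
_JITTER_FIELDS = (
    "onset_rate_scale",
    "frailty_sd",
    "mean_dwell_nonadv_to_adv_adenoma",
    "mean_dwell_adv_adenoma_to_crc",
    "mean_dwell_noncr_to_cr_sp",
    "mean_dwell_cr_sp_to_crc",
    "mean_sojourn",
)


@dataclass(frozen=True)
class NaturalHistoryParams:
    """One posterior-style draw of the disease natural history.

    Rates and dwell means are strictly positive; stage distributions sum to
    one; serrated-pathway dwell means are at least the corresponding
    adenoma-pathway means (serrated lesions dwell longer).
    """

    onset_rate_scale: float
    frailty_sd: float
    adenoma_fraction: float
    mean_dwell_nonadv_to_adv_adenoma: float
    mean_dwell_adv_adenoma_to_crc: float
    mean_dwell_noncr_to_cr_sp: float
    mean_dwell_cr_sp_to_crc: float
    mean_sojourn: float
    stage_dist_symptomatic: tuple = (0.25, 0.25, 0.25, 0.25)
    stage_dist_screen: tuple = (0.25, 0.25, 0.25, 0.25)
    survival_hazard_by_stage: tuple = (0.01, 0.03, 0.08, 0.45)

    def __post_init__(self):
        for name in _JITTER_FIELDS:
            value = getattr(self, name)
            if not value >= 0 or (name != "onset_rate_scale" and value == 0):
                raise ValueError(f"{name} must be positive, got {value!r}")
        if not 0.0 <= self.adenoma_fraction <= 1.0:
            raise ValueError("adenoma_fraction must be a probability")
        for name in ("stage_dist_symptomatic", "stage_dist_screen"):
            dist = np.asarray(getattr(self, name), dtype=float)
            if dist.shape != (4,) or abs(dist.sum() - 1.0) > 1e-9 or (dist < 0).any():
                raise ValueError(f"{name} must be a 4-vector summing to 1")
        if any(h <= 0 for h in self.survival_hazard_by_stage):
            raise ValueError("survival hazards must be positive")
        if self.mean_dwell_noncr_to_cr_sp < self.mean_dwell_nonadv_to_adv_adenoma:
            raise ValueError("serrated non-adv dwell must be >= adenoma dwell")
        if self.mean_dwell_cr_sp_to_crc < self.mean_dwell_adv_adenoma_to_crc:
            raise ValueError("serrated advanced dwell must be >= adenoma dwell")

    def replace(self, **kwargs) -> "NaturalHistoryParams":
        return dataclasses.replace(self, **kwargs)


def central_params(**overrides) -> NaturalHistoryParams:
    """The declared central natural-history parameter set."""
    values = dict(config.CENTRAL_PARAM_VALUES)
    values.update(overrides)
    return NaturalHistoryParams(**values)


def generate_posterior_draws(
    n_draws: int,
    seed: int,
    center: NaturalHistoryParams | None = None,
    cv: float = config.POSTERIOR_JITTER_CV,
) -> list[NaturalHistoryParams]:
    """Emulate posterior parameter draws by log-normal jitter around a center.

    Each positive-real field is multiplied by an independent
    ``LogNormal(-sigma^2/2, sigma)`` factor (mean 1) with
    ``sigma = sqrt(log(1 + cv^2))``; ``cv=0`` returns exact copies of the
    central set.  Stage distributions and the adenoma fraction are kept at
    their central values.  Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    center = center or central_params()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
    sigma = float(np.sqrt(np.log1p(cv**2)))
    draws = []
    for _ in range(n_draws):
        values = {f: getattr(center, f) for f in _JITTER_FIELDS}
        if sigma > 0:
            factors = rng.lognormal(-0.5 * sigma**2, sigma, size=len(_JITTER_FIELDS))
            values = {f: v * x for (f, v), x in zip(values.items(), factors)}
        # re-impose the pathway dwell ordering after independent jitter
        values["mean_dwell_noncr_to_cr_sp"] = max(
            values["mean_dwell_noncr_to_cr_sp"],
            values["mean_dwell_nonadv_to_adv_adenoma"],
        )
        values["mean_dwell_cr_sp_to_crc"] = max(
            values["mean_dwell_cr_sp_to_crc"],
            values["mean_dwell_adv_adenoma_to_crc"],
        )
        draws.append(center.replace(**values))
    return draws


def calibrate_onset_scale(
    params: NaturalHistoryParams,
    target_incidence: float = config.INCIDENCE_TARGET,
    n_persons: int = 20_000,
    seed: int = 0,
    tol: float = 0.02,
    max_doublings: int = 12,
    max_iter: int = 40,
) -> NaturalHistoryParams:
    """Bisect ``onset_rate_scale`` until the simulated no-screening lifetime
    CRC incidence (per 1,000 alive and CRC-free at 40) hits ``target_incidence``.

    Every evaluation reuses the same cohort seed, so the objective is a
    monotone (step) function of the scale and bisection is well posed.  The
    residual at convergence is bounded by ``tol`` relative to the target, up
    to Monte-Carlo granularity at ``n_persons``.
    """
    from .natural_history import simulate_cohort_no_screening

    if target_incidence <= 0:
        raise ValueError("target_incidence must be positive")
    life_table = config.load_life_table()

    def incidence(scale: float) -> float:
        p = params.replace(onset_rate_scale=scale)
        _, summary = simulate_cohort_no_screening(
            n_persons, p, life_table, seed=seed, histories=False
        )
        return summary["incidence"]

    lo = hi = params.onset_rate_scale
    f = incidence(lo)
    if f < target_incidence:
        for _ in range(max_doublings):
            hi *= 2.0
            f = incidence(hi)
            if f >= target_incidence:
                break
        else:
            raise CalibrationError(
                f"no bracket after {max_doublings} doublings (incidence {f:.2f})"
            )
    else:
        for _ in range(max_doublings):
            lo /= 2.0
            f = incidence(lo)
            if f <= target_incidence:
                break
        else:
            raise CalibrationError(
                f"no bracket after {max_doublings} halvings (incidence {f:.2f})"
            )
    logger.info("calibration bracket: scale in [%.4f, %.4f]", lo, hi)

    best_scale, best_err = None, np.inf
    for iteration in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = incidence(mid)
        err = abs(f - target_incidence) / target_incidence
        if err < best_err:
            best_scale, best_err = mid, err
        if err <= tol:
            logger.info(
                "calibration converged at scale %.4f (incidence %.2f) "
                "after %d bisections",
                mid,
                f,
                iteration + 1,
            )
            return params.replace(onset_rate_scale=mid)
        if f < target_incidence:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "calibration hit iteration cap; best relative residual %.3f", best_err
    )
    return params.replace(onset_rate_scale=best_scale)


def draw_psa_inputs(
    n: int, seed: int, ranges: dict[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Uniform probabilistic-sensitivity draws, one column per varied input.

    Every value is drawn ``Uniform(lower, upper)`` independently across rows
    and draws.  Screening unit costs are not varied and therefore have no
    range here.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranges = dict(config.PSA_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"inverted PSA range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 57]))
    data = {
        name: rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, float(lo))
        for name, (lo, hi) in ranges.items()
    }
    frame = pd.DataFrame(data)
    frame.index.name = "draw"
    return frame


# --------------------------------------------------------------------------
# Flat-text serialization of parameter draws
# --------------------------------------------------------------------------

def _to_row(p: NaturalHistoryParams) -> dict:
    row = {f: getattr(p, f) for f in _JITTER_FIELDS}
    row["adenoma_fraction"] = p.adenoma_fraction
    for i in range(4):
        row[f"stage_sympt_{i + 1}"] = p.stage_dist_symptomatic[i]
        row[f"stage_screen_{i + 1}"] = p.stage_dist_screen[i]
        row[f"surv_hazard_{i + 1}"] = p.survival_hazard_by_stage[i]
    return row


def write_draws(draws: list[NaturalHistoryParams], path, seed: int | None = None):
    """Write parameter draws as CSV, one record per draw, seed in the header."""
    frame = pd.DataFrame([_to_row(p) for p in draws])
    with open(path, "w") as fh:
        fh.write(f"# crcscreen natural-history draws; seed={seed}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_draws(path) -> list[NaturalHistoryParams]:
    frame = pd.read_csv(path, comment="#")
    draws = []
    for _, row in frame.iterrows():
        draws.append(
            NaturalHistoryParams(
                **{f: float(row[f]) for f in _JITTER_FIELDS},
                adenoma_fraction=float(row["adenoma_fraction"]),
                stage_dist_symptomatic=tuple(
                    float(row[f"stage_sympt_{i + 1}"]) for i in range(4)
                ),
                stage_dist_screen=tuple(
                    float(row[f"stage_screen_{i + 1}"]) for i in range(4)
                ),
                survival_hazard_by_stage=tuple(
                    float(row[f"surv_hazard_{i + 1}"]) for i in range(4)
                ),
            )
        )
    return draws
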