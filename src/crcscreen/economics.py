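"""Lifetime discounted costs and QALYs for one simulated life history.

Costs take the healthcare-system perspective in 2023 euro: screening costs
(invitation letters, a one-off consultation, FIT kits and processing,
colonoscopy with or without polypectomy, pathology per biopsied finding,
complication treatment) plus CRC treatment costs by stage group and care
phase (initial / continuing / terminal annual costs multiplied by fractional
phase durations).  Quality weights: a baseline utility accrues from the
reference age (40) until diagnosis, phase-specific utilities thereafter, and
small per-event utility losses are charged at the event age (FIT result
wait, colonoscopy, polypectomy-result wait, complications).

Everything is discounted to age 40 at an annual rate (default 3%): point
quantities by ``(1+r)^-(age-40)``, continuous flows by the exact integral of
that factor over the interval.  Events before age 40 accrue nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import config
from .natural_history import LifeHistory

__all__ = [
    "EconInputs",
    "PersonEconomics",
    "discount",
    "discount_flow",
    "phase_decomposition",
    "accrue_person",
    "aggregate_economics",
]


@dataclass(frozen=True)
class EconInputs:
    """Unit costs, treatment costs, utilities, utility losses, discounting."""

    unit_costs: dict
    treatment_costs: dict  # {"stage12"|"stage3"|"stage4": {phase: annual cost}}
    utilities: dict
    utility_losses: dict
    discount_rate: float = config.DISCOUNT_RATE
    reference_age: float = config.REFERENCE_AGE

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        for name, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {name!r} outside [0, 1]")
        for name, d in self.utility_losses.items():
            if d < 0:
                raise ValueError(f"utility loss {name!r} negative")

    @classmethod
    def default(cls) -> "EconInputs":
        return cls(
            unit_costs=dict(config.UNIT_COSTS),
            treatment_costs={k: dict(v) for k, v in config.TREATMENT_COSTS.items()},
            utilities=dict(config.UTILITIES),
            utility_losses=dict(config.UTILITY_LOSSES),
        )

    @classmethod
    def from_psa_row(cls, row) -> "EconInputs":
        """Build from one probabilistic-sensitivity draw (screening unit
        costs stay fixed; complication treatment, stage/phase treatment
        costs, utilities and losses vary)."""
        unit_costs = dict(config.UNIT_COSTS)
        unit_costs["complication"] = float(row["cost_complication"])
        treatment = {
            group: {
                phase: float(row[f"cost_{group}_{phase}"])
                for phase in ("initial", "continuing", "terminal")
            }
            for group in ("stage12", "stage3", "stage4")
        }
        return cls(
            unit_costs=unit_costs,
            treatment_costs=treatment,
            utilities=dict(
                baseline=float(row["utility_baseline"]),
                initial=float(row["utility_initial"]),
                continuing_stage13=float(row["utility_continuing_stage13"]),
                continuing_stage4=float(row["utility_continuing_stage4"]),
                terminal=float(row["utility_terminal"]),
            ),
            utility_losses=dict(
                colonoscopy=float(row["loss_colonoscopy"]),
                fit_wait=float(row["loss_fit_wait"]),
                polypectomy_wait=float(row["loss_polypectomy_wait"]),
                complication=float(row["loss_complication"]),
            ),
        )


@dataclass
class PersonEconomics:
    """Discounted totals with a component breakdown that sums to them."""

    cost: float = 0.0
    qalys: float = 0.0
    cost_screening: float = 0.0
    cost_complications: float = 0.0
    cost_treatment: float = 0.0
    qaly_life_years: float = 0.0
    qaly_losses: float = 0.0  # total per-event disutility (subtracted)
    negative_qaly_flag: bool = False
    included: bool = True


def discount(
    amount: float,
    event_age: float,
    rate: float = config.DISCOUNT_RATE,
    ref_age: float = config.REFERENCE_AGE,
) -> float:
    """Present value at ``ref_age`` of a point amount at ``event_age``."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if event_age < ref_age:
        return 0.0
    return amount / (1.0 + rate) ** (event_age - ref_age)


def discount_flow(
    rate_per_year: float,
    start_age: float,
    stop_age: float,
    rate: float = config.DISCOUNT_RATE,
    ref_age: float = config.REFERENCE_AGE,
) -> float:
    """Present value of a constant flow over ``[start_age, stop_age]``.

    Exact integral of ``(1+rate)^-(t-ref_age)``; intervals before
    ``ref_age`` contribute nothing.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    a = max(start_age, ref_age)
    b = max(stop_age, ref_age)
    if b <= a:
        return 0.0
    if rate == 0.0:
        return rate_per_year * (b - a)
    log1p = math.log1p(rate)
    return (
        rate_per_year
        * ((1.0 + rate) ** -(a - ref_age) - (1.0 + rate) ** -(b - ref_age))
        / log1p
    )


def phase_decomposition(
    diagnosis_age: float, death_age: float, death_cause: str
) -> tuple[float, float, float]:
    """Split post-diagnosis survival into (initial, continuing, terminal) years.

    Initial phase is the first 12 months after diagnosis; the terminal phase
    is the last 12 months before death *if* the death is from CRC (non-CRC
    deaths and censoring have no terminal phase).  When survival is shorter
    than 24 months the phases truncate in the order terminal > initial.
    """
    if death_age < diagnosis_age:
        raise ValueError("death before diagnosis")
    survival = death_age - diagnosis_age
    if death_cause == "crc":
        terminal = min(1.0, survival)
        initial = min(1.0, survival - terminal)
    else:
        terminal = 0.0
        initial = min(1.0, survival)
    continuing = survival - initial - terminal
    return initial, continuing, terminal


def _stage_group(stage: int) -> str:
    return {1: "stage12", 2: "stage12", 3: "stage3", 4: "stage4"}[stage]


def accrue_person(history: LifeHistory, econ: EconInputs) -> PersonEconomics:
    """Discounted lifetime cost and QALYs for one completed life history.

    Persons dead or diagnosed before the reference age are excluded
    (``included=False``, zero accrual), matching the per-1,000-40-year-olds
    reporting convention.
    """
    rate = econ.discount_rate
    ref = econ.reference_age
    out = PersonEconomics()
    if not history.eligible:
        out.included = False
        return out
    if history.death_age > config.END_AGE + 1e-9:
        raise ValueError("life history extends past the censoring horizon")

    uc = econ.unit_costs
    losses = econ.utility_losses

    # --- screening costs and event disutilities ---
    cost_screen = 0.0
    cost_compl = 0.0
    disutility = 0.0
    for age in history.notifications:
        cost_screen += discount(uc["notification"], age, rate, ref)
    if history.first_contact_age is not None:
        cost_screen += discount(uc["consultation"], history.first_contact_age, rate, ref)
    for age in history.fit_ages:
        cost_screen += discount(uc["fit_kit"] + uc["fit_processing"], age, rate, ref)
        disutility += discount(losses["fit_wait"], age, rate, ref)
    for age, _kind, polypectomy, n_findings, complication in history.colonoscopies:
        base = uc["colonoscopy_polypectomy"] if polypectomy else uc["colonoscopy"]
        cost_screen += discount(base + uc["pathology"] * n_findings, age, rate, ref)
        disutility += discount(losses["colonoscopy"], age, rate, ref)
        if polypectomy:
            disutility += discount(losses["polypectomy_wait"], age, rate, ref)
        if complication:
            cost_compl += discount(uc["complication"], age, rate, ref)
            disutility += discount(losses["complication"], age, rate, ref)

    # --- treatment costs and utility timeline ---
    u = econ.utilities
    cost_treat = 0.0
    qaly_life = 0.0
    death = history.death_age
    if history.dx_age is None:
        qaly_life += discount_flow(u["baseline"], ref, death, rate, ref)
    else:
        dx = history.dx_age
        qaly_life += discount_flow(u["baseline"], ref, dx, rate, ref)
        initial, continuing, terminal = phase_decomposition(
            dx, death, history.death_cause
        )
        group = econ.treatment_costs[_stage_group(history.dx_stage)]
        u_cont = (
            u["continuing_stage4"] if history.dx_stage == 4 else u["continuing_stage13"]
        )
        segments = (
            (dx, dx + initial, u["initial"], group["initial"]),
            (dx + initial, dx + initial + continuing, u_cont, group["continuing"]),
            (death - terminal, death, u["terminal"], group["terminal"]),
        )
        for a, b, util, annual_cost in segments:
            qaly_life += discount_flow(util, a, b, rate, ref)
            cost_treat += discount_flow(annual_cost, a, b, rate, ref)

    out.cost_screening = cost_screen
    out.cost_complications = cost_compl
    out.cost_treatment = cost_treat
    out.cost = cost_screen + cost_compl + cost_treat
    out.qaly_life_years = qaly_life
    out.qaly_losses = disutility
    out.qalys = qaly_life - disutility
    out.negative_qaly_flag = out.qalys < 0
    return out


def aggregate_economics(histories, econ: EconInputs) -> dict:
    """Per-1,000 (alive and CRC-free at 40) discounted cost and QALY totals."""
    total_cost = total_qalys = 0.0
    n_included = 0
    for h in histories:
        pe = accrue_person(h, econ)
        if pe.included:
            n_included += 1
            total_cost += pe.cost
            total_qalys += pe.qalys
    scale = 1000.0 / n_included if n_included else float("nan")
    return {
        "n_included": n_included,
        "cost": total_cost * scale,
        "qalys": total_qalys * scale,
    }
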