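"""Cost-effectiveness analysis: incremental comparison against a comparator,
efficiency frontier with extended dominance, net health benefit,
cost-effectiveness acceptability curves, and a Monte-Carlo ICER cloud.

Conventions: the ICER is incremental discounted cost over incremental
discounted QALYs.  A strategy that is cheaper *and* more effective than the
comparator is *dominant* (its ICER is negative and reported alongside the
flag); one that is costlier and less effective is *dominated* (no ICER).
The efficiency frontier drops strictly dominated strategies and then
extendedly dominated ones, leaving a strictly increasing ICER sequence
along increasing cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrategyResult",
    "CEARow",
    "incremental_vs_comparator",
    "efficiency_frontier",
    "nhb",
    "ceac",
    "icer_monte_carlo",
]


@dataclass
class StrategyResult:
    """Per-1,000-40-year-olds outcomes of one strategy under one scenario."""

    name: str
    scenario: int | str = ""
    incidence: float = float("nan")
    mortality: float = float("nan")
    qalys: float = float("nan")
    cost: float = float("nan")
    colonoscopies: float = float("nan")
    complications: float = float("nan")
    draw_costs: np.ndarray | None = None  # per posterior/PSA draw, for CEAC
    draw_qalys: np.ndarray | None = None

    def __post_init__(self):
        for name in ("qalys", "cost"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CEARow:
    """One strategy's incremental results against the comparator."""

    strategy: str
    d_cost: float
    d_qalys: float
    icer: float  # nan when dominated
    status: str  # "icer" | "dominant" | "dominated"
    d_colonoscopies: float = float("nan")
    incidence_reduction: float = float("nan")
    mortality_reduction: float = float("nan")

    @property
    def icer_rounded(self) -> float:
        """ICER to the nearest euro (reporting precision)."""
        return float("nan") if np.isnan(self.icer) else round(self.icer)


def incremental_vs_comparator(
    results: list[StrategyResult], comparator: str
) -> list[CEARow]:
    """Incremental cost, QALYs, ICER/dominance, colonoscopies and
    incidence/mortality reductions of every strategy against ``comparator``.

    The comparator's own (all-zero) row is omitted.
    """
    by_name = {r.name: r for r in results}
    if comparator not in by_name:
        raise ValueError(f"comparator {comparator!r} not among results")
    base = by_name[comparator]
    rows = []
    for r in results:
        if r.name == comparator:
            continue
        d_cost = r.cost - base.cost
        d_qalys = r.qalys - base.qalys
        if d_cost > 0 and d_qalys < 0:
            status, icer = "dominated", float("nan")
        elif d_cost < 0 and d_qalys > 0:
            status, icer = "dominant", d_cost / d_qalys  # negative by construction
        elif d_qalys == 0:
            status, icer = "dominated" if d_cost > 0 else "icer", float("nan")
        else:
            status, icer = "icer", d_cost / d_qalys
        rows.append(
            CEARow(
                strategy=r.name,
                d_cost=d_cost,
                d_qalys=d_qalys,
                icer=icer,
                status=status,
                d_colonoscopies=r.colonoscopies - base.colonoscopies,
                incidence_reduction=base.incidence - r.incidence,
                mortality_reduction=base.mortality - r.mortality,
            )
        )
    return rows


def efficiency_frontier(results: list[StrategyResult]) -> list[StrategyResult]:
    """The efficient subset, ordered by increasing cost.

    Strictly dominated strategies (another strategy is at least as cheap and
    at least as effective, strictly better in one) are dropped first, then
    extendedly dominated ones (pairwise ICER to the previous frontier point
    larger than the next step's), leaving strictly increasing ICERs.
    """
    if not results:
        return []
    candidates = []
    for r in results:
        dominated = any(
            (o.cost <= r.cost and o.qalys >= r.qalys)
            and (o.cost < r.cost or o.qalys > r.qalys)
            for o in results
            if o is not r
        )
        if not dominated:
            candidates.append(r)
    candidates.sort(key=lambda r: (r.cost, -r.qalys))
    # drop duplicates on (cost, qalys) to keep the walk well defined
    unique = []
    for r in candidates:
        if unique and r.cost == unique[-1].cost and r.qalys == unique[-1].qalys:
            continue
        unique.append(r)
    # extended dominance: keep the lower-left convex hull
    frontier: list[StrategyResult] = []
    for r in unique:
        while len(frontier) >= 2:
            a, b = frontier[-2], frontier[-1]
            icer_ab = (b.cost - a.cost) / (b.qalys - a.qalys)
            icer_br = (r.cost - b.cost) / (r.qalys - b.qalys)
            if icer_br <= icer_ab:
                frontier.pop()  # b extendedly dominated
            else:
                break
        frontier.append(r)
    return frontier


def nhb(cost: float, qalys: float, wtp: float) -> float:
    """Net health benefit in QALYs at willingness-to-pay ``wtp`` (euro/QALY)."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return qalys - cost / wtp


def ceac(
    results: list[StrategyResult],
    wtp_grid,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    For each WTP value, the probability that a strategy is cost-effective is
    the fraction of aligned per-draw (cost, QALY) pairs in which it attains
    the strictly highest net health benefit; exact ties split their draw
    equally.  At WTP 0 the cheapest strategy wins (cost-minimization limit).
    Columns (over strategies) sum to one at every WTP.
    """
    if len(results) < 2:
        raise ValueError("CEAC needs at least two strategies")
    lengths = set()
    for r in results:
        if r.draw_costs is None or r.draw_qalys is None:
            raise ValueError(f"strategy {r.name!r} has no per-draw results")
        if len(r.draw_costs) != len(r.draw_qalys):
            raise ValueError(f"strategy {r.name!r}: misaligned draw vectors")
        lengths.add(len(r.draw_costs))
    if len(lengths) != 1:
        raise ValueError("per-draw vectors differ in length across strategies")

    costs = np.vstack([np.asarray(r.draw_costs, dtype=float) for r in results])
    qalys = np.vstack([np.asarray(r.draw_qalys, dtype=float) for r in results])
    n_draws = costs.shape[1]
    names = [r.name for r in results]
    rows = []
    for wtp in wtp_grid:
        benefit = -costs if wtp == 0 else qalys - costs / wtp
        best = benefit.max(axis=0)
        winners = benefit == best[None, :]
        weights = winners / winners.sum(axis=0)[None, :]
        probs = weights.sum(axis=1) / n_draws
        for name, p in zip(names, probs):
            rows.append((name, float(wtp), float(p)))
    return pd.DataFrame(rows, columns=["strategy", "wtp", "probability"])


def icer_monte_carlo(
    d_cost_mean: float,
    d_cost_ci: tuple[float, float],
    d_qalys_mean: float,
    d_qalys_ci: tuple[float, float],
    n: int = 1000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo cloud on the cost-effectiveness plane.

    ``n`` (d_cost, d_QALY) points drawn independently and uniformly within
    the respective 95% confidence intervals, plus the point-estimate ICER.
    """
    for name, (lo, hi) in (("cost", d_cost_ci), ("qalys", d_qalys_ci)):
        if lo > hi:
            raise ValueError(f"{name} CI bounds out of order")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 73]))
    d_cost = rng.uniform(d_cost_ci[0], d_cost_ci[1], size=n)
    d_qalys = rng.uniform(d_qalys_ci[0], d_qalys_ci[1], size=n)
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = d_cost / d_qalys
    return {
        "d_cost": d_cost,
        "d_qalys": d_qalys,
        "icers": icers,
        "icer_point": d_cost_mean / d_qalys_mean if d_qalys_mean else float("nan"),
    }


def cea_table(rows: list[CEARow]) -> pd.DataFrame:
    """Incremental results as a tidy table (costs to the euro, QALYs to 0.01)."""
    data = []
    for r in rows:
        data.append(
            dict(
                strategy=r.strategy,
                d_cost=round(r.d_cost),
                d_qalys=round(r.d_qalys, 2),
                icer="Dominated" if r.status == "dominated" else round(r.icer),
                status=r.status,
                d_colonoscopies=round(r.d_colonoscopies)
                if np.isfinite(r.d_colonoscopies)
                else "",
                incidence_reduction=round(r.incidence_reduction, 2),
                mortality_reduction=round(r.mortality_reduction, 2),
            )
        )
    return pd.DataFrame(data)
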