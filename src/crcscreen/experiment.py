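"""Experiment orchestration: run the full strategy x scenario grid across
posterior-style parameter draws with common random numbers, aggregate the
per-draw results, and write CSV tables plus a JSON run manifest.

Seed scheme: one master seed; draw ``d`` derives the latent-cohort stream
from ``(seed, d)`` and person ``i``'s screening stream from ``(seed, d, i)``.
Both are counter-based and independent of the strategy, so all arms within a
draw share the same natural histories and person-level screening randomness;
an arm with zero participation is therefore *identical* to the no-screening
arm, and paired differences across strategies are pure screening effects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import config
from .cea import StrategyResult, cea_table, ceac, efficiency_frontier, incremental_vs_comparator
from .economics import EconInputs, aggregate_economics
from .natural_history import sample_latent_histories
from .params import central_params, draw_psa_inputs, generate_posterior_draws
from .screening import (
    AdherenceScenario,
    ConfigurationError,
    Strategy,
    TestPerformance,
    load_scenarios,
    load_strategies,
    run_strategy_arm,
)

logger = logging.getLogger("crcscreen")

__all__ = ["RunConfig", "run_experiment", "validate_config", "write_results"]

NO_SCREENING = "no_screening"


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    Desk-scale defaults (10,000 persons, 50 draws) finish in minutes; the
    full published scale is 100,000 persons and 1,000 draws.
    """

    cohort_size: int = 10_000
    n_draws: int = 50
    seed: int = 1
    scenarios: tuple = (1, 2, 3)
    strategies: tuple | None = None  # None = all bundled strategies
    comparator: str = "current"
    discount_rate: float = config.DISCOUNT_RATE
    wtp_grid: tuple = tuple(range(0, 100_001, 5_000))
    psa: bool = True  # vary test/utility/cost inputs across draws
    jitter_cv: float = config.POSTERIOR_JITTER_CV
    output_dir: str | None = None
    strategy_file: str | None = None
    scenario_file: str | None = None
    life_table_file: str | None = None
    adherence_mode: str = "per_offer"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("scenarios", "strategies", "wtp_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def validate_config(cfg: RunConfig) -> None:
    """Fail fast, naming the offending field."""
    if cfg.cohort_size < 1:
        raise ConfigurationError("cohort_size must be >= 1")
    if cfg.n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    if cfg.discount_rate < 0:
        raise ConfigurationError("discount_rate must be non-negative")
    if list(cfg.wtp_grid) != sorted(cfg.wtp_grid):
        raise ConfigurationError("wtp_grid must be sorted ascending")
    if cfg.adherence_mode not in ("per_offer", "persistent"):
        raise ConfigurationError("adherence_mode must be per_offer or persistent")
    strategies = load_strategies(cfg.strategy_file)
    wanted = cfg.strategies or tuple(strategies)
    missing = set(wanted) - set(strategies)
    if missing:
        raise ConfigurationError(f"unknown strategies requested: {sorted(missing)}")
    if cfg.comparator not in wanted:
        raise ConfigurationError(
            f"comparator {cfg.comparator!r} not among requested strategies"
        )
    scenarios = load_scenarios(cfg.scenario_file)
    missing_sc = set(cfg.scenarios) - set(scenarios)
    if missing_sc:
        raise ConfigurationError(f"unknown scenarios requested: {sorted(missing_sc)}")


def _econ_with_rate(econ: EconInputs, rate: float) -> EconInputs:
    return dataclasses.replace(econ, discount_rate=rate)


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full grid; returns a result bundle and optionally writes it.

    Bundle keys: ``results`` (DataFrame of per-1,000 strategy means),
    ``strategy_results`` ({scenario: [StrategyResult, ...]} incl. the
    no-screening arm), ``cea`` ({scenario: DataFrame}), ``frontier``
    ({scenario: [names]}), ``ceac`` ({scenario: DataFrame}), ``manifest``.
    """
    validate_config(cfg)
    strategies = load_strategies(cfg.strategy_file)
    wanted = list(cfg.strategies or tuple(strategies))
    scenarios = load_scenarios(cfg.scenario_file, mode=cfg.adherence_mode)
    life_table = config.load_life_table(cfg.life_table_file)

    nh_draws = generate_posterior_draws(cfg.n_draws, cfg.seed, cv=cfg.jitter_cv)
    psa_rows = draw_psa_inputs(cfg.n_draws, cfg.seed) if cfg.psa else None

    arm_names = [NO_SCREENING] + wanted
    acc: dict[tuple[int, str], dict[str, list]] = {
        (sc, name): {k: [] for k in _ACC_KEYS} for sc in cfg.scenarios for name in arm_names
    }

    for d in range(cfg.n_draws):
        params = nh_draws[d]
        if psa_rows is not None:
            perf = TestPerformance.from_psa_row(psa_rows.iloc[d])
            econ = EconInputs.from_psa_row(psa_rows.iloc[d])
        else:
            perf = TestPerformance.default()
            econ = EconInputs.default()
        econ = _econ_with_rate(econ, cfg.discount_rate)
        latent = sample_latent_histories(
            cfg.cohort_size, params, life_table, cfg.seed, draw=d
        )
        for sc in cfg.scenarios:
            scenario = scenarios[sc]
            for name in arm_names:
                strategy = None if name == NO_SCREENING else strategies[name]
                hist, summary = run_strategy_arm(
                    cfg.cohort_size,
                    params,
                    strategy,
                    scenario,
                    perf,
                    life_table,
                    seed=cfg.seed,
                    draw=d,
                    latent=latent,
                )
                money = aggregate_economics(hist, econ)
                bucket = acc[(sc, name)]
                for key in _ACC_KEYS:
                    bucket[key].append(summary[key] if key in summary else money[key])
        logger.info("draw %d/%d done", d + 1, cfg.n_draws)

    strategy_results: dict[int, list[StrategyResult]] = {}
    rows = []
    for sc in cfg.scenarios:
        per_scenario = []
        for name in arm_names:
            bucket = acc[(sc, name)]
            mean = {k: float(np.mean(v)) for k, v in bucket.items()}
            result = StrategyResult(
                name=name,
                scenario=sc,
                incidence=mean["incidence"],
                mortality=mean["mortality"],
                qalys=mean["qalys"],
                cost=mean["cost"],
                colonoscopies=mean["colonoscopies"],
                complications=mean["complications"],
                draw_costs=np.array(bucket["cost"]),
                draw_qalys=np.array(bucket["qalys"]),
            )
            per_scenario.append(result)
            rows.append({"scenario": sc, "strategy": name, **mean})
        strategy_results[sc] = per_scenario

    draw_rows = []
    for sc in cfg.scenarios:
        for r in strategy_results[sc]:
            for d in range(cfg.n_draws):
                draw_rows.append(
                    {
                        "scenario": sc,
                        "strategy": r.name,
                        "draw": d,
                        "cost": r.draw_costs[d],
                        "qalys": r.draw_qalys[d],
                    }
                )

    cea_tables = {}
    frontiers = {}
    ceac_tables = {}
    for sc in cfg.scenarios:
        screened = [r for r in strategy_results[sc] if r.name != NO_SCREENING]
        cea_tables[sc] = cea_table(incremental_vs_comparator(screened, cfg.comparator))
        frontiers[sc] = [r.name for r in efficiency_frontier(screened)]
        if cfg.n_draws >= 2:
            ceac_tables[sc] = ceac(screened, cfg.wtp_grid)

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "package": "crcscreen 0.1.0",
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list).encode()
        ).hexdigest(),
        "n_arms": len(arm_names) * len(cfg.scenarios),
    }
    bundle = {
        "results": pd.DataFrame(rows),
        "draws": pd.DataFrame(draw_rows),
        "strategy_results": strategy_results,
        "cea": cea_tables,
        "frontier": frontiers,
        "ceac": ceac_tables,
        "manifest": manifest,
    }
    if cfg.output_dir:
        write_results(bundle, cfg.output_dir)
    return bundle


_ACC_KEYS = (
    "incidence",
    "mortality",
    "colonoscopies",
    "complications",
    "cost",
    "qalys",
)


def write_results(bundle: dict, output_dir) -> None:
    """Write the result bundle as CSV tables plus a JSON manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["results"].to_csv(out / "strategy_means.csv", index=False)
    bundle["draws"].to_csv(out / "draws.csv", index=False)
    for sc, table in bundle["cea"].items():
        table.to_csv(out / f"cea_scenario{sc}.csv", index=False)
    for sc, table in bundle["ceac"].items():
        table.to_csv(out / f"ceac_scenario{sc}.csv", index=False)
    frontier_rows = [
        {"scenario": sc, "rank": i + 1, "strategy": name}
        for sc, names in bundle["frontier"].items()
        for i, name in enumerate(names)
    ]
    pd.DataFrame(frontier_rows).to_csv(out / "frontier.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
    logger.info("results written to %s", out)
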