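"""Full-run orchestration: base-case tables, one-way battery, thresholds, PSA.

:func:`run_all` drives the whole analysis from one flat config file and
writes the result bundle — the strategy cost/QALY table, the one-way
sensitivity grid, the program-cost thresholds and the PSA summary/scatter —
plus a manifest recording the resolved parameters, seed and package version
so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .cea import ce_ratio, format_icer
from .markov import run_strategy
from .parameters import ParameterSet, load_parameters
from .psa import PSAResult, run_psa
from .sensitivity import (
    SWEEP_RATES,
    dominant_for_any_program_cost,
    one_way_sweep,
    threshold_cp_cost,
)
from .tree import Strategy

__all__ = ["run_all", "strategy_table", "one_way_table"]

log = logging.getLogger("osas_cea")


def _result_columns(params: ParameterSet, rates=SWEEP_RATES):
    """The seven reported strategy columns: two fixed arms + swept CP rates."""
    cols = [
        ("no_screening", Strategy("no_screening")),
        ("without_cp", Strategy("without_cp")),
    ]
    for rate in rates:
        cols.append((f"with_cp_{int(round(rate * 100))}", Strategy("with_cp", rate)))
    return cols


def strategy_table(params: ParameterSet, rates=SWEEP_RATES) -> pd.DataFrame:
    """Expected cost, QALYs and CE ratio per strategy column."""
    data = {}
    for name, strat in _result_columns(params, rates):
        res = run_strategy(strat, params)
        data[name] = {
            "expected_cost": round(res.total_cost, 2),
            "qalys": round(res.total_qaly, 4),
            "ce_ratio": round(ce_ratio(res), 2),
        }
    return pd.DataFrame(data)


def one_way_table(params: ParameterSet, rates=SWEEP_RATES) -> pd.DataFrame:
    """One-way battery as a grid of ICER/dominance strings."""
    rows = []
    for scen in one_way_sweep(params, rates=rates):
        row: dict[str, object] = {
            "parameter": scen.parameter,
            "level": scen.level,
            "without_cp": "dominated" if scen.without_cp_dominated else "-",
        }
        for rate in rates:
            row[f"with_cp_{int(round(rate * 100))}"] = format_icer(scen.results[rate].icer)
        rows.append(row)
    return pd.DataFrame(rows)


def _psa_summary(result: PSAResult) -> dict:
    return {
        "n_draws": result.n_draws,
        "wtp": result.wtp,
        "seed": result.seed,
        "fractions": {k: dict(v) for k, v in result.fractions.items()},
    }


def run_all(
    config_path: Optional[str | Path | Mapping] = None,
    output_dir: str | Path = "results",
    seed: int = 0,
    n_draws: int = 10_000,
    wtp: float = 40_000.0,
) -> dict[str, Path]:
    """Run every analysis stage and write the bundle to ``output_dir``.

    Returns a mapping of artifact names to paths.  Any stage failure removes
    the partially written outputs and re-raises with the stage name.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = load_parameters(config_path)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "base_case"
        log.info("stage %s: strategy table", stage)
        table2 = strategy_table(params)
        written["table2"] = out / "table2.csv"
        table2.to_csv(written["table2"])

        stage = "one_way"
        log.info("stage %s: one-way sensitivity battery", stage)
        table3 = one_way_table(params)
        written["table3"] = out / "table3.csv"
        table3.to_csv(written["table3"], index=False)

        stage = "thresholds"
        log.info("stage %s: CP program cost thresholds", stage)
        thresholds = {}
        for rate in SWEEP_RATES:
            thr = threshold_cp_cost(params, rate)
            thresholds[f"{rate:.2f}"] = {
                "threshold_eur": None if thr is None else round(thr, 2),
                "dominant_for_any_program_cost": dominant_for_any_program_cost(params, rate),
            }
        written["thresholds"] = out / "thresholds.json"
        written["thresholds"].write_text(json.dumps(thresholds, indent=2) + "\n")

        stage = "psa"
        log.info("stage %s: %d-draw probabilistic sensitivity analysis", stage, n_draws)
        psa_result = run_psa(base_params=params, n_draws=n_draws, seed=seed, wtp=wtp)
        written["psa_summary"] = out / "psa_summary.json"
        written["psa_summary"].write_text(
            json.dumps(_psa_summary(psa_result), indent=2, sort_keys=True) + "\n"
        )
        written["psa_scatter"] = out / "psa_scatter.csv"
        psa_result.scatter.to_csv(written["psa_scatter"], index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": seed,
            "n_draws": n_draws,
            "wtp": wtp,
            "parameters": params.to_dict(),
        }
        written["manifest"] = out / "manifest.json"
        written["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"run_all failed during stage {stage!r}: {exc}") from exc
    log.info("wrote %d artifacts to %s", len(written), out)
    return written
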