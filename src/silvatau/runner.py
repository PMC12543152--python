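"""Experiment orchestration: spin-up, age-structure initialisation, the
management period, tau computation and aggregation, from a single config.

``run_experiment`` runs one forcing mode (the "management-only" or the
"management and climate change" family); ``compare_modes`` runs both on the
same grid and seed and pairs the zone summaries.  Everything stochastic is
derived from one integer seed through named SeedSequence spawns, so a run is
byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (common_cell_mask, dominance_stratify,
                          longest_tau_map, mode_deltas, scenario_deltas,
                          zone_summary)
from .config import ExperimentConfig
from .forcing import ForcingSeries, GridSpec, gen_forcing, make_grid
from .ledger import StandLedger
from .management import init_age_structure
from .simulate import simulate_stand
from .turnover import select_window, tau_table

log = logging.getLogger("silvatau")

_MODE_ID = {"fixed": 1, "warming": 2}


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    """Bundle of everything one experiment produced."""

    config: ExperimentConfig
    seed: int
    grid: GridSpec
    forcing: ForcingSeries
    ledgers: dict[tuple[int, str], StandLedger]
    window: tuple[int, int]
    tau: pd.DataFrame
    common_cells: set
    excluded_scenarios: set
    summary: pd.DataFrame
    deltas: pd.DataFrame
    longest: dict[str, pd.DataFrame]
    dominance: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, ledgers: bool = False) -> None:
        """Write tau and comparison tables (CSV) plus the run manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tau.to_csv(out / "tau_table.csv", index=False)
        self.summary.to_csv(out / "zone_summary.csv", index=False)
        self.deltas.to_csv(out / "scenario_deltas.csv", index=False)
        self.dominance.to_csv(out / "dominance_deltas.csv", index=False)
        for pool, df in self.longest.items():
            df.to_csv(out / f"longest_tau_{pool}.csv", index=False)
        self.grid.to_dataframe().to_csv(out / "grid.csv", index=False)
        if ledgers:
            pd.concat([led.to_dataframe()
                       for led in self.ledgers.values()]).to_csv(
                out / "ledgers.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def run_experiment(cfg: ExperimentConfig, seed: int = 0,
                   outdir: str | Path | None = None,
                   write_ledgers: bool = False) -> ExperimentResult:
    """Run every scenario on every cell for the config's forcing mode."""
    mode_id = _MODE_ID[cfg.mode]
    grid = make_grid(cfg.n_cells, cfg.zone_weights, seed=seed,
                     params=cfg.params)
    forcing = gen_forcing(grid, cfg.mode, cfg.total_years,
                          seed=seed * 7 + mode_id, params=cfg.params,
                          trend_start=cfg.management_start)

    plans = {
        cell: init_age_structure(
            cfg.n_patches, cfg.age_histogram, cfg.management_start,
            seed=np.random.default_rng(
                np.random.SeedSequence([seed, 5, cell])))
        for cell in range(cfg.n_cells)
    }
    accel = (cfg.spinup_years - 40 if cfg.spinup_years >= 120 else None)

    ledgers: dict[tuple[int, str], StandLedger] = {}
    for scenario in cfg.scenarios:
        scen = cfg.scenario_config(scenario)
        log.info("simulating scenario %s (%d cells, %s mode)",
                 scenario, cfg.n_cells, cfg.mode)
        for cell in range(cfg.n_cells):
            led = simulate_stand(
                forcing.cell_arrays(cell), t_amp=float(grid.t_amp[cell]),
                initial_pft=grid.initial_pft(cell), scen=scen,
                params=cfg.params, n_patches=cfg.n_patches,
                plan=plans[cell],
                seed=np.random.SeedSequence(
                    [seed, mode_id, 10 + list(cfg.scenarios).index(scenario),
                     cell]),
                dist_seed=np.random.SeedSequence([seed, mode_id, 3, cell]),
                soil_accel_year=accel, cell_id=cell,
                zone=str(grid.zone[cell]))
            led.mode = cfg.mode
            ledgers[(cell, scenario)] = led

    window = select_window(cfg.total_years, cfg.management_start,
                           cfg.rotation, cfg.mode, cfg.window_length)
    dominant = {c: str(grid.initial_dominant[c]) for c in range(cfg.n_cells)}
    tau = tau_table(ledgers, window, mode=cfg.mode,
                    height_threshold=cfg.height_threshold,
                    initial_dominant=dominant)
    cells, excluded = common_cell_mask(tau, list(cfg.scenarios))
    summary = zone_summary(tau, cells, coverage=cfg.trim_coverage)
    deltas = scenario_deltas(summary)
    longest = {pool: longest_tau_map(tau, cells, pool)
               for pool in ("eco", "stem", "soil")}
    dominance = dominance_stratify(tau, cells, exclude=excluded)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "mode": cfg.mode,
        "config_hash": _config_hash(cfg),
        "n_cells": cfg.n_cells,
        "scenarios": list(cfg.scenarios),
        "window": list(window),
        "excluded_scenarios": sorted(excluded),
    }
    result = ExperimentResult(
        config=cfg, seed=seed, grid=grid, forcing=forcing, ledgers=ledgers,
        window=window, tau=tau, common_cells=cells,
        excluded_scenarios=excluded, summary=summary, deltas=deltas,
        longest=longest, dominance=dominance, manifest=manifest)
    if outdir is not None:
        result.write(outdir, ledgers=write_ledgers)
    return result


def compare_modes(cfg: ExperimentConfig, seed: int = 0
                  ) -> tuple[ExperimentResult, ExperimentResult, pd.DataFrame]:
    """Run the management-only and climate-change families on one grid.

    Returns (fixed result, warming result, paired zone-mean differences).
    """
    fixed = run_experiment(cfg.replace(mode="fixed"), seed=seed)
    warming = run_experiment(cfg.replace(mode="warming"), seed=seed)
    deltas = mode_deltas(warming.summary, fixed.summary)
    return fixed, warming, deltas
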