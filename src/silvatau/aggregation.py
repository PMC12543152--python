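"""Comparison logic across scenarios: common retained-cell masks, zone means
with standard errors, longest-tau classification and dominance stratification.

Averages are across grid cells (not years); the standard error is sd/sqrt(n)
over the retained, trimmed cell set.  Cells failing the 5-m forest height
filter in any compared scenario are masked everywhere so scenario means refer
to a common extent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SCENARIOS, ConfigError
from .turnover import trim_extremes

#: documented tie-break order for longest-tau labels
SCENARIO_ORDER = {s: i for i, s in enumerate(SCENARIOS)}


def common_cell_mask(table: pd.DataFrame,
                     scenarios: list[str] | None = None,
                     min_fraction: float = 0.5) -> tuple[set, set]:
    """Cells retained (height filter) in *every* compared scenario.

    Returns ``(common_cells, excluded_scenarios)``: a scenario whose own
    retained set covers less than ``min_fraction`` of the baseline's is
    flagged for exclusion from dominance-stratified comparisons (its extent is
    not comparable), and does not constrain the common mask.
    """
    if scenarios is None:
        scenarios = sorted(table["scenario"].unique(), key=SCENARIO_ORDER.get)
    retained = {
        s: set(table.loc[(table.scenario == s) & table.retained, "cell"])
        for s in scenarios
    }
    base = retained.get("base", set().union(*retained.values()))
    excluded = {s for s, cells in retained.items()
                if s != "base" and base and len(cells) < min_fraction * len(base)}
    common = None
    for s, cells in retained.items():
        if s in excluded:
            continue
        common = cells if common is None else (common & cells)
    if not common:
        raise ConfigError("no cell passes the height filter in all scenarios")
    return common, excluded


def zone_summary(table: pd.DataFrame, cells: set,
                 coverage: float = 0.99) -> pd.DataFrame:
    """Mean tau and SE per zone x scenario x pool over the masked cell set.

    Values are trimmed to the central ``coverage`` quantile band within each
    group before averaging.  Single-cell groups get SE = 0 with a flag.
    """
    sub = table[table.cell.isin(cells)]
    rows = []
    for (zone, scenario, pool), grp in sub.groupby(
            ["zone", "scenario", "pool"], sort=True):
        vals = grp["tau_years"].to_numpy()
        kept, n_excl = trim_extremes(vals, coverage)
        if kept.size == 0:
            mean = se = np.nan
        else:
            mean = float(np.mean(kept))
            se = (float(np.std(kept, ddof=1) / np.sqrt(kept.size))
                  if kept.size > 1 else 0.0)
        rows.append(dict(zone=zone, scenario=scenario, pool=pool,
                         mean_tau=mean, se=se, n_cells=int(kept.size),
                         n_trimmed=n_excl, single_cell=kept.size == 1))
    return pd.DataFrame(rows)


def scenario_deltas(summary: pd.DataFrame,
                    baseline: str = "base") -> pd.DataFrame:
    """Scenario-minus-baseline differences of zone means."""
    base = summary[summary.scenario == baseline].set_index(["zone", "pool"])
    rows = []
    for _, r in summary.iterrows():
        if r["scenario"] == baseline:
            continue
        key = (r["zone"], r["pool"])
        if key not in base.index:
            continue
        rows.append(dict(zone=r["zone"], pool=r["pool"],
                         scenario=r["scenario"],
                         delta_tau=r["mean_tau"] - base.loc[key, "mean_tau"]))
    return pd.DataFrame(rows)


def mode_deltas(summary_climate: pd.DataFrame,
                summary_fixed: pd.DataFrame) -> pd.DataFrame:
    """Climate-change minus management-only zone means (paired groups)."""
    keys = ["zone", "scenario", "pool"]
    merged = summary_climate.merge(summary_fixed, on=keys,
                                   suffixes=("_climate", "_fixed"))
    merged["delta_tau"] = merged["mean_tau_climate"] - merged["mean_tau_fixed"]
    return merged[keys + ["mean_tau_climate", "mean_tau_fixed", "delta_tau"]]


def longest_tau_map(table: pd.DataFrame, cells: set, pool: str,
                    exclude_unmanaged: bool = False) -> pd.DataFrame:
    """Per-cell label of the scenario with the longest tau for one pool kind.

    Exact ties go to the first scenario in the documented order
    (base < toNE < toBD < toBE < unmanaged) and are flagged.
    """
    sub = table[(table.pool == pool) & table.cell.isin(cells)]
    if exclude_unmanaged:
        sub = sub[sub.scenario != "unmanaged"]
    rows = []
    for cell, grp in sub.groupby("cell"):
        grp = grp.dropna(subset=["tau_years"])
        if grp.empty:
            continue
        best = grp["tau_years"].max()
        winners = sorted(grp.loc[grp.tau_years == best, "scenario"],
                         key=SCENARIO_ORDER.get)
        rows.append(dict(cell=cell, pool=pool, longest=winners[0],
                         tau_years=best, tie=len(winners) > 1))
    return pd.DataFrame(rows)


def dominance_stratify(table: pd.DataFrame, cells: set,
                       baseline: str = "base",
                       exclude: set | None = None) -> pd.DataFrame:
    """Scenario-minus-baseline mean deltas by pre-management dominance group.

    Cells are grouped by their initial needle-leaved vs broadleaved dominance;
    per group and pool kind the mean (with SE) of the per-cell tau difference
    to the baseline is reported.  Empty groups are flagged with n_cells = 0.
    """
    exclude = exclude or set()
    sub = table[table.cell.isin(cells)]
    piv = sub.pivot_table(index=["cell", "initial_dominant", "pool"],
                          columns="scenario", values="tau_years")
    rows = []
    scenarios = [s for s in sub["scenario"].unique()
                 if s != baseline and s not in exclude]
    for (group, pool), grp in piv.groupby(level=["initial_dominant", "pool"]):
        for s in scenarios:
            if s not in grp.columns or baseline not in grp.columns:
                continue
            diff = (grp[s] - grp[baseline]).dropna().to_numpy()
            rows.append(dict(
                group=group, pool=pool, scenario=s,
                mean_delta=float(np.mean(diff)) if diff.size else np.nan,
                se=(float(np.std(diff, ddof=1) / np.sqrt(diff.size))
                    if diff.size > 1 else 0.0),
                n_cells=int(diff.size), empty=diff.size == 0))
    return pd.DataFrame(rows)
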