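"""Carbon turnover time (tau) diagnostics from annual ledgers.

tau is estimated as the ratio of window-mean carbon stock to window-mean
outflow, assuming the pool is near steady state over the window:

* ecosystem: Ceco / (FRa + FRh + FDOC + Ffire + Fharv_products + Fharv_atm),
  with Ceco the live + litter + soil carbon, excluding the product pool;
* stem (stem + branches + coarse roots): Cstem / (Fmort + Fdist + stem-share
  of Ffire + total felled stem C, including the residue left as litter);
* soil (single pool): Csoil / FRh;
* named soil sub-pools: stock / total decay outflow (respiration + transfers
  + leaching).

A GPP-based variant Ceco / GPP serves as the steady-state cross-check: the
two estimates coincide exactly when the stock is not changing, and the GPP
variant is shorter while carbon is still accumulating.

Windows are the last 30 years of a rotation cycle, excluding the clear-cut
year; extreme values across cells are trimmed to a central quantile band
before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError
from .ledger import StandLedger

#: pool kinds with per-pool tau support
SUB_POOLS = {"surfcwd": "SURFCWD", "surffwd": "SURFFWD",
             "surfhum": "SURFHUMUS", "slow": "SLOW"}
POOL_KINDS = ("eco", "stem", "soil") + tuple(SUB_POOLS)


def select_window(n_years: int, management_start: int, rotation: int,
                  mode: str = "fixed", window_length: int = 30,
                  cycle: int | None = None) -> tuple[int, int]:
    """Half-open year interval [start, end) of the tau averaging window.

    Management-only runs use the last ``window_length`` years of the third
    rotation cycle; climate-change runs the last years of the first cycle.
    The next clear-cut falls exactly at ``end`` and is therefore excluded.
    """
    if cycle is None:
        cycle = 3 if mode == "fixed" else 1
    end = management_start + cycle * rotation
    start = end - window_length
    if start < 0 or end > n_years:
        raise ConfigError(
            f"run of {n_years} yr too short for a [{start}, {end}) window")
    return start, end


def _window_ratio(stock: np.ndarray, outflow: np.ndarray,
                  window: tuple[int, int]) -> tuple[float, float, float]:
    a, b = window
    if b <= a:
        raise ConfigError("empty tau window")
    mean_pool = float(np.mean(stock[a:b]))
    mean_out = float(np.mean(outflow[a:b]))
    tau = mean_pool / mean_out if mean_out > 0 else math.nan
    return tau, mean_pool, mean_out


def tau_eco(ledger: StandLedger, window: tuple[int, int]) -> float:
    """Ecosystem turnover time (yr); NaN when the outflow is zero."""
    ceco = ledger["c_eco"]
    return _window_ratio(ceco, ledger.fturn_eco, window)[0]


def tau_stem(ledger: StandLedger, window: tuple[int, int]) -> float:
    return _window_ratio(ledger["c_stem"], ledger.fturn_stem, window)[0]


def tau_soil(ledger: StandLedger, window: tuple[int, int]) -> float:
    """Whole-soil turnover time: all litter + SOM pools over FRh."""
    return _window_ratio(ledger["c_soil"], ledger["frh"], window)[0]


def tau_pool(pool_id: str, ledger: StandLedger,
             window: tuple[int, int]) -> float:
    """Turnover time of one named soil pool (outflow includes transfers)."""
    if pool_id not in SUB_POOLS:
        raise ConfigError(f"unknown sub-pool {pool_id!r}; "
                          f"expected one of {sorted(SUB_POOLS)}")
    name = SUB_POOLS[pool_id]
    return _window_ratio(ledger[f"pool_{name}"], ledger[f"out_{name}"],
                         window)[0]


def tau_gpp(ledger: StandLedger, window: tuple[int, int]) -> float:
    """Input-based ecosystem turnover time Ceco / GPP (equilibrium check)."""
    return _window_ratio(ledger["c_eco"], ledger["gpp"], window)[0]


def trim_extremes(values, coverage: float = 0.99):
    """Retain values inside the central ``coverage`` quantile band.

    Returns ``(retained, n_excluded)``.  ``coverage=1`` is the identity;
    NaNs are dropped (not counted as excluded extremes).
    """
    if not 0.0 < coverage <= 1.0:
        raise ConfigError("coverage must be in (0, 1]")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ConfigError("cannot trim an empty sample")
    arr = arr[~np.isnan(arr)]
    if arr.size == 0 or coverage == 1.0:
        return arr, 0
    # order-statistic band edges: a value is extreme only if observations
    # actually lie beyond the band, so small samples are never over-trimmed
    lo = np.quantile(arr, (1 - coverage) / 2, method="lower")
    hi = np.quantile(arr, 1 - (1 - coverage) / 2, method="higher")
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], int(np.sum(~keep))


@dataclass(frozen=True)
class TauRow:
    cell: int
    zone: str
    scenario: str
    mode: str
    pool: str
    tau_years: float
    mean_pool: float
    mean_outflow: float
    window_start: int
    window_end: int
    tau_gpp_years: float  # NaN except for the ecosystem rows
    height: float
    retained: bool


def tau_table(ledgers: dict, window: tuple[int, int], mode: str = "fixed",
              height_threshold: float = 5.0,
              initial_dominant: dict | None = None) -> pd.DataFrame:
    """Tidy per-cell tau table across scenarios and pool kinds.

    ``ledgers`` maps (cell, scenario) -> StandLedger.  Height retention uses
    the scenario-average stand height over the window (closed lower bound).
    """
    a, b = window
    rows: list[dict] = []
    for (cell, scenario), led in sorted(ledgers.items()):
        height = float(np.mean(led["height"][a:b]))
        retained = height >= height_threshold
        tg = tau_gpp(led, window)
        taus = {
            "eco": tau_eco(led, window),
            "stem": tau_stem(led, window),
            "soil": tau_soil(led, window),
            **{pid: tau_pool(pid, led, window) for pid in SUB_POOLS},
        }
        stocks = {
            "eco": led["c_eco"], "stem": led["c_stem"], "soil": led["c_soil"],
            **{pid: led[f"pool_{nm}"] for pid, nm in SUB_POOLS.items()},
        }
        outs = {
            "eco": led.fturn_eco, "stem": led.fturn_stem, "soil": led["frh"],
            **{pid: led[f"out_{nm}"] for pid, nm in SUB_POOLS.items()},
        }
        for pool in POOL_KINDS:
            rows.append(dict(
                cell=cell, zone=led.zone, scenario=scenario, mode=led.mode,
                pool=pool, tau_years=taus[pool],
                mean_pool=float(np.mean(stocks[pool][a:b])),
                mean_outflow=float(np.mean(outs[pool][a:b])),
                window_start=a, window_end=b,
                tau_gpp_years=tg if pool == "eco" else math.nan,
                height=height, retained=retained,
                initial_dominant=(initial_dominant or {}).get(cell, ""),
            ))
    return pd.DataFrame(rows)
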