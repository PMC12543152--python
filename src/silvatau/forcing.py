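"""Synthetic grid and climate forcing.

Stands in for the external datasets a continental study would ingest: a small
grid of cells with grouped Koppen-Geiger zone labels, an initial dominance
group per cell, and annual climate / CO2 / N-deposition series in two modes:

* ``fixed`` -- a detrended base block (default 20 yr) recycled verbatim, with
  constant CO2 and N deposition (the "management-only" design);
* ``warming`` -- a linear temperature trend plus a CO2 ramp starting at a
  configurable year (the "management and climate change" design).

Forcing is annual: the reduced vegetation and soil models run on an annual
step, so daily weather would carry no information here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import ConfigError
from .params import (GROUP_PFT, NEEDLE_DOMINANCE_P, ZONE_CLIMATE, ZONES,
                     ModelParams, DEFAULT_PARAMS)


@dataclass(frozen=True)
class GridSpec:
    """Synthetic grid: zone label, climatology and initial dominance per cell."""

    n_cells: int
    cell_ids: np.ndarray          # int cell identifiers
    zone: np.ndarray              # str zone label per cell
    initial_dominant: np.ndarray  # "needleleaved" | "broadleaved" per cell
    t_mean: np.ndarray            # cell climatology (jittered prototypes)
    t_amp: np.ndarray
    precip: np.ndarray
    summer_frac: np.ndarray

    def initial_pft(self, cell: int) -> str:
        return GROUP_PFT[str(self.initial_dominant[cell])]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.cell_ids, "zone": self.zone,
            "initial_dominant": self.initial_dominant,
            "t_mean": self.t_mean, "t_amp": self.t_amp,
            "precip": self.precip, "summer_frac": self.summer_frac,
        })


def make_grid(n_cells: int, zone_weights: dict[str, float] | None = None,
              seed: int = 0, params: ModelParams = DEFAULT_PARAMS) -> GridSpec:
    """Draw a synthetic grid of ``n_cells`` cells from zone weights.

    Cells are assigned independently to the five retained zones with
    probability proportional to the weights ("tundra" is never assigned).
    Each cell receives a jittered copy of its zone's prototype climatology and
    an initial dominance group drawn with a zone-specific needle-leaved share.
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    if zone_weights is None:
        zone_weights = {z: 1.0 for z in ZONES}
    unknown = set(zone_weights) - set(ZONES)
    if unknown:
        raise ConfigError(f"unknown zones in weights: {sorted(unknown)}")
    zones = [z for z in ZONES if zone_weights.get(z, 0.0) > 0]
    w = np.array([zone_weights[z] for z in zones], dtype=float)
    if np.any(w < 0):
        raise ConfigError("zone weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ConfigError("zone weights sum to zero")
    w /= total

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    idx = rng.choice(len(zones), size=n_cells, p=w)
    zone = np.array([zones[i] for i in idx], dtype=object)

    nz = params.noise
    t_jit = rng.normal(0.0, nz.cell_jitter_t, n_cells)
    p_jit = 1.0 + rng.normal(0.0, nz.cell_jitter_precip, n_cells)
    proto = [ZONE_CLIMATE[z] for z in zone]
    t_mean = np.array([c.t_mean for c in proto]) + t_jit
    t_amp = np.array([c.t_amp for c in proto])
    precip = np.maximum(np.array([c.precip for c in proto]) * p_jit, 1.0)
    summer_frac = np.clip(
        np.array([c.summer_frac for c in proto])
        + rng.normal(0.0, 0.02, n_cells), 0.02, 0.95)

    p_needle = np.array([NEEDLE_DOMINANCE_P[z] for z in zone])
    needle = rng.random(n_cells) < p_needle
    dominant = np.where(needle, "needleleaved", "broadleaved").astype(object)

    return GridSpec(
        n_cells=n_cells, cell_ids=np.arange(n_cells), zone=zone,
        initial_dominant=dominant, t_mean=t_mean, t_amp=t_amp,
        precip=precip, summer_frac=summer_frac)


@dataclass
class ForcingSeries:
    """Annual forcing per (cell, year) plus cell climatology, as xarray."""

    data: xr.Dataset

    @property
    def n_years(self) -> int:
        return self.data.sizes["year"]

    def cell_arrays(self, cell: int) -> dict[str, np.ndarray]:
        """Plain numpy views for the simulator inner loop."""
        d = self.data.isel(cell=cell)
        return {v: d[v].values for v in ("temp", "precip", "rad", "co2", "ndep")}

    def to_dataframe(self) -> pd.DataFrame:
        return self.data.to_dataframe().reset_index()


def gen_forcing(grid: GridSpec, mode: str, years: int, seed: int = 0,
                params: ModelParams = DEFAULT_PARAMS,
                trend_start: int = 0, block_years: int = 20) -> ForcingSeries:
    """Generate annual forcing for every cell of ``grid``.

    fixed mode
        A ``block_years``-long anomaly block is drawn per cell, detrended to
        zero mean, and recycled for the whole run; CO2 and N deposition are
        constant.  Full recycled blocks therefore have identical means.
    warming mode
        Independent interannual anomalies every year, plus a linear
        temperature trend and a CO2 ramp that start at ``trend_start``.

    Identical (grid, mode, years, seed) give bit-identical output.
    """
    if years < 1:
        raise ConfigError("years must be >= 1")
    if mode not in ("fixed", "warming"):
        raise ConfigError(f"unknown forcing mode {mode!r}")

    nz, wp = params.noise, params.warming
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    n = grid.n_cells

    if mode == "fixed":
        nb = int(np.ceil(years / block_years))
        t_block = rng.normal(0.0, nz.sigma_t, (n, block_years))
        p_block = rng.normal(0.0, nz.sigma_precip, (n, block_years))
        r_block = rng.normal(0.0, nz.sigma_rad, (n, block_years))
        for b in (t_block, p_block, r_block):
            b -= b.mean(axis=1, keepdims=True)  # detrend: zero block mean
        t_anom = np.tile(t_block, nb)[:, :years]
        p_anom = np.tile(p_block, nb)[:, :years]
        r_anom = np.tile(r_block, nb)[:, :years]
        trend = np.zeros(years)
        co2 = np.full(years, params.co2_fixed)
    else:
        t_anom = rng.normal(0.0, nz.sigma_t, (n, years))
        p_anom = rng.normal(0.0, nz.sigma_precip, (n, years))
        r_anom = rng.normal(0.0, nz.sigma_rad, (n, years))
        yr = np.arange(years, dtype=float)
        ramp = np.clip(yr - trend_start, 0.0, wp.trend_years)
        trend = wp.t_slope * ramp
        co2 = wp.co2_start + (wp.co2_end - wp.co2_start) * ramp / wp.trend_years

    temp = grid.t_mean[:, None] + trend[None, :] + t_anom
    precip = np.maximum(grid.precip[:, None] * (1.0 + p_anom), 0.0)
    if mode == "warming" and wp.precip_slope:
        precip = np.maximum(precip + wp.precip_slope *
                            np.clip(np.arange(years) - trend_start, 0, None), 0.0)
    rad = np.clip(nz.rad_mean + r_anom, 0.0, 1.0)
    ndep = np.full(years, params.ndep_fixed)

    ds = xr.Dataset(
        {
            "temp": (("cell", "year"), temp),
            "precip": (("cell", "year"), precip),
            "rad": (("cell", "year"), rad),
            "co2": (("year",), co2),
            "ndep": (("year",), ndep),
            "zone": (("cell",), grid.zone.astype(str)),
            "t_amp": (("cell",), grid.t_amp),
        },
        coords={"cell": grid.cell_ids, "year": np.arange(years)},
        attrs={"mode": mode, "seed": int(seed), "trend_start": int(trend_start)},
    )
    return ForcingSeries(ds)


def months_above(t_mean: float, t_amp: float, threshold: float = 10.0) -> int:
    """Months warmer than ``threshold`` for a sinusoidal seasonal cycle."""
    m = np.arange(12) + 0.5
    t = t_mean - t_amp * np.cos(2.0 * np.pi * m / 12.0)
    return int(np.sum(t > threshold))


_SUMMARY_FIELDS = ("t_mean", "t_warm", "t_cold", "precip", "summer_frac")


def climate_summary(grid: GridSpec, forcing: ForcingSeries, cell: int,
                    years: slice | None = None) -> dict[str, float]:
    """30-yr style climatological summary of one cell, for zone assignment."""
    temp = forcing.data["temp"].isel(cell=cell).values
    prec = forcing.data["precip"].isel(cell=cell).values
    if years is not None:
        temp, prec = temp[years], prec[years]
    amp = float(grid.t_amp[cell])
    tm = float(np.mean(temp))
    return {
        "t_mean": tm, "t_warm": tm + amp, "t_cold": tm - amp,
        "precip": float(np.mean(prec)),
        "summer_frac": float(grid.summer_frac[cell]),
    }


def assign_zone(summary: dict[str, float]) -> str:
    """Classify a climate summary into the grouped Koppen-Geiger classes.

    Simplified threshold rules (documented constants):

    * arid: annual P < 10 x Pth, Pth = 2T (winter rain), 2T+28 (summer rain,
      summer share >= 0.7) or 2T+14 otherwise;
    * tundra: warmest month < 10 degC (recognised, excluded from analyses);
    * cold (D): coldest month <= -3 degC, split at >= 4 months above 10 degC
      into warm- vs cold-summer classes;
    * temperate (C): split by the dry-summer rule Psummer < Pwinter / 3.

    Deterministic and idempotent; raises on missing fields.
    """
    missing = [f for f in _SUMMARY_FIELDS if f not in summary]
    if missing:
        raise ConfigError(f"climate summary missing fields: {missing}")
    tm = float(summary["t_mean"])
    tw = float(summary["t_warm"])
    tc = float(summary["t_cold"])
    p = float(summary["precip"])
    sf = float(summary["summer_frac"])

    if sf >= 0.7:
        pth = 2.0 * tm + 28.0
    elif sf <= 0.3:
        pth = 2.0 * tm
    else:
        pth = 2.0 * tm + 14.0
    if p < 10.0 * max(pth, 0.0):
        return "arid"
    if tw < 10.0:
        return "tundra"
    if tc <= -3.0:
        amp = (tw - tc) / 2.0
        if months_above(tm, amp) >= 4:
            return "cold with warm summer"
        return "cold with cold summer"
    p_summer = p * sf
    p_winter = p * (1.0 - sf)
    if p_summer < p_winter / 3.0:
        return "temperate with dry summer"
    return "temperate without dry season"
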