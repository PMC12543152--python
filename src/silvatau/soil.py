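"""CENTURY-style litter and soil organic matter cascade.

Ten pools (surface CWD/FWD/structural/metabolic/humus, soil
structural/metabolic, active, slow, passive) linked by a configurable
transfer-fraction matrix.  Each pool decays at an intrinsic rate scaled by a
Q10 temperature modifier and a saturating moisture modifier; decayed carbon is
split between heterotrophic respiration, transfers to downstream pools and --
for the active pool -- a dissolved-organic-carbon leaching loss.

The annual step is sub-stepped (default 24) for stability of the fast
metabolic pools; outflow is accounted as rate x stock, so an isolated pool in
equilibrium has turnover time exactly 1/(k f g).  Mass balance is exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SOIL_POOLS, SoilParams

N_POOLS = len(SOIL_POOLS)
POOL_INDEX = {p: i for i, p in enumerate(SOIL_POOLS)}
_ACTIVE = POOL_INDEX["ACTIVE"]


@dataclass
class SoilStepResult:
    """Annual outcome of one soil step (all kgC m-2 or kgC m-2 yr-1)."""

    pools: np.ndarray       # state after the step
    outflow: np.ndarray     # per-pool total decay (respiration + transfers + DOC)
    rh: np.ndarray          # per-pool heterotrophic respiration
    transfers: np.ndarray   # per-pool carbon passed to downstream pools
    fdoc: float             # leaching loss from the active pool

    @property
    def total_rh(self) -> float:
        return float(self.rh.sum())


def new_pools() -> np.ndarray:
    return np.zeros(N_POOLS)


def route_litter(stem: float = 0.0, leaf: float = 0.0, froot: float = 0.0,
                 lignin_leaf: float = 0.35, lignin_froot: float = 0.45,
                 cwd_frac: float = 0.7, out: np.ndarray | None = None
                 ) -> np.ndarray:
    """Additions to the pool vector from one litter parcel.

    Dead stem splits into coarse vs fine woody debris by ``cwd_frac``; leaf and
    fine-root litter split between structural and metabolic pools by the PFT's
    lignin fraction (leaves at the surface, fine roots below ground).  Totals
    are conserved exactly.
    """
    if stem < 0 or leaf < 0 or froot < 0:
        raise ValueError("litter amounts must be nonnegative")
    add = out if out is not None else np.zeros(N_POOLS)
    add[POOL_INDEX["SURFCWD"]] += cwd_frac * stem
    add[POOL_INDEX["SURFFWD"]] += (1.0 - cwd_frac) * stem
    add[POOL_INDEX["SURFSTRUCT"]] += lignin_leaf * leaf
    add[POOL_INDEX["SURFMETA"]] += (1.0 - lignin_leaf) * leaf
    add[POOL_INDEX["SOILSTRUCT"]] += lignin_froot * froot
    add[POOL_INDEX["SOILMETA"]] += (1.0 - lignin_froot) * froot
    return add


def temperature_factor(t: float, params: SoilParams) -> float:
    return float(min(params.q10 ** ((t - params.t_ref) / 10.0), params.f_t_max))


def moisture_factor(precip: float, params: SoilParams) -> float:
    if precip < 0:
        raise ValueError("precipitation must be nonnegative")
    return float(precip / (precip + params.moisture_half))


def step_soil(pools: np.ndarray, temp: float, precip: float,
              params: SoilParams, inputs: np.ndarray | None = None
              ) -> SoilStepResult:
    """Advance the cascade one year under (temp, precip) with litter inputs."""
    if np.any(pools < -1e-12):
        raise ValueError("soil pools must be nonnegative")
    f = temperature_factor(temp, params)
    g = moisture_factor(precip, params)
    n = params.n_substeps
    rate = params.k * (f * g / n)
    if np.any(rate >= 1.0):
        raise ValueError("soil sub-step unstable; increase n_substeps")

    topo = params.topology
    resp_frac = 1.0 - topo.sum(axis=1)
    doc_frac = params.doc_coeff * g
    resp_frac = resp_frac.copy()
    resp_frac[_ACTIVE] -= doc_frac

    c = pools.astype(float).copy()
    in_sub = (inputs / n) if inputs is not None else None
    outflow = np.zeros(N_POOLS)
    for _ in range(n):
        out = rate * c
        outflow += out
        c -= out
        c += out @ topo
        if in_sub is not None:
            c += in_sub
    rh = resp_frac * outflow
    transfers = outflow @ topo
    fdoc = float(doc_frac * outflow[_ACTIVE])
    return SoilStepResult(pools=c, outflow=outflow, rh=rh,
                          transfers=transfers, fdoc=fdoc)


def total_rh(rh_per_pool: np.ndarray) -> float:
    """Total heterotrophic respiration: the single source of truth for FRh."""
    return float(np.sum(rh_per_pool))


def soil_equilibrium(inputs: np.ndarray, temp: float, precip: float,
                     params: SoilParams) -> np.ndarray:
    """Analytic steady-state pool vector for constant annual litter inputs.

    At steady state the annual outflow vector o solves (I - T') o = inputs and
    pools are o / (k f g).  Used to accelerate spin-up of the slow pools and as
    a closed-form oracle in tests.
    """
    f = temperature_factor(temp, params)
    g = moisture_factor(precip, params)
    eye = np.eye(N_POOLS)
    out = np.linalg.solve(eye - params.topology.T, np.asarray(inputs, float))
    kfg = params.k * f * g
    pools = np.divide(out, kfg, out=np.zeros(N_POOLS), where=kfg > 0)
    if np.any(pools < -1e-9):
        raise ValueError("equilibrium solve produced negative pools")
    return np.maximum(pools, 0.0)
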