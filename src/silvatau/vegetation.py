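"""Annual cohort dynamics per patch.

A stand is a fixed set of patches (default 25); each patch carries cohorts of
one plant functional type with stem (stem + branches + coarse roots), leaf and
fine-root carbon, an age, and a stem density.  The year proceeds as:
production and allocation, demographic mortality, fire (unmanaged patches
only), management (clear-cut / thinning, handled by the management module),
then stochastic patch-destroying disturbance.

Production is a deliberately simple saturating model: canopy assimilation is a
light- and temperature-limited saturating function of leaf carbon with a
logarithmic CO2 multiplier; maintenance respiration is pool- and
temperature-dependent (Q10), growth respiration a fixed share of the surplus.
Net production first replaces leaf and fine-root turnover, and the remainder
is allocated with fixed PFT fractions, which gives a stable fixed point under
constant forcing.  The claims under test are accounting identities and
management contrasts, not tree physiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import FireParams, PFTParams, VegParams
from .soil import POOL_INDEX, route_litter


@dataclass
class Cohort:
    """Even-aged group of trees of one PFT within a patch (pools kgC m-2)."""

    pft: str
    age: float = 0.0
    density: float = 0.0     # stems m-2
    c_stem: float = 0.0      # stem + branches + coarse roots
    c_leaf: float = 0.0
    c_froot: float = 0.0
    ge: float = math.inf     # last year's growth efficiency (NPP per leaf C)

    def stem_mass(self) -> float:
        """Mean stem carbon per tree, kgC."""
        return self.c_stem / self.density if self.density > 0 else 0.0

    def height(self, veg: VegParams) -> float:
        return veg.h_coef * self.stem_mass() ** veg.h_exp

    def diameter_cm(self, veg: VegParams) -> float:
        m = self.stem_mass()
        return (m / veg.d_coef) ** (1.0 / veg.d_exp) if m > 0 else 0.0

    @property
    def c_live(self) -> float:
        return self.c_stem + self.c_leaf + self.c_froot


@dataclass
class Patch:
    """One disturbance replicate of a stand."""

    cohorts: list[Cohort] = field(default_factory=list)
    managed: bool = False
    pending_plant: list[tuple[int, str]] = field(default_factory=list)

    @property
    def c_leaf(self) -> float:
        return sum(c.c_leaf for c in self.cohorts)

    @property
    def c_live(self) -> float:
        return sum(c.c_live for c in self.cohorts)


@dataclass
class Stand:
    """The analysed (initially managed) patch set of one grid cell.

    Patch-average pools are per-m2 means over the analysis patches; the
    pristine remainder of the cell is tracked only as a count.
    """

    patches: list[Patch]
    pristine_patches: int = 0
    cell_id: int = 0
    scenario: str = "base"

    @property
    def n_patches(self) -> int:
        return len(self.patches)


class ForcingNaNError(ValueError):
    pass


@dataclass
class YearFluxes:
    """Per-patch-step flux accumulator (kgC m-2 of patch area)."""

    gpp: float = 0.0
    fra: float = 0.0
    fmort_stem: float = 0.0
    fdist_stem: float = 0.0
    ffire_live: float = 0.0
    ffire_stem: float = 0.0
    litter_leaf: float = 0.0
    litter_froot: float = 0.0
    litter_stem: float = 0.0


def annual_production(patch: Patch, temp: float, rad: float, co2: float,
                      pfts: dict[str, PFTParams], veg: VegParams,
                      litter_out: np.ndarray, fluxes: YearFluxes) -> None:
    """One year of assimilation, respiration, turnover and allocation.

    Light capture saturates on the *patch* total leaf carbon (one shared
    canopy) and is partitioned among cohorts by their leaf-C share, so
    understorey cohorts are suppressed.  Surplus production is allocated with
    fixed PFT fractions, except that leaf growth stops once the patch canopy
    is closed (leaf C at the PFT's cap) and fine-root growth stops above a
    fixed root:leaf ratio; withheld shares go to the stem.  Mutates cohort
    pools, stores each cohort's growth efficiency for the stress-mortality
    channel, and routes leaf/fine-root turnover to litter.
    """
    if math.isnan(temp) or math.isnan(rad) or math.isnan(co2):
        raise ForcingNaNError("forcing contains NaN")
    total_leaf = patch.c_leaf
    capture = (1.0 - math.exp(-veg.canopy_k * total_leaf)) if total_leaf > 0 else 0.0
    q10m = min(veg.q10_resp ** ((temp - veg.resp_t_ref) / 10.0),
               veg.resp_t_factor_max)
    fco2 = 1.0 + veg.co2_beta * math.log(co2 / veg.co2_ref)
    for coh in patch.cohorts:
        p = pfts[coh.pft]
        ft = math.exp(-(((temp - p.t_opt) / p.t_width) ** 2))
        light = capture * (coh.c_leaf / total_leaf) if total_leaf > 0 else 0.0
        gpp = p.pmax * ft * fco2 * (rad / veg.rad_ref) * light
        rm = q10m * (p.resp_leaf * coh.c_leaf + p.resp_froot * coh.c_froot
                     + p.resp_stem * coh.c_stem)
        npp = (1.0 - p.growth_resp) * max(gpp - rm, 0.0)
        fra = gpp - npp

        l_leaf = coh.c_leaf / p.leaf_longevity
        l_froot = p.froot_turnover * coh.c_froot
        repl = l_leaf + l_froot
        if npp >= repl:
            s = npp - repl
            al = p.alloc_leaf if total_leaf < p.leaf_cap else 0.0
            af = (p.alloc_froot
                  if coh.c_froot < veg.froot_leaf_ratio * coh.c_leaf else 0.0)
            a_leaf = l_leaf + al * s
            a_froot = l_froot + af * s
            a_stem = (1.0 - al - af) * s
        else:
            scale = npp / repl if repl > 0 else 0.0
            a_leaf, a_froot, a_stem = scale * l_leaf, scale * l_froot, 0.0

        coh.ge = npp / coh.c_leaf if coh.c_leaf > 0 else 0.0
        coh.c_leaf += a_leaf - l_leaf
        coh.c_froot += a_froot - l_froot
        coh.c_stem += a_stem
        coh.age += 1.0

        fluxes.gpp += gpp
        fluxes.fra += fra
        fluxes.litter_leaf += l_leaf
        fluxes.litter_froot += l_froot
        route_litter(leaf=l_leaf, froot=l_froot,
                     lignin_leaf=p.lignin_frac_leaf,
                     lignin_froot=p.lignin_frac_froot, out=litter_out)


def plant(patch: Patch, pft: str, veg: VegParams) -> float:
    """Establish a sapling cohort; returns the establishment assimilation.

    First-year seedling production (a few gC m-2) is counted as part of GPP in
    the planting year, which keeps the ecosystem ledger identity exact.
    """
    patch.cohorts.append(Cohort(
        pft=pft, age=0.0, density=veg.sapling_density,
        c_stem=veg.estab_stem, c_leaf=veg.estab_leaf, c_froot=veg.estab_froot))
    return veg.estab_stem + veg.estab_leaf + veg.estab_froot


def _kill_fraction(coh: Cohort, frac: float, pfts: dict[str, PFTParams],
                   veg: VegParams, litter_out: np.ndarray,
                   fluxes: YearFluxes) -> float:
    """Route a dead fraction of a cohort to litter; returns dead stem C."""
    p = pfts[coh.pft]
    d_stem = frac * coh.c_stem
    d_leaf = frac * coh.c_leaf
    d_froot = frac * coh.c_froot
    route_litter(stem=d_stem, leaf=d_leaf, froot=d_froot,
                 lignin_leaf=p.lignin_frac_leaf,
                 lignin_froot=p.lignin_frac_froot,
                 cwd_frac=veg.cwd_frac, out=litter_out)
    coh.c_stem -= d_stem
    coh.c_leaf -= d_leaf
    coh.c_froot -= d_froot
    coh.density *= (1.0 - frac)
    fluxes.litter_stem += d_stem
    fluxes.litter_leaf += d_leaf
    fluxes.litter_froot += d_froot
    return d_stem


def apply_mortality(patch: Patch, rng: np.random.Generator,
                    pfts: dict[str, PFTParams], veg: VegParams,
                    tc_track: float, tw_track: float,
                    litter_out: np.ndarray, fluxes: YearFluxes) -> None:
    """Background + growth-efficiency-stress + bioclimatic mortality.

    Stem deaths are binomial draws on the integer stem count of each cohort;
    a cohort whose PFT falls outside its bioclimatic envelope dies whole.
    Dead stem C is recorded in the mortality flux (the stem-turnover channel);
    all dead biomass is routed to litter.  Empty patch is a no-op.
    """
    survivors: list[Cohort] = []
    for coh in patch.cohorts:
        p = pfts[coh.pft]
        outside = (tc_track < p.tc_min or tc_track > p.tc_max
                   or tw_track < p.tw_min)
        if outside:
            frac = 1.0
        else:
            prob = p.mort_background + veg.ageing_mort_scale * (
                (coh.age / p.longevity) ** veg.ageing_mort_power)
            if coh.ge < p.ge_threshold:
                prob += p.ge_mort_max * (1.0 - coh.ge / p.ge_threshold)
            prob = min(max(prob, 0.0), 1.0)
            n_stems = int(round(coh.density * veg.patch_area))
            if n_stems <= 0:
                frac = 1.0
            elif prob > 0.0:
                frac = rng.binomial(n_stems, prob) / n_stems
            else:
                frac = 0.0
        if frac > 0.0:
            fluxes.fmort_stem += _kill_fraction(coh, frac, pfts, veg,
                                                litter_out, fluxes)
        if coh.density * veg.patch_area >= 0.5 and coh.c_live > 0:
            survivors.append(coh)
        elif coh.c_live > 0:  # below half a stem: finish the cohort off
            fluxes.fmort_stem += _kill_fraction(coh, 1.0, pfts, veg,
                                                litter_out, fluxes)
    patch.cohorts[:] = survivors


def destroy_patch(patch: Patch, pfts: dict[str, PFTParams], veg: VegParams,
                  litter_out: np.ndarray, fluxes: YearFluxes) -> None:
    """Patch-destroying disturbance: all live C to litter, cohorts cleared."""
    for coh in patch.cohorts:
        fluxes.fdist_stem += _kill_fraction(coh, 1.0, pfts, veg,
                                            litter_out, fluxes)
    patch.cohorts.clear()


def apply_disturbance(stand: Stand, return_interval: float,
                      rng: np.random.Generator, pfts: dict[str, PFTParams],
                      veg: VegParams, litter_out: np.ndarray,
                      fluxes: YearFluxes) -> list[int]:
    """Destroy each patch independently with probability 1/return_interval.

    Returns the indices of destroyed patches (regeneration is scheduled by
    the caller according to the scenario's replanting rule).  An infinite
    interval disables the process; draws are consumed either way so that the
    destruction sequence is identical across scenarios sharing a stream.
    """
    if not return_interval > 0:
        raise ValueError("return interval must be positive")
    u = rng.random(stand.n_patches)
    if math.isinf(return_interval):
        return []
    prob = 1.0 / return_interval
    destroyed = [i for i in range(stand.n_patches) if u[i] < prob]
    for i in destroyed:
        destroy_patch(stand.patches[i], pfts, veg, litter_out, fluxes)
    return destroyed


def burned_fraction(temp: float, precip: float, fire: FireParams) -> float:
    """Annual burned area fraction: base rate times a dryness multiplier."""
    dry = min(max(fire.dryness_ref / max(precip, 1.0), fire.dryness_min),
              fire.dryness_max)
    frac = fire.base_rate * dry
    if not 0.0 <= frac <= 1.0:
        raise ValueError("burned fraction outside [0, 1]")
    return frac


def apply_fire(patch: Patch, frac: float, fire: FireParams,
               pfts: dict[str, PFTParams], veg: VegParams,
               litter_out: np.ndarray, fluxes: YearFluxes) -> None:
    """Burn one unmanaged patch: combust live pools, kill part of the rest.

    Managed patches never burn (callers pass them over); combusted C leaves
    as the fire flux, killed-but-uncombusted biomass becomes litter.
    """
    if patch.managed or frac <= 0.0:
        return
    survivors: list[Cohort] = []
    for coh in patch.cohorts:
        p = pfts[coh.pft]
        comb_leaf = frac * fire.cc_leaf * coh.c_leaf
        comb_stem = frac * fire.cc_stem * coh.c_stem
        fluxes.ffire_live += comb_leaf + comb_stem
        fluxes.ffire_stem += comb_stem
        coh.c_leaf -= comb_leaf
        coh.c_stem -= comb_stem
        # killed-but-uncombusted biomass becomes litter; it is not attributed
        # to the stem-turnover fire term, which counts combustion only
        killed = frac * fire.kill_frac
        if killed > 0.0:
            _kill_fraction(coh, killed, pfts, veg, litter_out, fluxes)
        if coh.density * veg.patch_area >= 0.5 and coh.c_live > 0:
            survivors.append(coh)
        elif coh.c_live > 0:
            _kill_fraction(coh, 1.0, pfts, veg, litter_out, fluxes)
    patch.cohorts[:] = survivors


def burn_surface_litter(pools: np.ndarray, frac: float, fire: FireParams
                        ) -> float:
    """Combust surface litter pools over the burned fraction; returns flux."""
    flux = 0.0
    for name, cc in fire.cc_litter.items():
        i = POOL_INDEX[name]
        burnt = frac * cc * pools[i]
        pools[i] -= burnt
        flux += burnt
    return flux


def mean_height(stand: Stand, veg: VegParams) -> float:
    """Density-weighted mean cohort height over the analysis patches."""
    num = den = 0.0
    for patch in stand.patches:
        for coh in patch.cohorts:
            num += coh.density * coh.height(veg)
            den += coh.density
    return num / den if den > 0 else 0.0


def forest_filter(mean_heights, threshold: float = 5.0) -> np.ndarray:
    """Cells whose scenario-average height reaches the forest threshold.

    The bound is closed: a cell at exactly the threshold is retained.
    """
    return np.asarray(mean_heights, dtype=float) >= threshold
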