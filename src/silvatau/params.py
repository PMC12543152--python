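"""Default parameter sets for the reduced forest carbon model.

All constants that the science does not pin down are collected here so that a
run is fully described by (config, seed).  Units: carbon pools kgC m-2, fluxes
kgC m-2 yr-1, temperature degC, precipitation mm yr-1, density stems m-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PFTS = ("NE", "ND", "BD", "BE")

#: grouped Koppen-Geiger classes retained for the analysis; "tundra" is
#: recognised by the classifier but never assigned to synthetic grid cells.
ZONES = (
    "arid",
    "cold with cold summer",
    "cold with warm summer",
    "temperate without dry season",
    "temperate with dry summer",
)

PFT_GROUP = {"NE": "needleleaved", "ND": "needleleaved",
             "BD": "broadleaved", "BE": "broadleaved"}


@dataclass(frozen=True)
class PFTParams:
    """Physiology, allometry and demography of one plant functional type."""

    name: str
    pmax: float              # light-saturated canopy production, kgC m-2 yr-1
    t_opt: float             # temperature optimum of production, degC
    t_width: float           # Gaussian width of the temperature response, degC
    leaf_cap: float          # canopy-closure leaf C above which no leaf growth
    leaf_longevity: float    # yr (1 for deciduous)
    froot_turnover: float    # yr-1
    alloc_leaf: float        # surplus-NPP allocation fractions (sum to 1)
    alloc_froot: float
    alloc_stem: float
    resp_leaf: float         # maintenance respiration coefficients, yr-1
    resp_froot: float
    resp_stem: float
    growth_resp: float       # fraction of assimilate surplus respired as growth
    longevity: float         # yr, scales the ageing mortality ramp
    mort_background: float   # yr-1 baseline stochastic mortality
    ge_threshold: float      # growth-efficiency stress threshold, yr-1 per kgC leaf
    ge_mort_max: float       # added mortality prob. when efficiency reaches zero
    tc_min: float            # bioclimatic envelope: coldest-month degC limits
    tc_max: float
    tw_min: float            # minimum warmest-month degC
    lignin_frac_leaf: float  # structural (lignin-rich) share of leaf litter
    lignin_frac_froot: float


def _pft(name, **kw) -> PFTParams:
    base = dict(
        t_width=12.0, froot_turnover=0.7,
        alloc_leaf=0.30, alloc_froot=0.10, alloc_stem=0.60,
        resp_leaf=0.18, resp_froot=0.22, resp_stem=0.12, growth_resp=0.25,
        ge_threshold=0.08, ge_mort_max=0.3,
    )
    base.update(kw)
    return PFTParams(name=name, **base)


DEFAULT_PFTS: dict[str, PFTParams] = {
    "NE": _pft("NE", pmax=2.6, t_opt=12.0, leaf_cap=0.7, leaf_longevity=3.0,
               longevity=400.0, mort_background=0.005,
               tc_min=-32.0, tc_max=9.0, tw_min=10.0,
               lignin_frac_leaf=0.45, lignin_frac_froot=0.55),
    "ND": _pft("ND", pmax=2.4, t_opt=10.0, leaf_cap=0.5, leaf_longevity=1.0,
               longevity=350.0, mort_background=0.006,
               tc_min=-45.0, tc_max=-2.0, tw_min=10.0,
               lignin_frac_leaf=0.40, lignin_frac_froot=0.50),
    "BD": _pft("BD", pmax=3.0, t_opt=16.0, leaf_cap=0.6, leaf_longevity=1.0,
               longevity=250.0, mort_background=0.010,
               tc_min=-30.0, tc_max=18.0, tw_min=10.0,
               lignin_frac_leaf=0.30, lignin_frac_froot=0.40),
    # evergreen broadleaves: year-round canopy maintenance makes them the
    # high-respiration, low-stock type
    "BE": _pft("BE", pmax=3.2, t_opt=20.0, leaf_cap=0.7, leaf_longevity=2.0,
               longevity=200.0, mort_background=0.012,
               resp_leaf=0.28, resp_stem=0.16,
               tc_min=-0.5, tc_max=22.0, tw_min=14.0,
               lignin_frac_leaf=0.40, lignin_frac_froot=0.45),
}


@dataclass(frozen=True)
class VegParams:
    """Stand-level vegetation constants shared across PFTs."""

    co2_ref: float = 400.0       # ppm, reference for the fertilisation term
    co2_beta: float = 0.15       # GPP multiplier = 1 + beta*ln(CO2/co2_ref)
    canopy_k: float = 3.5        # light capture = 1 - exp(-k * patch leaf C)
    froot_leaf_ratio: float = 1.0  # fine-root growth allowed up to this x leaf
    q10_resp: float = 2.0        # maintenance respiration Q10 (ref 15 degC)
    resp_t_ref: float = 15.0
    resp_t_factor_max: float = 3.5
    rad_ref: float = 0.75        # radiation index at which pmax is attained
    # height h = h_coef * (stem kgC per tree)**h_exp (metres)
    h_coef: float = 2.0
    h_exp: float = 0.4
    # quadratic mean diameter D_cm = (stem kgC per tree / d_coef)**(1/d_exp)
    d_coef: float = 0.03
    d_exp: float = 2.5
    # (re)planting: sapling density and first-year establishment production
    sapling_density: float = 0.25          # stems m-2
    estab_leaf: float = 0.002              # kgC m-2 assimilated at planting
    estab_froot: float = 0.0015
    estab_stem: float = 0.0015
    canopy_open_leaf: float = 0.10         # kgC m-2 leaf below which regen occurs
    max_cohorts: int = 8
    cwd_frac: float = 0.7                  # coarse share of dead-stem litter
    ageing_mort_scale: float = 0.25        # added prob. = scale*(age/longevity)**6
    ageing_mort_power: float = 6.0
    bioclim_ema_alpha: float = 0.10        # smoothing of the climate tracker
    patch_area: float = 1000.0             # m2, sets stem counts for demography


@dataclass(frozen=True)
class FireParams:
    """Parametric stand-in for a process fire model (unmanaged stands only)."""

    base_rate: float = 0.015        # mean annual burned fraction
    dryness_ref: float = 450.0      # mm; multiplier = clip(ref/precip, lo, hi)
    dryness_min: float = 0.25
    dryness_max: float = 2.5
    cc_leaf: float = 0.7            # combustion completeness, live pools
    cc_stem: float = 0.2
    kill_frac: float = 0.5          # burned-but-uncombusted stems that die
    # combustion completeness of surface litter pools within the burned area
    cc_litter: dict[str, float] = field(default_factory=lambda: {
        "SURFCWD": 0.3, "SURFFWD": 0.7, "SURFSTRUCT": 0.7,
        "SURFMETA": 0.7, "SURFHUMUS": 0.4,
    })


#: harvest partitioning constants
WOOD_REMOVAL_FRAC = 0.66      # share of felled wood removed from the stand
LEAF_REMOVAL_FRAC = 0.30      # share of felled leaf removed from the stand
WOOD_OXIDISED_FRAC = 0.67     # share of removed wood oxidised in the same year
PRODUCT_OXIDATION_RATE = 0.04  # yr-1 decay of the wood product pool


@dataclass(frozen=True)
class ThinningParams:
    """Reineke maximum-density rule for one PFT group."""

    k_density: float           # stems ha-1 at reference diameter
    exponent: float = 1.605
    d_ref_cm: float = 25.0
    trigger_frac: float = 1.0  # thin when density > trigger * N_max
    target_frac: float = 0.9   # thin down to target * N_max


#: broadleaves self-thin at lower maximum density than conifers
DEFAULT_THINNING = {
    "needleleaved": ThinningParams(k_density=1050.0),
    "broadleaved": ThinningParams(k_density=700.0),
}


SOIL_POOLS = (
    "SURFCWD", "SURFFWD", "SURFSTRUCT", "SURFMETA", "SURFHUMUS",
    "SOILSTRUCT", "SOILMETA", "ACTIVE", "SLOW", "PASSIVE",
)
_IDX = {p: i for i, p in enumerate(SOIL_POOLS)}


def _default_topology() -> np.ndarray:
    """Transfer matrix T[i, j]: share of pool i's decay routed to pool j.

    The remainder of each row (1 - sum - DOC share for ACTIVE) is respired.
    Standard litter->humus->active->slow->passive cascade.
    """
    t = np.zeros((10, 10))

    def put(src, dst, frac):
        t[_IDX[src], _IDX[dst]] = frac

    put("SURFCWD", "SURFHUMUS", 0.45)
    put("SURFFWD", "SURFHUMUS", 0.45)
    put("SURFSTRUCT", "SURFHUMUS", 0.45)
    put("SURFMETA", "SURFHUMUS", 0.45)
    put("SURFHUMUS", "ACTIVE", 0.40)
    put("SOILSTRUCT", "ACTIVE", 0.40)
    put("SOILSTRUCT", "SLOW", 0.15)
    put("SOILMETA", "ACTIVE", 0.45)
    put("ACTIVE", "SLOW", 0.30)
    put("ACTIVE", "PASSIVE", 0.04)
    put("SLOW", "ACTIVE", 0.42)
    put("SLOW", "PASSIVE", 0.03)
    put("PASSIVE", "ACTIVE", 0.45)
    return t


@dataclass(frozen=True)
class SoilParams:
    """CENTURY-style cascade: intrinsic rates, topology, climate modifiers."""

    k: np.ndarray = field(default_factory=lambda: np.array(
        # SURFCWD SURFFWD SURFSTR SURFMET SURFHUM SOILSTR SOILMET ACTIVE SLOW PASSIVE
        [0.08, 0.25, 0.38, 5.0, 0.02, 0.45, 6.0, 0.7, 0.006, 0.00045]))
    topology: np.ndarray = field(default_factory=_default_topology)
    q10: float = 2.0            # f(T) = q10**((T - t_ref)/10), capped
    t_ref: float = 10.0
    f_t_max: float = 3.5
    moisture_half: float = 400.0  # g(P) = P / (P + moisture_half)
    doc_coeff: float = 0.01       # DOC share of ACTIVE-pool decay, times g(P)
    n_substeps: int = 24

    def __post_init__(self):
        rowsum = self.topology.sum(axis=1)
        if np.any(rowsum > 1.0 + 1e-12) or np.any(self.topology < 0):
            raise ValueError("topology rows must be nonnegative, summing <= 1")
        if np.any(self.k < 0):
            raise ValueError("decay rates must be nonnegative")


@dataclass(frozen=True)
class ZoneClimate:
    """Prototype climatology used to synthesise forcing for one zone."""

    t_mean: float        # annual mean temperature, degC
    t_amp: float         # seasonal half-amplitude: Twarm = mean + amp
    precip: float        # annual precipitation, mm
    summer_frac: float   # share of precipitation in the summer half-year


ZONE_CLIMATE: dict[str, ZoneClimate] = {
    "arid": ZoneClimate(16.0, 9.0, 250.0, 0.30),
    "temperate with dry summer": ZoneClimate(14.0, 8.0, 600.0, 0.12),
    "temperate without dry season": ZoneClimate(9.0, 7.5, 800.0, 0.50),
    "cold with warm summer": ZoneClimate(5.0, 11.0, 650.0, 0.55),
    "cold with cold summer": ZoneClimate(-1.0, 12.0, 500.0, 0.50),
}

#: probability that a cell starts needle-leaved dominated, by zone
NEEDLE_DOMINANCE_P = {
    "arid": 0.5,
    "temperate with dry summer": 0.3,
    "temperate without dry season": 0.4,
    "cold with warm summer": 0.7,
    "cold with cold summer": 0.9,
}

#: representative planted PFT for each dominance group
GROUP_PFT = {"needleleaved": "NE", "broadleaved": "BD"}


@dataclass(frozen=True)
class NoiseParams:
    """Interannual and between-cell variability of the synthetic forcing."""

    sigma_t: float = 0.6        # degC, interannual temperature anomalies
    sigma_precip: float = 0.12  # relative, multiplicative precip anomalies
    sigma_rad: float = 0.04     # radiation-index anomalies
    rad_mean: float = 0.75
    cell_jitter_t: float = 0.5        # degC, fixed between-cell offsets
    cell_jitter_precip: float = 0.08  # relative


@dataclass(frozen=True)
class WarmingParams:
    """Trend settings for the climate-change forcing mode."""

    t_slope: float = 0.04        # degC yr-1 from the start of the trend
    co2_start: float = 400.0     # ppm
    co2_end: float = 850.0       # ppm, reached at trend_years
    trend_years: int = 90        # length of the ramp
    precip_slope: float = 0.0    # mm yr-1


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all process parameters for one experiment."""

    pfts: dict[str, PFTParams] = field(default_factory=lambda: dict(DEFAULT_PFTS))
    veg: VegParams = field(default_factory=VegParams)
    fire: FireParams = field(default_factory=FireParams)
    soil: SoilParams = field(default_factory=SoilParams)
    thinning: dict[str, ThinningParams] = field(default_factory=lambda: dict(DEFAULT_THINNING))
    noise: NoiseParams = field(default_factory=NoiseParams)
    warming: WarmingParams = field(default_factory=WarmingParams)
    co2_fixed: float = 400.0     # ppm in the management-only mode
    ndep_fixed: float = 0.8      # gN m-2 yr-1, constant in both modes
    disturbance_interval: float = 400.0  # yr; inf disables the process

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


DEFAULT_PARAMS = ModelParams()
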