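"""Annual stand stepper: orchestrates vegetation, management, harvest, fire,
disturbance and soil into one mass-conserving yearly update.

Order of operations within a year (documented convention):

1. planting events due this year (pending replants; natural regeneration in
   unmanaged patches with an open canopy) -- first-year establishment
   production counts toward GPP;
2. production, allocation and leaf/fine-root turnover;
3. demographic mortality (background, stress, bioclimatic);
4. fire on unmanaged patches (live combustion; surface-litter combustion is
   applied to the soil pools before the soil step);
5. management: initialisation-wave conversions, scheduled clear-cuts or
   Reineke thinning, harvest partitioning and removal routing;
6. stochastic patch-destroying disturbance (replanting scheduled per the
   scenario rule for the following year);
7. soil cascade step with the year's litter inputs; product-pool step;
8. end-of-year recording.

Stochastic draws come from two per-stand streams: a general stream (mortality
binomials, in patch order then cohort order) and a dedicated disturbance
stream (one uniform vector per year), so that the destruction sequence is
identical across scenarios run with the same disturbance seed.
"""

from __future__ import annotations

import numpy as np

from .config import ScenarioConfig
from .harvest import ProductPool, partition_harvest, route_removals
from .ledger import StandLedger
from .management import (AgeStructurePlan, Felled, fell_patch,
                         natural_regen_pft, reineke_thin, replant_pft,
                         schedule_clearcut)
from .params import PFTS, SOIL_POOLS, ModelParams
from .soil import N_POOLS, route_litter, soil_equilibrium, step_soil
from .vegetation import (Patch, Stand, YearFluxes, annual_production,
                         apply_disturbance, apply_fire, apply_mortality,
                         burn_surface_litter, burned_fraction, mean_height,
                         plant)


def _dominant_pft(patch: Patch) -> str | None:
    if not patch.cohorts:
        return None
    return max(patch.cohorts, key=lambda c: c.c_stem).pft


def simulate_stand(forcing: dict[str, np.ndarray], t_amp: float,
                   initial_pft: str, scen: ScenarioConfig,
                   params: ModelParams, *, n_patches: int = 25,
                   plan: AgeStructurePlan | None = None,
                   seed: int | np.random.SeedSequence = 0,
                   dist_seed: int | np.random.SeedSequence | None = None,
                   soil_accel_year: int | None = None,
                   cell_id: int = 0, zone: str = "") -> StandLedger:
    """Run one stand for the full forcing period and return its ledger.

    ``plan`` assigns analysis patches to historical conversion waves; when it
    is None all ``n_patches`` patches form the analysis set and are never
    converted before ``scen.management_start``.  ``soil_accel_year``, if set,
    replaces the soil state in that (pre-analysis) year with the analytic
    equilibrium of the trailing 30-yr mean litter input and climate.
    """
    temp_a = np.asarray(forcing["temp"], dtype=float)
    n_years = temp_a.size
    precip_a = np.asarray(forcing["precip"], dtype=float)
    rad_a = np.asarray(forcing["rad"], dtype=float)
    co2_a = np.asarray(forcing["co2"], dtype=float)

    pfts, veg, fire = params.pfts, params.veg, params.fire
    soilp = params.soil
    interval = params.disturbance_interval

    if plan is not None:
        conv_years: list[int | None] = list(plan.conversion_year)
    else:
        conv_years = [None] * n_patches
    n_analysis = len(conv_years)
    if n_analysis == 0:
        raise ValueError("no analysis patches: age structure is all pristine")

    rng = np.random.default_rng(seed)
    dist_rng = np.random.default_rng(dist_seed if dist_seed is not None else seed)

    # without a wave plan, managed scenarios run plantation stands throughout
    managed_init = scen.managed and plan is None
    stand = Stand(patches=[Patch(managed=managed_init)
                           for _ in range(n_analysis)],
                  pristine_patches=(plan.n_pristine if plan else 0),
                  cell_id=cell_id, scenario=scen.option)
    last_pft: list[str | None] = [None] * n_analysis
    soil_pools = np.zeros(N_POOLS)
    product = ProductPool()
    ledger = StandLedger(n_years=n_years, cell_id=cell_id,
                         scenario=scen.option, zone=zone)
    d = ledger.data

    t_ema = float(temp_a[0])
    alpha = veg.bioclim_ema_alpha
    accel_hist: list[tuple[np.ndarray, float, float]] = []
    accel_years: list[int] = []

    # initial establishment: bare ground colonised by the cell's dominant PFT
    for i, patch in enumerate(stand.patches):
        last_pft[i] = initial_pft

    start = scen.management_start

    for year in range(n_years):
        temp, precip = float(temp_a[year]), float(precip_a[year])
        rad, co2 = float(rad_a[year]), float(co2_a[year])
        t_ema = (1.0 - alpha) * t_ema + alpha * temp if year else temp
        tc_track, tw_track = t_ema - t_amp, t_ema + t_amp
        viable = [p for p in PFTS
                  if pfts[p].tc_min <= tc_track <= pfts[p].tc_max
                  and tw_track >= pfts[p].tw_min]

        fx = YearFluxes()
        litter = np.zeros(N_POOLS)
        estab_gpp = 0.0
        harv = {"to_atm": 0.0, "to_products": 0.0, "to_litter": 0.0,
                "felled_wood": 0.0, "felled_leaf": 0.0, "felled_total": 0.0}

        unmanaged_now = (not scen.managed) and year >= start
        if unmanaged_now:
            for patch in stand.patches:
                patch.managed = False
        # before the management start every option replants the pre-death
        # species (the scenarios share one initialisation history)
        replant_option = scen.option if year >= start else "base"

        # --- 1. planting -------------------------------------------------
        for i, patch in enumerate(stand.patches):
            if patch.pending_plant:
                due = [pp for pp in patch.pending_plant if pp[0] <= year]
                patch.pending_plant = [pp for pp in patch.pending_plant
                                       if pp[0] > year]
                for _, pft in due:
                    estab_gpp += plant(patch, pft, veg)
                    last_pft[i] = pft
            elif not patch.managed and not patch.cohorts:
                # natural regeneration colonises emptied patches only; gap
                # dynamics come from the patch-destroying disturbance
                pft = natural_regen_pft(last_pft[i], initial_pft, viable)
                if pft is not None:
                    estab_gpp += plant(patch, pft, veg)
                    last_pft[i] = pft

        # --- 2. production ----------------------------------------------
        for patch in stand.patches:
            annual_production(patch, temp, rad, co2, pfts, veg, litter, fx)

        # --- 3. mortality -------------------------------------------------
        for patch in stand.patches:
            apply_mortality(patch, rng, pfts, veg, tc_track, tw_track,
                            litter, fx)

        # --- 4. fire (unmanaged patches only) -----------------------------
        ffire_litter = 0.0
        if fire.base_rate > 0.0:
            frac = burned_fraction(temp, precip, fire)
            n_burnable = sum(1 for p in stand.patches if not p.managed)
            if n_burnable:
                for patch in stand.patches:
                    apply_fire(patch, frac, fire, pfts, veg, litter, fx)
                ffire_litter = burn_surface_litter(
                    soil_pools, frac * n_burnable / n_analysis, fire)

        # --- 5. management -------------------------------------------------
        def process_harvest(felled: Felled, lignin_pft: str) -> None:
            if felled.total <= 0.0:
                return
            split = partition_harvest(felled.wood, felled.leaf, felled.froot)
            to_atm, to_prod = route_removals(split.removed_wood,
                                             split.removed_leaf)
            p = pfts[lignin_pft]
            route_litter(stem=split.residue_wood, leaf=split.residue_leaf,
                         froot=split.residue_froot,
                         lignin_leaf=p.lignin_frac_leaf,
                         lignin_froot=p.lignin_frac_froot,
                         cwd_frac=veg.cwd_frac, out=litter)
            harv["to_atm"] += to_atm
            harv["to_products"] += to_prod
            harv["to_litter"] += split.residue_total
            harv["felled_wood"] += felled.wood
            harv["felled_leaf"] += felled.leaf
            harv["felled_total"] += felled.total

        cut_year = schedule_clearcut(year, scen)
        for i, patch in enumerate(stand.patches):
            cy = conv_years[i]
            if cy is not None and year == cy and not patch.managed:
                # initialisation wave: convert to managed with a clear-cut
                prev = _dominant_pft(patch) or last_pft[i] or initial_pft
                felled = fell_patch(patch)
                process_harvest(felled, prev)
                patch.managed = True
                patch.pending_plant.clear()
                estab_gpp += plant(patch, prev, veg)   # same-year replant
                last_pft[i] = prev
            elif patch.managed and year >= start and cut_year:
                prev = _dominant_pft(patch) or last_pft[i] or initial_pft
                felled = fell_patch(patch)
                process_harvest(felled, prev)
                patch.pending_plant.clear()
                new_pft = replant_pft(replant_option, prev, initial_pft)
                estab_gpp += plant(patch, new_pft, veg)
                last_pft[i] = new_pft
            elif patch.managed and scen.thin_enabled and patch.cohorts:
                prev = _dominant_pft(patch) or last_pft[i] or initial_pft
                felled = reineke_thin(patch, params.thinning, pfts, veg)
                process_harvest(felled, prev)

        # --- 6. disturbance ------------------------------------------------
        destroyed = apply_disturbance(stand, interval, dist_rng, pfts, veg,
                                      litter, fx)
        for i in destroyed:
            patch = stand.patches[i]
            prev = last_pft[i] or initial_pft
            if patch.managed:
                new_pft = replant_pft(replant_option, prev, initial_pft)
                patch.pending_plant.append((year + scen.replant_lag, new_pft))
        # managed patches emptied by mortality also get replanted with a lag
        for i, patch in enumerate(stand.patches):
            if (patch.managed and not patch.cohorts
                    and not patch.pending_plant):
                new_pft = replant_pft(replant_option,
                                      last_pft[i] or initial_pft, initial_pft)
                patch.pending_plant.append((year + scen.replant_lag, new_pft))

        # --- 7. soil and product pool ---------------------------------------
        litter /= n_analysis
        if soil_accel_year is not None:
            accel_hist.append((litter.copy(), temp, precip))
            if len(accel_hist) > 30:
                accel_hist.pop(0)
        res = step_soil(soil_pools, temp, precip, soilp, inputs=litter)
        soil_pools = res.pools
        if soil_accel_year is not None and year == soil_accel_year:
            mean_in = np.mean([h[0] for h in accel_hist], axis=0)
            mean_t = float(np.mean([h[1] for h in accel_hist]))
            mean_p = float(np.mean([h[2] for h in accel_hist]))
            soil_pools = soil_equilibrium(mean_in, mean_t, mean_p, soilp)
            accel_years.append(year)

        to_products = harv["to_products"] / n_analysis
        prod_ox = product.step(to_products)

        # --- 8. record -------------------------------------------------------
        n = float(n_analysis)
        d["gpp"][year] = (fx.gpp + estab_gpp) / n
        d["fra"][year] = fx.fra / n
        d["npp"][year] = d["gpp"][year] - d["fra"][year]
        d["frh"][year] = res.total_rh
        d["fdoc"][year] = res.fdoc
        d["ffire"][year] = fx.ffire_live / n + ffire_litter
        d["ffire_stem"][year] = fx.ffire_stem / n
        d["ffire_litter"][year] = ffire_litter
        d["fmort"][year] = fx.fmort_stem / n
        d["fdist"][year] = fx.fdist_stem / n
        d["fharv_total"][year] = harv["felled_total"] / n
        d["fharv_stem"][year] = harv["felled_wood"] / n
        d["fharv_to_products"][year] = to_products
        d["fharv_to_atm"][year] = harv["to_atm"] / n
        d["fharv_to_litter"][year] = harv["to_litter"] / n
        d["product_oxidation"][year] = prod_ox
        d["litter_input"][year] = float(litter.sum())

        c_leaf = sum(p.c_leaf for p in stand.patches) / n
        c_froot = sum(sum(c.c_froot for c in p.cohorts)
                      for p in stand.patches) / n
        c_stem = sum(sum(c.c_stem for c in p.cohorts)
                     for p in stand.patches) / n
        c_soil = float(soil_pools.sum())
        d["c_leaf"][year] = c_leaf
        d["c_froot"][year] = c_froot
        d["c_stem"][year] = c_stem
        d["c_soil"][year] = c_soil
        d["c_eco"][year] = c_leaf + c_froot + c_stem + c_soil
        d["c_products"][year] = product.carbon
        d["height"][year] = mean_height(stand, veg)
        for k, pool_name in enumerate(SOIL_POOLS):
            d[f"pool_{pool_name}"][year] = soil_pools[k]
            d[f"out_{pool_name}"][year] = res.outflow[k]

    ledger.accel_years = tuple(accel_years)
    return ledger
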