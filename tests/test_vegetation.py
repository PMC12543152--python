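"""Cohort dynamics: production fixed point, mortality channels, disturbance,
fire arithmetic, height bookkeeping and the stand mass balance."""

import dataclasses
import math

import numpy as np
import pytest

from silvatau.params import DEFAULT_PARAMS, FireParams
from silvatau.simulate import simulate_stand
from silvatau.soil import new_pools
from silvatau.vegetation import (Cohort, ForcingNaNError, Patch, Stand,
                                 YearFluxes, annual_production,
                                 apply_disturbance, apply_fire,
                                 apply_mortality, burn_surface_litter,
                                 burned_fraction, forest_filter, mean_height)
from tests.conftest import constant_forcing

PFTS = DEFAULT_PARAMS.pfts
VEG = DEFAULT_PARAMS.veg


def one_cohort_patch(pft="BD", density=0.2, stem=5.0, leaf=0.5, froot=0.4,
                     age=40.0, managed=False) -> Patch:
    return Patch(cohorts=[Cohort(pft=pft, age=age, density=density,
                                 c_stem=stem, c_leaf=leaf, c_froot=froot)],
                 managed=managed)


class TestProduction:
    def test_no_leaves_no_production(self):
        patch = one_cohort_patch(leaf=0.0)
        fx, litter = YearFluxes(), new_pools()
        annual_production(patch, 15.0, 0.75, 400.0, PFTS, VEG, litter, fx)
        assert fx.gpp == 0.0

    def test_disabled_co2_fertilisation(self):
        veg0 = dataclasses.replace(VEG, co2_beta=0.0)
        gpps = []
        for co2 in (400.0, 800.0):
            patch = one_cohort_patch()
            fx, litter = YearFluxes(), new_pools()
            annual_production(patch, 15.0, 0.75, co2, PFTS, veg0, litter, fx)
            gpps.append(fx.gpp)
        assert gpps[0] == pytest.approx(gpps[1], rel=1e-12)

    def test_nan_forcing_rejected(self):
        with pytest.raises(ForcingNaNError):
            annual_production(one_cohort_patch(), float("nan"), 0.75, 400.0,
                              PFTS, VEG, new_pools(), YearFluxes())

    def test_patch_gpp_saturates_on_total_leaf(self):
        """Two cohorts sharing a canopy produce no more than one big one."""
        single = one_cohort_patch(leaf=1.0)
        split = Patch(cohorts=[
            Cohort(pft="BD", age=40, density=0.1, c_stem=2.5, c_leaf=0.5,
                   c_froot=0.2),
            Cohort(pft="BD", age=40, density=0.1, c_stem=2.5, c_leaf=0.5,
                   c_froot=0.2)])
        out = []
        for patch in (single, split):
            fx = YearFluxes()
            annual_production(patch, 15.0, 0.75, 400.0, PFTS, VEG,
                              new_pools(), fx)
            out.append(fx.gpp)
        assert out[1] == pytest.approx(out[0], rel=1e-9)

    def test_fixed_point_reached(self, quiet_params, unmanaged_scen):
        """Constant forcing, no death channels: pools converge to a fixed
        point with |dC| < 1e-6 kgC m-2 yr-1 after 300 years, nondecreasing."""
        forcing = constant_forcing(300)
        led = simulate_stand(forcing, t_amp=7.5, initial_pft="BD",
                             scen=unmanaged_scen, params=quiet_params,
                             n_patches=1, seed=0)
        c_live = led["c_leaf"] + led["c_froot"] + led["c_stem"]
        dc = np.diff(c_live)
        assert np.all(dc >= -1e-12)          # monotone approach
        assert abs(dc[-1]) < 1e-6            # fixed point reached

    def test_fixed_point_matches_direct_iteration(self, quiet_params,
                                                  unmanaged_scen):
        """The simulator's fixed point equals iterating the closed-form
        single-cohort update directly (independent oracle)."""
        forcing = constant_forcing(400)
        led = simulate_stand(forcing, t_amp=7.5, initial_pft="NE",
                             scen=unmanaged_scen, params=quiet_params,
                             n_patches=1, seed=0)
        patch = Patch(cohorts=[Cohort(pft="NE", density=VEG.sapling_density,
                                      c_stem=VEG.estab_stem,
                                      c_leaf=VEG.estab_leaf,
                                      c_froot=VEG.estab_froot)])
        for _ in range(400):
            annual_production(patch, 15.0, 0.75, 400.0, quiet_params.pfts,
                              quiet_params.veg, new_pools(), YearFluxes())
        coh = patch.cohorts[0]
        assert led["c_stem"][-1] == pytest.approx(coh.c_stem, rel=1e-9)
        assert led["c_leaf"][-1] == pytest.approx(coh.c_leaf, rel=1e-9)


class TestMortality:
    def kill_rng(self, seed=0):
        return np.random.default_rng(seed)

    def test_empty_patch_noop(self):
        fx = YearFluxes()
        apply_mortality(Patch(), self.kill_rng(), PFTS, VEG, 0.0, 20.0,
                        new_pools(), fx)
        assert fx.fmort_stem == 0.0

    def test_background_rate_binomial_oracle(self):
        """Mean killed fraction over many replicates equals the background
        rate within 3 sigma of the binomial standard error."""
        m = PFTS["BD"].mort_background
        n_stems = int(0.2 * VEG.patch_area)
        reps = 3000
        rng = self.kill_rng(123)
        fracs = np.empty(reps)
        for r in range(reps):
            patch = one_cohort_patch(age=0.0)   # ageing term ~ 0
            before = patch.cohorts[0].density
            apply_mortality(patch, rng, PFTS, VEG, 0.0, 20.0, new_pools(),
                            YearFluxes())
            after = patch.cohorts[0].density if patch.cohorts else 0.0
            fracs[r] = 1.0 - after / before
        se = math.sqrt(m * (1 - m) / n_stems / reps)
        assert abs(fracs.mean() - m) < 3 * se

    def test_bioclim_kill_whole_cohort(self):
        """A broadleaved evergreen cohort dies whole in a cold-winter
        climate (coldest month far below its envelope minimum)."""
        patch = one_cohort_patch(pft="BE")
        fx = YearFluxes()
        apply_mortality(patch, self.kill_rng(), PFTS, VEG, -13.0, 11.0,
                        new_pools(), fx)
        assert patch.cohorts == []
        assert fx.fmort_stem == pytest.approx(5.0)

    def test_stress_mortality_raises_rate(self):
        rng = np.random.default_rng(7)
        killed = {}
        for ge in (1.0, 0.0):
            fracs = []
            for _ in range(400):
                patch = one_cohort_patch(age=0.0)
                patch.cohorts[0].ge = ge
                before = patch.cohorts[0].density
                apply_mortality(patch, rng, PFTS, VEG, 0.0, 20.0,
                                new_pools(), YearFluxes())
                after = patch.cohorts[0].density if patch.cohorts else 0.0
                fracs.append(1.0 - after / before)
            killed[ge] = np.mean(fracs)
        assert killed[0.0] > killed[1.0] + 0.1


class TestDisturbance:
    def make_stand(self, n=25):
        return Stand(patches=[one_cohort_patch() for _ in range(n)])

    def test_disabled_interval_no_flux(self):
        fx = YearFluxes()
        destroyed = apply_disturbance(self.make_stand(), math.inf,
                                      np.random.default_rng(0), PFTS, VEG,
                                      new_pools(), fx)
        assert destroyed == [] and fx.fdist_stem == 0.0

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            apply_disturbance(self.make_stand(), 0.0,
                              np.random.default_rng(0), PFTS, VEG,
                              new_pools(), YearFluxes())

    def test_seeded_sequence_reproducible(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            seq = []
            for year in range(200):
                stand = self.make_stand()
                seq.append(tuple(apply_disturbance(
                    stand, 400.0, rng, PFTS, VEG, new_pools(), YearFluxes())))
            seqs.append(seq)
        assert seqs[0] == seqs[1]

    def test_patch_independence(self):
        """Destroying patch i never mutates patch j."""
        stand = self.make_stand(5)
        marks = [p.cohorts[0].c_stem for p in stand.patches]
        rng = np.random.default_rng(1)
        for _ in range(300):
            destroyed = apply_disturbance(stand, 50.0, rng, PFTS, VEG,
                                          new_pools(), YearFluxes())
            for i in range(5):
                if i not in destroyed and stand.patches[i].cohorts:
                    assert stand.patches[i].cohorts[0].c_stem == marks[i]
            for i in destroyed:
                stand.patches[i].cohorts = [Cohort(
                    pft="BD", density=0.2, c_stem=marks[i], c_leaf=0.5,
                    c_froot=0.4, age=1.0)]

    def test_empirical_return_interval(self):
        """25 patches over 10^4 yr at a 400-yr interval: the empirical mean
        destruction interval is statistically compatible with 400 yr."""
        rng = np.random.default_rng(2024)
        n_patches, years, interval = 25, 10_000, 400.0
        u = rng.random((years, n_patches))
        events = u < 1.0 / interval
        n_events = int(events.sum())
        est = years * n_patches / n_events
        # 99% CI of the mean geometric interval
        se = est / math.sqrt(n_events)
        assert abs(est - interval) < 2.576 * se


class TestFire:
    def test_managed_patch_never_burns(self):
        patch = one_cohort_patch(managed=True)
        fx = YearFluxes()
        apply_fire(patch, 0.05, DEFAULT_PARAMS.fire, PFTS, VEG, new_pools(),
                   fx)
        assert fx.ffire_live == 0.0

    def test_zero_base_rate_disables(self):
        fire = FireParams(base_rate=0.0)
        assert burned_fraction(20.0, 300.0, fire) == 0.0

    def test_stem_combustion_arithmetic(self):
        """Stem fire flux = burned fraction x completeness x stem pool."""
        fire = DEFAULT_PARAMS.fire
        stem = 5.0
        patch = one_cohort_patch(stem=stem)
        fx = YearFluxes()
        frac = 0.04
        apply_fire(patch, frac, fire, PFTS, VEG, new_pools(), fx)
        assert fx.ffire_stem == pytest.approx(frac * fire.cc_stem * stem)

    def test_surface_litter_combustion(self):
        fire = DEFAULT_PARAMS.fire
        pools = new_pools() + 1.0
        before = pools.sum()
        flux = burn_surface_litter(pools, 0.1, fire)
        assert flux == pytest.approx(before - pools.sum())
        assert flux == pytest.approx(0.1 * sum(fire.cc_litter.values()))


class TestHeight:
    def test_empty_stand_height_zero_filtered(self):
        stand = Stand(patches=[Patch()])
        assert mean_height(stand, VEG) == 0.0
        assert not forest_filter([0.0])[0]

    def test_uniform_height(self):
        coh = Cohort(pft="NE", density=0.1, c_stem=0.1 * (12.0 / VEG.h_coef)
                     ** (1.0 / VEG.h_exp))
        stand = Stand(patches=[Patch(cohorts=[coh])])
        assert mean_height(stand, VEG) == pytest.approx(12.0)
        assert forest_filter([12.0])[0]

    def test_threshold_is_closed_lower_bound(self):
        kept = forest_filter([4.9, 5.0, 5.1], threshold=5.0)
        assert list(kept) == [False, True, True]


class TestStandMassBalance:
    def test_annual_ledger_identity_with_all_processes(self, params):
        """dCeco = GPP - Fturn_eco every year, all processes active."""
        from silvatau.config import ScenarioConfig
        scen = ScenarioConfig(option="base", management_start=60)
        forcing = constant_forcing(220, temp=12.0, precip=700.0)
        rng = np.random.default_rng(5)
        forcing["temp"] = forcing["temp"] + rng.normal(0, 0.6, 220)
        led = simulate_stand(forcing, t_amp=9.0, initial_pft="NE", scen=scen,
                             params=params, n_patches=10, seed=3, dist_seed=4)
        resid = np.diff(led["c_eco"]) - (led["gpp"][1:] - led.fturn_eco[1:])
        assert np.max(np.abs(resid)) <= 1e-9 * max(led["c_eco"].max(), 1.0)

    def test_all_fluxes_nonnegative(self, params):
        from silvatau.config import ScenarioConfig
        from silvatau.ledger import FLUX_FIELDS
        scen = ScenarioConfig(option="unmanaged", management_start=100)
        forcing = constant_forcing(180, temp=16.0, precip=400.0)
        led = simulate_stand(forcing, t_amp=9.0, initial_pft="BD", scen=scen,
                             params=params, n_patches=8, seed=9)
        for f in FLUX_FIELDS:
            assert np.all(led[f] >= -1e-15), f
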