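"""Unit and property tests for the pool model and its fire module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrocycle.carbon_model import (
    annualize,
    apply_fire,
    area_weighted_total,
    compute_gpp,
    simulate,
    step,
)
from pyrocycle.types import (
    DEFAULT_CONFIG,
    ForcingSeries,
    MetRecord,
    ParameterSet,
    PoolState,
)
from conftest import constant_forcing


class TestComputeGpp:
    def test_zero_canopy_absorbs_no_light(self, savanna_params, met):
        assert compute_gpp(0.0, savanna_params, met) == 0.0

    def test_zero_efficiency(self, savanna_params, met):
        p = savanna_params.replace(lue=0.0)
        assert compute_gpp(500.0, p, met) == 0.0

    def test_saturation_asymptote(self, savanna_params, met):
        """Closed canopy: GPP -> lue * 0.5 * sw * g_T * days analytically."""
        p = savanna_params
        foliar = 50.0 * p.lcma  # LAI = 50
        g_t = min(np.exp(p.theta * (met.t_mean - DEFAULT_CONFIG.t_ref)),
                  DEFAULT_CONFIG.gt_cap)
        asymptote = p.lue * 0.5 * met.sw_rad * g_t * met.days
        assert compute_gpp(foliar, p, met) == pytest.approx(asymptote, rel=1e-6)

    def test_strictly_increasing_in_foliar(self, savanna_params, met):
        vals = [compute_gpp(f, savanna_params, met) for f in np.linspace(0, 2000, 50)]
        assert np.all(np.diff(vals) > 0)

    def test_negative_foliar_rejected(self, savanna_params, met):
        with pytest.raises(ValueError):
            compute_gpp(-1.0, savanna_params, met)

    def test_temperature_scalar_capped(self, savanna_params):
        hot = MetRecord(t_mean=80.0, precip=0.0, sw_rad=20.0, days=30.0)
        p = savanna_params.replace(theta=0.1)
        cap = p.lue * 0.5 * hot.sw_rad * DEFAULT_CONFIG.gt_cap * hot.days
        assert compute_gpp(1e5, p, hot) <= cap * (1 + 1e-12)


class TestApplyFire:
    def test_no_fire_leaves_state_unchanged(self, savanna_params, pools):
        new, emission, mort = apply_fire(pools, 0.0, savanna_params)
        assert emission == 0.0
        assert all(v == 0.0 for v in mort.values())
        np.testing.assert_array_equal(new.as_array(), pools.as_array())

    def test_worked_combustion_example(self):
        """Combustion and mortality arithmetic on a fixed pool state."""
        p = ParameterSet(
            lue=0.3, f_auto=0.5, alloc_foliar=0.3, alloc_labile=0.1,
            alloc_root=0.2, labile_release=0.25, lcma=60.0, turn_foliar=0.08,
            turn_root=0.05, turn_wood=0.004, decomp_litter=0.08,
            decomp_som=0.001, lit2som=0.02, theta=0.05, w_half=50.0,
            cc_foliar=0.9, cc_wood=0.1, cc_litter=0.5, cc_som=0.01,
            resilience=0.5,
        )
        state = PoolState(labile=0.0, foliar=200.0, fine_root=0.0, wood=1000.0,
                          litter=300.0, som=5000.0, water=100.0)
        new, emission, mort = apply_fire(state, 0.1, p)
        # 0.1 * (200*0.9 + 1000*0.1 + 300*0.5 + 5000*0.01) = 48
        assert emission == pytest.approx(48.0, rel=1e-14)
        assert mort["foliar"] == pytest.approx(1.0, rel=1e-12)
        assert mort["wood"] == pytest.approx(45.0, rel=1e-14)

    def test_full_resilience_suppresses_mortality(self, savanna_params, pools):
        p = savanna_params.replace(resilience=1.0)
        _, _, mort = apply_fire(pools, 0.7, p)
        assert all(v == 0.0 for v in mort.values())

    def test_emission_linear_in_burned_fraction(self, savanna_params, pools):
        _, e1, _ = apply_fire(pools, 0.1, savanna_params)
        _, e2, _ = apply_fire(pools, 0.2, savanna_params)
        _, e5, _ = apply_fire(pools, 0.5, savanna_params)
        assert e2 == pytest.approx(2 * e1, rel=1e-14)
        assert e5 == pytest.approx(5 * e1, rel=1e-14)

    def test_ba_out_of_range_rejected(self, savanna_params, pools):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                apply_fire(pools, bad, savanna_params)

    @given(cc=st.floats(0.0, 1.0), cc_hi=st.floats(0.0, 1.0),
           res=st.floats(0.0, 1.0), res_hi=st.floats(0.0, 1.0),
           ba=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_combustion_and_resilience(self, cc, cc_hi, res,
                                                   res_hi, ba):
        """More complete combustion never lowers the emission; more
        resilience never raises the mortality transfer."""
        lo, hi = sorted((cc, cc_hi))
        r_lo, r_hi = sorted((res, res_hi))
        base = savanna_like = dict(
            lue=0.3, f_auto=0.5, alloc_foliar=0.2, alloc_labile=0.1,
            alloc_root=0.2, labile_release=0.2, lcma=70.0, turn_foliar=0.08,
            turn_root=0.05, turn_wood=0.005, decomp_litter=0.08,
            decomp_som=0.001, lit2som=0.02, theta=0.05, w_half=50.0,
            cc_wood=0.15, cc_litter=0.5, cc_som=0.01,
        )
        state = PoolState(labile=10, foliar=100, fine_root=100, wood=900,
                          litter=200, som=4000, water=100)
        _, e_lo, _ = apply_fire(state, ba, ParameterSet(**base, cc_foliar=lo,
                                                        resilience=0.3))
        _, e_hi, _ = apply_fire(state, ba, ParameterSet(**base, cc_foliar=hi,
                                                        resilience=0.3))
        assert e_hi >= e_lo - 1e-12
        _, _, m_lo = apply_fire(state, ba, ParameterSet(**base, cc_foliar=0.5,
                                                        resilience=r_lo))
        _, _, m_hi = apply_fire(state, ba, ParameterSet(**base, cc_foliar=0.5,
                                                        resilience=r_hi))
        assert sum(m_hi.values()) <= sum(m_lo.values()) + 1e-12


def _hand_step(state: PoolState, p: ParameterSet, met: MetRecord, ba: float):
    """Independent re-derivation of one month, phase by phase."""
    cfg = DEFAULT_CONFIG
    g_t = min(np.exp(p.theta * (met.t_mean - cfg.t_ref)), cfg.gt_cap)
    lai = state.foliar / p.lcma
    apar = 0.5 * met.sw_rad * (1 - np.exp(-cfg.k_ext * lai))
    gpp = p.lue * apar * g_t * met.days
    ra = p.f_auto * gpp
    npp = gpp - ra

    lab = state.labile + p.alloc_labile * npp
    fol = state.foliar + p.alloc_foliar * npp
    root = state.fine_root + p.alloc_root * npp
    wood = state.wood + p.alloc_wood * npp
    rel = lab * p.labile_release
    lab -= rel
    fol += rel

    t_f, t_r, t_w = fol * p.turn_foliar, root * p.turn_root, wood * p.turn_wood
    fol -= t_f
    root -= t_r
    wood -= t_w
    lit = state.litter + t_f + t_r
    som = state.som + t_w

    g_w = state.water / (state.water + p.w_half)
    g = g_t * g_w
    rh_l = lit * p.decomp_litter * g
    to_som = lit * p.lit2som * g
    lit -= rh_l + to_som
    som += to_som
    rh_s = som * p.decomp_som * g
    som -= rh_s

    mf = 1 - p.resilience
    em = ba * (lab * p.cc_foliar + fol * p.cc_foliar + root * p.cc_foliar
               + wood * p.cc_wood + lit * p.cc_litter + som * p.cc_som)
    mort = ba * ((lab + fol + root) * (1 - p.cc_foliar) * mf
                 + wood * (1 - p.cc_wood) * mf)
    lab -= ba * lab * (p.cc_foliar + (1 - p.cc_foliar) * mf)
    fol -= ba * fol * (p.cc_foliar + (1 - p.cc_foliar) * mf)
    root -= ba * root * (p.cc_foliar + (1 - p.cc_foliar) * mf)
    wood -= ba * wood * (p.cc_wood + (1 - p.cc_wood) * mf)
    lit = lit - ba * lit * p.cc_litter + mort
    som -= ba * som * p.cc_som

    water = min(max(state.water + met.precip - gpp / cfg.wue, 0.0), cfg.w_max)
    pools = np.array([lab, fol, root, wood, lit, som, water])
    fluxes = dict(gpp=gpp, ra=ra, rh_litter=rh_l, rh_som=rh_s, fire=em)
    return pools, fluxes


class TestStep:
    def test_single_step_matches_hand_computation(self, savanna_params, pools,
                                                  met):
        new, flux = step(pools, savanna_params, met, 0.05)
        exp_pools, exp_flux = _hand_step(pools, savanna_params, met, 0.05)
        np.testing.assert_allclose(new.as_array(), exp_pools, rtol=1e-12)
        assert flux.gpp == pytest.approx(exp_flux["gpp"], rel=1e-12)
        assert flux.ra == pytest.approx(exp_flux["ra"], rel=1e-12)
        assert flux.rh_litter == pytest.approx(exp_flux["rh_litter"], rel=1e-12)
        assert flux.rh_som == pytest.approx(exp_flux["rh_som"], rel=1e-12)
        assert flux.fire_emission == pytest.approx(exp_flux["fire"], rel=1e-12)

    def test_source_free_decay(self, savanna_params, pools, met):
        """With lue = 0 and no fire, pools only lose carbon and the monthly
        loss is exactly the respired amount."""
        p = savanna_params.replace(lue=0.0)
        state = pools
        for _ in range(12):
            new, flux = step(state, p, met, 0.0)
            assert flux.gpp == 0.0
            assert new.total_carbon <= state.total_carbon
            loss = state.total_carbon - new.total_carbon
            assert loss == pytest.approx(flux.ra + flux.rh_litter + flux.rh_som,
                                         abs=1e-9)
            state = new

    def test_closure_single_step(self, savanna_params, pools, met):
        new, flux = step(pools, savanna_params, met, 0.1)
        lhs = new.total_carbon - pools.total_carbon
        rhs = flux.gpp - flux.ra - flux.rh_litter - flux.rh_som - flux.fire_emission
        assert lhs == pytest.approx(rhs, abs=1e-9 * max(1.0, pools.total_carbon))

    def test_fire_emission_linear_in_ba_within_step(self, savanna_params,
                                                    pools, met):
        _, f1 = step(pools, savanna_params, met, 0.1)
        _, f2 = step(pools, savanna_params, met, 0.2)
        assert f2.fire_emission == pytest.approx(2 * f1.fire_emission, rel=1e-12)

    def test_extreme_rates_never_go_negative(self, met):
        """Proportional flux limitation keeps pools at >= 0 even for rates
        that would overdraw a pool in one month."""
        p = ParameterSet(
            lue=0.5, f_auto=0.5, alloc_foliar=0.3, alloc_labile=0.1,
            alloc_root=0.2, labile_release=1.0, lcma=50.0, turn_foliar=1.0,
            turn_root=1.0, turn_wood=0.5, decomp_litter=1.0, decomp_som=0.5,
            lit2som=1.0, theta=0.1, w_half=5.0, cc_foliar=1.0, cc_wood=1.0,
            cc_litter=1.0, cc_som=0.1, resilience=0.0,
        )
        state = PoolState(labile=1, foliar=5, fine_root=5, wood=10, litter=5,
                          som=100, water=10)
        for _ in range(6):
            state, _ = step(state, p, met, 1.0)
            assert np.all(state.as_array() >= 0)


class TestSimulate:
    def test_deterministic(self, savanna_params, pools, small_forcing):
        t1 = simulate(savanna_params, pools, small_forcing)
        t2 = simulate(savanna_params, pools, small_forcing)
        np.testing.assert_array_equal(t1.pools, t2.pools)
        np.testing.assert_array_equal(t1.fluxes, t2.fluxes)

    def test_empty_forcing_rejected(self):
        with pytest.raises(ValueError):
            ForcingSeries(t_mean=[], precip=[], sw_rad=[], days=[], ba_frac=[])

    def test_conserves_carbon_over_14_years(self, savanna_params, pools):
        forcing = constant_forcing(168, ba=0.03)
        traj = simulate(savanna_params, pools, forcing)
        total = np.concatenate([[pools.total_carbon], traj.total_carbon])
        resid = np.diff(total) - (traj.gpp - traj.ra - traj.rh
                                  - traj.fire_emission)
        scale = np.maximum(1.0, total[:-1])
        assert np.all(np.abs(resid) < 1e-9 * scale)

    def test_matches_sequential_steps(self, savanna_params, pools):
        """simulate() is exactly the fold of step() over the forcing."""
        forcing = constant_forcing(6, ba=0.04)
        traj = simulate(savanna_params, pools, forcing)
        state = pools
        for i in range(6):
            state, flux = step(state, savanna_params, forcing.record(i),
                               forcing.ba_frac[i])
            np.testing.assert_allclose(traj.pools[i], state.as_array(),
                                       rtol=1e-14)


class TestAnnualize:
    def test_constant_flux_sums_to_twelve(self, savanna_params):
        forcing = constant_forcing(24, ba=0.0)
        traj = simulate(savanna_params, PoolState(0, 0, 0, 0, 0, 0, 100),
                        forcing)
        traj.fluxes[:, 0] = 1.0  # overwrite gpp with 1 gC/m2/month
        ann = annualize(traj)
        assert ann["gpp"].tolist() == [12.0, 12.0]

    def test_partial_year_rejected(self, savanna_params, pools):
        forcing = constant_forcing(13)
        traj = simulate(savanna_params, pools, forcing)
        with pytest.raises(ValueError):
            annualize(traj)

    def test_area_weighted_total_unit_conversion(self):
        # one cell of 1e12 m2 at 100 gC/m2/yr -> 0.1 PgC/yr
        assert area_weighted_total([100.0], [1e12]) == pytest.approx(0.1)

    def test_area_weighted_total_two_cells(self):
        got = area_weighted_total([100.0, 50.0], [1e12, 2e12])
        assert got == pytest.approx((100 * 1e12 + 50 * 2e12) * 1e-15)
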