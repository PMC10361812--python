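"""Flux model: controls, acquisition, digestion, recycling, closure."""
import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

import protistph as pp
from protistph.physiology import (
    effective_assimilation,
    quota_balancing,
)

CM = pp.make_config("CM")
PHYTO = pp.make_config("phytoplankton")
ZOO = pp.make_config("zooplankton")
GNCM = pp.make_config("GNCM")
PSNCM = pp.make_config("pSNCM")


def state_at(config, q=0.5, C=10.0, chl_frac=1.0, acq=1.0):
    """Biomass state with both quotas at normalized position q."""
    qn = config.NC_min + q * (config.NC_max - config.NC_min)
    qp = config.PC_min + q * (config.PC_max - config.PC_min)
    return pp.ProtistState(
        C=C, N=qn * C, P=qp * C, Chl=chl_frac * config.ChlC_max * C,
        acquired_capacity=acq,
    )


POOLS = pp.DissolvedPools()
PREY = pp.build_default_prey()


class TestControls:
    def test_satiation_represses_acquisition(self):
        photo, phago, up = pp.control_factors(state_at(CM, q=1.0), CM)
        assert phago <= 0.05
        assert up["N"] <= 0.05 and up["P"] <= 0.05

    def test_full_stress_fully_derepresses(self):
        photo, phago, up = pp.control_factors(state_at(CM, q=0.0), CM)
        assert photo == phago == up["N"] == up["P"] == 1.0

    @pytest.mark.parametrize("q", [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    def test_equal_priority_couples_photo_and_phago(self, q):
        photo, phago, _ = pp.control_factors(state_at(CM, q=q), CM)
        assert photo == pytest.approx(phago, abs=1e-12)

    @pytest.mark.parametrize("q", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_priority_orders_controls_at_every_quota(self, q):
        cm_photo = pp.make_config("CM", variant="photo_first")
        cm_phago = pp.make_config("CM", variant="phago_first")
        p1, g1, _ = pp.control_factors(state_at(cm_photo, q=q), cm_photo)
        assert p1 >= g1
        p2, g2, _ = pp.control_factors(state_at(cm_phago, q=q), cm_phago)
        assert g2 >= p2

    def test_priority_strict_at_mid_stress(self):
        cfg = pp.make_config("CM", variant="photo_first")
        photo, phago, _ = pp.control_factors(state_at(cfg, q=0.5), cfg)
        assert photo > phago

    def test_controls_monotone_in_stress(self):
        vals = [pp.control_factors(state_at(CM, q=q), CM)[0]
                for q in (0.9, 0.7, 0.5, 0.3, 0.1)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_quota_outside_bounds_rejected(self):
        bad = pp.ProtistState(C=10.0, N=5.0, P=0.1)  # N/C = 0.5 >> max
        with pytest.raises(ValueError, match="quota"):
            pp.control_factors(bad, CM)

    def test_starved_heterotroph_keeps_eating_when_replete(self):
        """A zooplankton at maximum quota is carbon-starved, not sated."""
        _, phago, _ = pp.control_factors(state_at(ZOO, q=1.0, chl_frac=0.0,
                                                  acq=0.0), ZOO)
        assert phago > 0.9


class TestPhotosynthesis:
    def test_darkness_gives_zero(self):
        assert pp.gross_photosynthesis(state_at(CM), 0.0, CM) == 0.0

    def test_default_light_saturates(self):
        s = state_at(CM)
        g500 = pp.gross_photosynthesis(s, 500.0, CM)
        gmax = pp.gross_photosynthesis(s, 1e6, CM)
        assert g500 >= 0.95 * gmax > 0.0

    def test_no_photosystems_no_fixation(self):
        assert pp.gross_photosynthesis(state_at(CM, chl_frac=0.0), 500.0,
                                       CM) == 0.0
        assert pp.gross_photosynthesis(state_at(GNCM, acq=0.0), 500.0,
                                       GNCM) == 0.0
        assert pp.gross_photosynthesis(state_at(ZOO), 500.0, ZOO) == 0.0

    def test_replete_cell_fixes_at_capacity(self):
        """Growth demand keeps fixation high when quota is full."""
        g = pp.gross_photosynthesis(state_at(CM, q=1.0), 500.0, CM)
        assert g > 0.9 * CM.photo_max_multiplier * CM.mu_max * 10.0 * 0.95


class TestUptake:
    def test_gncm_cannot_use_nitrate(self):
        pools = pp.DissolvedPools(NH4=0.0, NO3=10.0)
        v = pp.inorganic_uptake(state_at(GNCM), pools, GNCM)
        assert v[1] == 0.0 and v[0] == 0.0
        assert pp.inorganic_uptake(state_at(GNCM), pools, GNCM)[2] > 0.0

    def test_empty_pools_no_uptake(self):
        pools = pp.DissolvedPools(NH4=0.0, NO3=0.0, PO4=0.0)
        assert pp.inorganic_uptake(state_at(CM), pools, CM) == (0, 0, 0)

    def test_zooplankton_takes_up_nothing(self):
        assert pp.inorganic_uptake(state_at(ZOO), POOLS, ZOO) == (0, 0, 0)

    def test_ammonium_represses_nitrate_uptake(self):
        s = state_at(CM)
        with_nh4 = pp.inorganic_uptake(s, pp.DissolvedPools(NH4=10.0), CM)[1]
        no_nh4 = pp.inorganic_uptake(s, pp.DissolvedPools(NH4=0.0), CM)[1]
        assert with_nh4 < 0.1 * no_nh4


class TestIngestion:
    def test_no_prey_no_ingestion(self):
        empty = pp.PreyField(prey_C=0.0, prey_N=0.0, prey_P=0.0, prey_Chl=0.0)
        assert pp.ingestion(state_at(ZOO), empty, ZOO) == (0, 0, 0, 0)

    def test_non_phagotroph_never_ingests(self):
        assert pp.ingestion(state_at(PHYTO), PREY, PHYTO) == (0, 0, 0, 0)

    def test_larger_predator_higher_encounter(self):
        big = pp.make_config("CM", overrides={"ESD": 250.0})
        small = pp.make_config("CM", overrides={"ESD": 20.0})
        i_big = pp.ingestion(state_at(big), PREY, big)[0]
        i_small = pp.ingestion(state_at(small), PREY, small)[0]
        assert i_big > i_small

    def test_prey_stoichiometry_preserved(self):
        i_c, i_n, i_p, i_chl = pp.ingestion(state_at(ZOO), PREY, ZOO)
        assert i_n / i_c == pytest.approx(PREY.prey_N / PREY.prey_C)
        assert i_p / i_c == pytest.approx(PREY.prey_P / PREY.prey_C)


class TestDigestion:
    def test_default_partition_fractions(self):
        cfg = dataclasses.replace(ZOO, AE=0.75, SDA=0.30)
        (v,), (s,), (a,) = pp.digestion_partition((1.0,), cfg)
        assert v == pytest.approx(0.25)
        assert s == pytest.approx(0.225)
        assert a == pytest.approx(0.525)

    def test_lossless_assimilation(self):
        cfg = dataclasses.replace(ZOO, AE=1.0, SDA=0.0)
        (v,), (s,), (a,) = pp.digestion_partition((1.0,), cfg)
        assert (v, s, a) == (0.0, 0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ing=st.tuples(*[st.floats(0.0, 100.0)] * 3),
           ae=st.floats(0.05, 1.0), sda=st.floats(0.0, 0.95))
    def test_partition_conserves_mass(self, ing, ae, sda):
        cfg = dataclasses.replace(ZOO, AE=ae, SDA=sda)
        voided, sda_r, anab = pp.digestion_partition(ing, cfg)
        for x, v, s, a in zip(ing, voided, sda_r, anab):
            assert v + s + a == pytest.approx(x, abs=1e-12)

    def test_effective_assimilation_penalizes_poor_prey(self):
        assert effective_assimilation(PREY, ZOO) == pytest.approx(ZOO.AE)
        poor = pp.build_default_prey(N_target=40.0, NC_quality=0.5)
        assert effective_assimilation(poor, ZOO) < ZOO.AE


class TestSDARecycle:
    def test_zooplankton_releases_everything(self):
        rec, ext = pp.sda_recycle((1.0, 0.2, 0.01), 0.0, 0.0, 0.0, ZOO)
        assert rec == (0.0, 0.0, 0.0)
        assert ext == (1.0, 0.2, 0.01)

    def test_sufficient_demand_means_no_external_release(self):
        rec, ext = pp.sda_recycle((1.0, 0.2, 0.01), 5.0, 1.0, 0.1, CM)
        assert ext == (0.0, 0.0, 0.0)
        assert rec == (1.0, 0.2, 0.01)

    def test_no_release_no_flows(self):
        rec, ext = pp.sda_recycle((0.0, 0.0, 0.0), 5.0, 1.0, 0.1, CM)
        assert rec == ext == (0.0, 0.0, 0.0)


class TestAcquiredPhototrophy:
    def test_constitutive_types_are_noop(self):
        assert pp.acquired_phototrophy_update(state_at(CM), 1.0, CM) == (0, 0)
        assert pp.acquired_phototrophy_update(state_at(ZOO), 1.0, ZOO) == (0, 0)

    def test_capacity_decays_without_ingestion(self):
        d_acq, d_chl = pp.acquired_phototrophy_update(
            state_at(GNCM, acq=0.8), 0.0, GNCM
        )
        assert d_acq == pytest.approx(-GNCM.acquired_decay_rate * 0.8)
        assert d_chl < 0.0

    def test_specialist_halflife_at_least_5x_generalist(self):
        assert GNCM.acquired_decay_rate >= 5.0 * PSNCM.acquired_decay_rate

    def test_gain_saturates_toward_full_capacity(self):
        s_lo = state_at(GNCM, acq=0.1)
        s_hi = state_at(GNCM, acq=0.95)
        g_lo = (pp.acquired_phototrophy_update(s_lo, 1.0, GNCM)[0]
                + GNCM.acquired_decay_rate * 0.1)
        g_hi = (pp.acquired_phototrophy_update(s_hi, 1.0, GNCM)[0]
                + GNCM.acquired_decay_rate * 0.95)
        assert 0.0 < g_hi < g_lo


class TestMaintenanceAndQuota:
    def test_zero_biomass_zero_losses(self):
        zero = pp.ProtistState(C=0.0, N=0.0, P=0.0)
        assert pp.maintenance_losses(zero, 0.0, CM) == (0, 0, 0, 0)

    def test_dark_cell_is_net_CO2_source(self):
        fl, _, d_pools, _ = pp.protist_derivatives(
            state_at(CM), POOLS, PREY, CM, PFD=0.0
        )
        assert fl.gross_photosynthesis_C == 0.0
        assert d_pools.DIC_biological_delta > 0.0

    def test_balanced_replete_growth_needs_no_regeneration(self):
        fl, _, _, _ = pp.protist_derivatives(
            state_at(PHYTO, q=0.5), POOLS, PREY, PHYTO, PFD=500.0
        )
        assert fl.regeneration_NH4 == 0.0
        assert fl.regeneration_PO4 == 0.0

    @pytest.mark.parametrize("q,edge", [(1.0, "max"), (0.0, "min")])
    def test_derivatives_respect_quota_bounds(self, q, edge):
        for cfg in (PHYTO, ZOO, CM):
            s = state_at(cfg, q=q)
            _, ds, _, _ = pp.protist_derivatives(s, POOLS, PREY, cfg, 500.0)
            dqn = (ds.N * s.C - s.N * ds.C) / s.C**2
            dqp = (ds.P * s.C - s.P * ds.C) / s.C**2
            if edge == "max":
                assert dqn <= 1e-12 and dqp <= 1e-12
            else:
                assert dqn >= -1e-12 and dqp >= -1e-12

    def test_quota_balancing_inactive_mid_range(self):
        of, rn, rp = quota_balancing(state_at(CM, q=0.5), 1.0, 0.2, 0.01, CM)
        assert of == rn == rp == 0.0


class TestDerivativeAssembly:
    def test_autotroph_draws_down_DIC_in_light(self):
        fl, _, d_pools, _ = pp.protist_derivatives(
            state_at(PHYTO, q=0.5), POOLS, PREY, PHYTO, PFD=500.0
        )
        assert d_pools.DIC_biological_delta < 0.0

    @pytest.mark.parametrize("pfd", [0.0, 500.0])
    def test_zooplankton_always_respires_DIC(self, pfd):
        fl, _, d_pools, _ = pp.protist_derivatives(
            state_at(ZOO, q=0.5), POOLS, PREY, ZOO, PFD=pfd
        )
        assert d_pools.DIC_biological_delta > 0.0
        assert fl.SDA_net_external_C == pytest.approx(fl.SDA_release_C)

    def test_switching_off_ingestion_equals_prey_absence(self):
        no_prey = pp.PreyField(prey_C=0.0, prey_N=0.0, prey_P=0.0,
                               prey_Chl=0.0)
        cfg_off = pp.make_config("CM", overrides={"can_ingest": False})
        s = state_at(cfg_off, q=0.4)
        fl_off, _, _, _ = pp.protist_derivatives(s, POOLS, PREY, cfg_off, 500.0)
        fl_none, _, _, _ = pp.protist_derivatives(s, POOLS, no_prey, cfg_off,
                                                  500.0)
        assert fl_off == fl_none

    def test_more_prey_never_raises_external_CO2_demand(self):
        """Internal SDA recycling substitutes for external CO2 uptake."""
        s = state_at(CM, q=0.5)
        rich = pp.build_default_prey(N_target=40.0)
        fl_poor, _, _, _ = pp.protist_derivatives(s, POOLS, PREY, CM, 500.0)
        fl_rich, _, _, _ = pp.protist_derivatives(s, POOLS, rich, CM, 500.0)
        assert fl_rich.ingestion_C > fl_poor.ingestion_C
        assert fl_rich.CO2_external_uptake <= fl_poor.CO2_external_uptake

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        ft=st.sampled_from(("phytoplankton", "zooplankton", "GNCM",
                            "pSNCM", "CM")),
        q_n=st.floats(0.0, 1.0), q_p=st.floats(0.0, 1.0),
        C=st.floats(0.01, 400.0),
        chl_frac=st.floats(0.0, 1.0), acq=st.floats(0.0, 1.0),
        nh4=st.floats(0.0, 10.0), no3=st.floats(0.0, 10.0),
        po4=st.floats(0.0, 1.25), doc=st.floats(0.0, 50.0),
        prey_c=st.floats(0.0, 265.0),
        pfd=st.sampled_from((0.0, 50.0, 500.0)),
    )
    def test_element_closure_for_random_states(self, ft, q_n, q_p, C,
                                               chl_frac, acq, nh4, no3, po4,
                                               doc, prey_c, pfd):
        """d/dt of every element summed over all pools is zero."""
        cfg = pp.make_config(ft)
        qn = cfg.NC_min + q_n * (cfg.NC_max - cfg.NC_min)
        qp = cfg.PC_min + q_p * (cfg.PC_max - cfg.PC_min)
        state = pp.ProtistState(C=C, N=qn * C, P=qp * C,
                                Chl=chl_frac * cfg.ChlC_max * C,
                                acquired_capacity=acq)
        pools = pp.DissolvedPools(NH4=nh4, NO3=no3, PO4=po4, DOC=doc)
        prey = pp.PreyField(prey_C=prey_c, prey_N=prey_c * 16.0 / 106.0,
                            prey_P=prey_c / 106.0, prey_Chl=0.1 * prey_c)
        fl, ds, dp, dprey = pp.protist_derivatives(state, pools, prey, cfg, pfd)
        sums = {
            "C": ds.C + dprey.prey_C + dp.DOC + dp.VOC
            + dp.DIC_biological_delta,
            "N": ds.N + dprey.prey_N + dp.NH4 + dp.NO3 + dp.DON + dp.VON,
            "P": ds.P + dprey.prey_P + dp.PO4 + dp.DOP + dp.VOP,
        }
        scales = {
            "C": abs(fl.gross_photosynthesis_C) + abs(fl.ingestion_C)
            + abs(fl.basal_respiration_C) + 1.0,
            "N": abs(fl.ingestion_N) + abs(fl.NH4_uptake)
            + abs(fl.NO3_uptake) + 1.0,
            "P": abs(fl.ingestion_P) + abs(fl.PO4_uptake) + 1.0,
        }
        for el in "CNP":
            assert abs(sums[el]) <= 1e-10 * scales[el], el
        # the carbon flux ledger balances exactly
        ledger = (fl.ingestion_C + fl.gross_photosynthesis_C - fl.void_C
                  - fl.SDA_release_C - fl.basal_respiration_C - fl.DOC_leak
                  + fl.DOC_reabsorption)
        assert ledger == pytest.approx(fl.net_growth_C,
                                       abs=1e-10 * scales["C"])
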