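"""Unit and property tests of the monthly site carbon model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prairiecarbon as pc
from prairiecarbon.carbon import _beta_scalar

from conftest import make_single_pool_state

CORN = pc.DEFAULT_CROPS["corn"]


class TestTemperatureScalar:
    def test_optimum_gives_one(self):
        assert pc.temperature_scalar(CORN.t_opt, CORN) == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [8.0, 40.0, -20.0, 60.0])
    def test_zero_at_and_beyond_limits(self, t):
        assert pc.temperature_scalar(t, CORN) == 0.0

    def test_matches_direct_formula_evaluation(self):
        # brute-force evaluation of the documented beta form at t = 16.5
        t, tmin, topt, tmax = 16.5, 8.0, 25.0, 40.0
        q = (topt - tmin) / (tmax - topt)
        expected = ((tmax - t) / (tmax - topt)) * ((t - tmin) / (topt - tmin)) ** q
        assert pc.temperature_scalar(t, CORN) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=-10, max_value=50))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_unit_interval(self, t):
        assert 0.0 <= pc.temperature_scalar(t, CORN) <= 1.0

    def test_unimodal_around_optimum(self):
        ts = np.linspace(CORN.t_min, CORN.t_max, 201)
        vals = [pc.temperature_scalar(t, CORN) for t in ts]
        peak = int(np.argmax(vals))
        assert np.all(np.diff(vals[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(vals[peak:]) <= 1e-12)


class TestMoistureScalar:
    @pytest.mark.parametrize(
        "precip,demand,expected", [(65, 65, 1.0), (0, 65, 0.0), (39, 65, 0.6)]
    )
    def test_ratio_capped(self, precip, demand, expected):
        assert pc.moisture_scalar(precip, demand) == pytest.approx(expected)

    def test_rejects_nonpositive_demand(self):
        with pytest.raises(ValueError):
            pc.moisture_scalar(10, 0)


class TestCO2AndEnhancement:
    def test_reference_concentration_is_neutral(self):
        assert pc.co2_multiplier(CORN.co2_ref, CORN) == pytest.approx(1.0)

    def test_closed_form_at_550ppm(self):
        crop = pc.CropParameters("x", prdx=100, co2_beta=0.2, co2_ref=370)
        assert pc.co2_multiplier(550, crop) == pytest.approx(
            1 + 0.2 * np.log(550 / 370), rel=1e-12
        )

    def test_zero_beta_is_flat(self):
        crop = pc.CropParameters("x", prdx=100, co2_beta=0.0)
        for co2 in (200, 370, 900):
            assert pc.co2_multiplier(co2, crop) == 1.0

    def test_enhancement_compound_growth(self):
        assert pc.enhancement_multiplier(2041, 2001, 0.01) == pytest.approx(
            1.01**40, rel=1e-12
        )
        assert pc.enhancement_multiplier(2001, 2001, 0.01) == 1.0
        assert pc.enhancement_multiplier(2030, 2001, 0.0) == 1.0

    def test_enhancement_rejects_past_year(self):
        with pytest.raises(ValueError):
            pc.enhancement_multiplier(2000, 2001, 0.01)


class TestProduction:
    def test_product_of_factors(self):
        crop = pc.CropParameters(
            "x", prdx=150, t_min=0, t_opt=20, t_max=40,
            co2_beta=0.0, enhancement_rate=0.0,
        )
        npp = pc.production_month(crop, t=20.0, moisture=0.75, co2=370,
                                  year=2001, base_year=2001)
        assert npp == pytest.approx(150 * 1.0 * 0.75)

    def test_zero_moisture_blocks_production(self):
        npp = pc.production_month(CORN, t=25.0, moisture=0.0, co2=370,
                                  year=2001, base_year=2001)
        assert npp == 0.0

    def test_doubling_prdx_doubles_npp(self):
        lo = pc.production_month(CORN, 22.0, 0.6, 420, 2010, 2001)
        hi = pc.production_month(CORN.with_prdx(2 * CORN.prdx), 22.0, 0.6, 420,
                                 2010, 2001)
        assert hi == pytest.approx(2 * lo, rel=1e-12)


class TestPartitionHarvest:
    def test_one_to_one_index_with_half_removal(self):
        crop = pc.CropParameters("corn", prdx=100, harvest_index=1.0,
                                 root_fraction=0.0)
        mgmt = pc.Management(stover_removal_rate=0.5)
        grain, stover, exported, residue, root = pc.partition_harvest(
            0.9, crop, mgmt
        )
        assert grain == pytest.approx(0.45)
        assert stover == pytest.approx(0.45)
        assert exported == pytest.approx(0.225)
        assert residue == pytest.approx(0.225)
        assert root == 0.0

    @pytest.mark.parametrize("removal,check", [(0.0, "residue"), (1.0, "exported")])
    def test_removal_extremes(self, removal, check):
        mgmt = pc.Management(stover_removal_rate=removal)
        grain, stover, exported, residue, root = pc.partition_harvest(
            1.0, CORN, mgmt
        )
        if removal == 0.0:
            assert exported == 0.0 and residue == pytest.approx(stover)
        else:
            assert exported == pytest.approx(stover) and residue == pytest.approx(0.0)

    @given(
        npp=st.floats(min_value=0, max_value=5),
        removal=st.floats(min_value=0, max_value=1),
        root_f=st.floats(min_value=0, max_value=0.9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_components_sum_to_npp(self, npp, removal, root_f):
        crop = pc.CropParameters("x", prdx=100, root_fraction=root_f)
        mgmt = pc.Management(stover_removal_rate=removal)
        grain, stover, exported, residue, root = pc.partition_harvest(
            npp, crop, mgmt
        )
        assert grain + exported + residue + root == pytest.approx(npp, abs=1e-12)
        assert exported <= stover + 1e-12

    def test_unharvested_cover_returns_everything(self):
        grass = pc.DEFAULT_CROPS["grass_shrub"]
        mgmt = pc.Management(stover_removal_rate=0.7)
        grain, stover, exported, residue, root = pc.partition_harvest(
            1.0, grass, mgmt
        )
        assert grain == 0.0 and exported == 0.0
        assert residue + root == pytest.approx(1.0)


class TestDecomposition:
    def test_zero_rates_identity(self):
        state = pc.initialize_state(6.0)
        decomp = pc.DecompositionParams(
            k_month={k: 0.0 for k in ("structural", "metabolic", "active",
                                      "slow", "passive")}
        )
        new, resp = pc.decompose_month(state, 0.8, 0.9, decomp)
        assert resp == 0.0
        np.testing.assert_array_equal(new.som, state.som)

    def test_single_pool_matches_closed_form(self, single_pool_params):
        c0, k, s = 2.0, 0.01, 0.8 * 0.75
        state = make_single_pool_state(c0)
        for _ in range(120):
            state, _ = pc.decompose_month(state, 0.8, 0.75, single_pool_params)
        assert state.som[0, 0] == pytest.approx(c0 * (1 - k * s) ** 120, rel=1e-12)

    def test_full_respiration_means_no_transfers(self):
        decomp = pc.DecompositionParams(
            respiration_fraction={k: 1.0 for k in ("structural", "metabolic",
                                                   "active", "slow", "passive")}
        )
        state = pc.initialize_state(6.0)
        total0 = state.soc_total
        new, resp = pc.decompose_month(state, 0.5, 0.5, decomp)
        assert total0 - new.soc_total == pytest.approx(resp, abs=1e-14)

    def test_conservation_under_default_routing(self):
        state = pc.initialize_state(6.31)
        state.litter_structural = 0.2
        state.litter_metabolic = 0.3
        before = state.total_carbon
        new, resp = pc.decompose_month(state, 0.7, 0.8, pc.DecompositionParams())
        assert before - new.total_carbon == pytest.approx(resp, abs=1e-12)

    def test_unstable_step_raises(self):
        decomp = pc.DecompositionParams(
            k_month={"structural": 0.0, "metabolic": 2.5, "active": 0.0,
                     "slow": 0.0, "passive": 0.0}
        )
        state = pc.initialize_state(6.0)
        with pytest.raises(ValueError, match="unstable"):
            pc.decompose_month(state, 1.0, 0.9, decomp)


class TestInitializeState:
    def test_total_preserved_exactly(self):
        state = pc.initialize_state(6.31)
        assert state.soc_total == pytest.approx(6.31, abs=1e-12)

    def test_single_layer_holds_everything(self):
        state = pc.initialize_state(5.0, n_layers=1)
        assert state.som.shape == (1, 3)
        assert state.som.sum() == pytest.approx(5.0)

    def test_all_active_partition(self):
        state = pc.initialize_state(4.0, pool_fractions=(1.0, 0.0, 0.0))
        assert state.som[:, 1:].sum() == 0.0
        assert state.som[:, 0].sum() == pytest.approx(4.0)

    def test_rejects_nonpositive_soc(self):
        with pytest.raises(ValueError):
            pc.initialize_state(0.0)


class TestRunSite:
    def test_flat_soc_with_zero_forcing(self, quiet_climate):
        decomp = pc.DecompositionParams(
            k_month={k: 0.0 for k in ("structural", "metabolic", "active",
                                      "slow", "passive")}
        )
        crops = {"corn": CORN.with_prdx(1e-9)}
        traj = pc.run_site(6.0, quiet_climate, ["corn"] * 10,
                           pc.Management(), crops, decomp=decomp)
        np.testing.assert_allclose(traj.soc, 6.0, rtol=1e-6)

    def test_export_ratio_tracks_removal(self, baseline_climate):
        traj = pc.run_site(
            6.31, baseline_climate, ["corn"] * baseline_climate.n_years,
            pc.Management(stover_removal_rate=0.5), pc.DEFAULT_CROPS,
        )
        ratio = traj.stover_exported / traj.stover_produced
        np.testing.assert_allclose(ratio, 0.5, rtol=1e-9)

    def test_deterministic_given_inputs(self, baseline_climate):
        args = (6.31, baseline_climate, ["corn"] * baseline_climate.n_years,
                pc.Management(stover_removal_rate=0.3), pc.DEFAULT_CROPS)
        a, b = pc.run_site(*args), pc.run_site(*args)
        np.testing.assert_array_equal(a.soc, b.soc)
        np.testing.assert_array_equal(a.grain, b.grain)

    def test_scaling_prdx_scales_npp(self, quiet_climate):
        crops = {"corn": CORN}
        double = {"corn": CORN.with_prdx(2 * CORN.prdx)}
        t1 = pc.run_site(6.0, quiet_climate, ["corn"] * 10, pc.Management(), crops)
        t2 = pc.run_site(6.0, quiet_climate, ["corn"] * 10, pc.Management(), double)
        np.testing.assert_allclose(t2.npp, 2 * t1.npp, rtol=1e-12)

    def test_calendar_mismatch_raises(self, quiet_climate):
        with pytest.raises(ValueError):
            pc.run_site(6.0, quiet_climate, ["corn"] * 3, pc.Management(),
                        pc.DEFAULT_CROPS)


def test_beta_scalar_continuity_at_edges():
    assert _beta_scalar(8.0 + 1e-9, 8, 25, 40) < 1e-6
    assert _beta_scalar(40.0 - 1e-9, 8, 25, 40) < 1e-6
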