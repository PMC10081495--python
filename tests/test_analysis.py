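"""Canopy aggregation, grid bookkeeping, derived analyses, cost arithmetic."""

import numpy as np
import pandas as pd
import pytest

from canopylight import analysis
from canopylight.exceptions import DomainError, MissingDataError
from canopylight.leaf import BilateralIrradiance, bilateral_pn
from canopylight.transport import IrradianceMap

from conftest import TRUTH


def make_map(e_ad, e_ab, area, rank=None, z=None):
    n = len(e_ad)
    df = pd.DataFrame(
        {
            "tri": np.arange(n),
            "plant": 0,
            "rank": rank if rank is not None else np.full(n, 3),
            "area": area,
            "z": z if z is not None else np.full(n, 0.15),
            "e_ad": e_ad,
            "e_ab": e_ab,
            "se_ad": 0.0,
            "se_ab": 0.0,
        }
    )
    return IrradianceMap(triangles=df, budget={})


PARAMS = {3: TRUTH}


class TestCanopyPn:
    def test_single_triangle_hand_value(self):
        irr = make_map([400.0], [100.0], [0.01])
        pn = bilateral_pn(BilateralIrradiance(400.0, 100.0), TRUTH)
        cpn, cpg = analysis.canopy_pn(irr, PARAMS)
        assert cpn == pytest.approx(pn * 0.01)
        assert cpg == pytest.approx((pn - TRUTH.rd) * 0.01)

    def test_dark_map_respires(self):
        irr = make_map([0.0, 0.0], [0.0, 0.0], [0.01, 0.02])
        cpn, cpg = analysis.canopy_pn(irr, PARAMS)
        assert cpn == pytest.approx(TRUTH.rd * 0.03)
        assert cpg == pytest.approx(0.0, abs=1e-15)

    def test_two_triangle_hand_sum(self):
        irr = make_map([300.0, 50.0], [0.0, 150.0], [0.004, 0.011])
        pn1 = bilateral_pn(BilateralIrradiance(300.0, 0.0), TRUTH)
        pn2 = bilateral_pn(BilateralIrradiance(50.0, 150.0), TRUTH)
        cpn, _ = analysis.canopy_pn(irr, PARAMS)
        assert cpn == pytest.approx(pn1 * 0.004 + pn2 * 0.011, rel=1e-12)

    def test_missing_rank_named_in_error(self):
        irr = make_map([100.0], [0.0], [0.01], rank=[5])
        with pytest.raises(MissingDataError, match="5"):
            analysis.canopy_pn(irr, PARAMS)

    def test_respiration_accounting_identity(self):
        rng = np.random.default_rng(0)
        irr = make_map(
            rng.uniform(0, 500, 20), rng.uniform(0, 200, 20), rng.uniform(1e-4, 1e-2, 20)
        )
        cpn, cpg = analysis.canopy_pn(irr, PARAMS)
        a = irr.triangles["area"].sum()
        assert cpg - cpn == pytest.approx(-TRUTH.rd * a, rel=1e-12)

    def test_invariance_to_order_and_splitting(self):
        e_ad = np.array([120.0, 40.0])
        e_ab = np.array([10.0, 80.0])
        area = np.array([0.004, 0.006])
        base, _ = analysis.canopy_pn(make_map(e_ad, e_ab, area), PARAMS)
        shuffled, _ = analysis.canopy_pn(
            make_map(e_ad[::-1], e_ab[::-1], area[::-1]), PARAMS
        )
        split, _ = analysis.canopy_pn(
            make_map(
                [120.0, 120.0, 40.0], [10.0, 10.0, 80.0], [0.002, 0.002, 0.006]
            ),
            PARAMS,
        )
        assert shuffled == pytest.approx(base, rel=1e-12)
        assert split == pytest.approx(base, rel=1e-12)


class TestLightMetrics:
    def test_two_equal_triangles(self):
        irr = make_map([100.0, 200.0], [0.0, 0.0], [0.01, 0.01])
        phi, sd, mean = analysis.canopy_light_metrics(irr)
        assert mean == pytest.approx(150.0)
        assert sd == pytest.approx(50.0)
        assert phi == pytest.approx(100.0 * 0.01 + 200.0 * 0.01)

    def test_uniform_map_has_zero_sd(self):
        irr = make_map([80.0, 80.0], [20.0, 20.0], [0.01, 0.03])
        _, sd, mean = analysis.canopy_light_metrics(irr)
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_unequal_area_hand_arithmetic(self):
        # areas 1, 2, 3 (in 1e-3 m2) with totals 60, 120, 300
        irr = make_map([60.0, 120.0, 300.0], [0.0, 0.0, 0.0], [0.001, 0.002, 0.003])
        phi, sd, mean = analysis.canopy_light_metrics(irr)
        assert phi == pytest.approx(0.06 + 0.24 + 0.9)
        assert mean == pytest.approx(1.2 / 0.006)
        var = (1 * (60 - 200) ** 2 + 2 * (120 - 200) ** 2 + 3 * (300 - 200) ** 2) / 6
        assert sd == pytest.approx(np.sqrt(var))


class TestGrid:
    def test_default_grid_has_220_conditions(self):
        assert len(analysis.condition_grid()) == 220

    def test_singleton_grid(self):
        assert len(analysis.condition_grid([1.0], [122.0], [50.0])) == 1

    def test_empty_levels_rejected(self):
        with pytest.raises(DomainError):
            analysis.condition_grid([], [122.0], [50.0])

    def test_run_grid_single_condition_and_determinism(self):
        kw = dict(
            lai_levels=[0.5], phi_levels=[122.0], pdw_levels=[100.0],
            photons=3000, seed=5,
        )
        a = analysis.run_grid(**kw)
        b = analysis.run_grid(**kw)
        assert len(a) == 1
        assert a.loc[0, "error"] == ""
        assert a.equals(b)
        assert a.loc[0, "phi_leaves"] > 0


class TestRatioToDownwardOnly:
    def base_group(self, cpn, cpg):
        return pd.DataFrame(
            {
                "lai": 1.5,
                "phi_lamps": 122.0,
                "p_dw": np.linspace(0, 100, len(cpn)),
                "cpn": cpn,
                "cpg": cpg,
            }
        )

    def test_flat_group_ties_resolve_to_downward(self):
        df = self.base_group([2.0] * 11, [5.0] * 11)
        out = analysis.ratio_to_downward_only(df)
        assert out.loc[0, "best_p_dw"] == 100.0
        assert out.loc[0, "cpg_ratio"] == pytest.approx(1.0)

    def test_interior_maximum_hand_ratio(self):
        cpn = [1, 2, 5, 4, 3, 2, 1, 1, 1, 1, 1]
        cpg = [3, 4, 7, 6, 5, 4, 3, 3, 3, 3, 2.5]
        out = analysis.ratio_to_downward_only(self.base_group(cpn, cpg))
        assert out.loc[0, "best_p_dw"] == 20.0
        assert out.loc[0, "cpg_ratio"] == pytest.approx(7 / 2.5)

    def test_zero_baseline_flagged_not_divided(self):
        df = self.base_group([1.0] * 11, [0.0] * 11)
        out = analysis.ratio_to_downward_only(df)
        assert not out.loc[0, "ratio_defined"]
        assert np.isnan(out.loc[0, "cpg_ratio"])

    def test_missing_baseline_raises(self):
        df = self.base_group([1.0] * 11, [2.0] * 11)
        df = df[df["p_dw"] < 100.0]
        with pytest.raises(MissingDataError):
            analysis.ratio_to_downward_only(df)


class TestVerticalProfile:
    def test_single_layer_equals_mean(self):
        irr = make_map([60.0, 120.0], [0.0, 0.0], [0.001, 0.003], z=[0.12, 0.18])
        prof = analysis.vertical_profile(irr, 1)
        _, _, mean = analysis.canopy_light_metrics(irr)
        assert prof.loc[0, "mean_ppfd"] == pytest.approx(mean)

    def test_all_triangles_at_one_height(self):
        irr = make_map([60.0, 120.0], [0.0, 0.0], [0.001, 0.003], z=[0.15, 0.15])
        prof = analysis.vertical_profile(irr, 4)
        assert prof["area"].gt(0).sum() == 1

    def test_two_layer_hand_means(self):
        irr = make_map(
            [10.0, 30.0, 100.0, 200.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.001, 0.001, 0.001, 0.003],
            z=[0.11, 0.12, 0.19, 0.20],
        )
        prof = analysis.vertical_profile(irr, 2)
        assert prof.loc[0, "mean_ppfd"] == pytest.approx(20.0)
        assert prof.loc[1, "mean_ppfd"] == pytest.approx((100 + 3 * 200) / 4)


class TestNormalizeMetrics:
    def test_hand_group(self):
        df = pd.DataFrame(
            {"lai": 1.0, "phi_lamps": 122.0, "p_dw": [0.0, 100.0],
             "phi_leaves": [2.0, 4.0], "sd_e": [5.0, 5.0]}
        )
        out = analysis.normalize_metrics(df)
        np.testing.assert_allclose(out["phi_leaves_norm"], [0.5, 1.0])
        np.testing.assert_allclose(out["sd_e_norm"], [1.0, 1.0])

    def test_zero_group_flagged(self):
        df = pd.DataFrame(
            {"lai": 1.0, "phi_lamps": 0.0, "p_dw": [0.0, 100.0],
             "phi_leaves": [0.0, 0.0], "sd_e": [0.0, 0.0]}
        )
        out = analysis.normalize_metrics(df)
        assert not out["phi_leaves_norm_defined"].any()


class TestLampCostShare:
    def test_upper_bound(self):
        assert analysis.lamp_cost_share(0.30, 0.30) == pytest.approx(9.0)

    def test_lower_bound(self):
        assert analysis.lamp_cost_share(0.25, 0.30) == pytest.approx(7.5)

    def test_zero_factor(self):
        assert analysis.lamp_cost_share(0.0, 0.9) == 0.0

    @pytest.mark.parametrize("args", [(-0.1, 0.3), (0.3, 1.2)])
    def test_out_of_range(self, args):
        with pytest.raises(DomainError):
            analysis.lamp_cost_share(*args)


def test_default_leaf_params_cover_seven_ranks():
    params = analysis.default_leaf_params()
    assert set(params) == set(range(7))
    assert params[3].p_max == pytest.approx(53.7)
    assert params[2].p_max == pytest.approx(50.2)
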