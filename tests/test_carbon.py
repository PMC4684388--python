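"""Carbon-stock computation and the four-method comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from allocarbon.carbon import (
    FactorKind,
    bootstrap_rmse_rc,
    conversion_factors_for_method,
    mean_concentrations,
    method_error_matrix,
    observed_carbon,
    predict_carbon_by_method,
    rmse_r,
    rmse_rc,
    rmse_rc_indirect,
    rmse_rc_table,
)
from allocarbon.data import carbon_matrix
from allocarbon.nsur import CompatibleSystemModel
from allocarbon.simulate import SimulationConfig, simulate_dataset


class TestObservedCarbon:
    def test_component_wise_product(self):
        cv = observed_carbon([100, 20, 10, 30], [0.47, 0.48, 0.49, 0.48])
        np.testing.assert_allclose(cv.as_array(), [47.0, 9.6, 4.9, 14.4])
        assert cv.total == pytest.approx(75.9)

    def test_zero_biomass_gives_zero_carbon(self):
        assert observed_carbon([0, 0, 0, 0], [0.47, 0.48, 0.49, 0.48]).total == 0.0

    def test_half_concentration_halves_biomass(self):
        cv = observed_carbon([10, 10, 10, 10], [0.5] * 4)
        np.testing.assert_allclose(cv.as_array(), 5.0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_concentration_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            observed_carbon([1, 1, 1, 1], [0.47, bad, 0.49, 0.48])


class TestMeanConcentrations:
    def _one_tree(self):
        return pd.DataFrame(
            {
                "tree_id": [1], "plot_id": [1], "D_cm": [20.0], "H_m": [15.0],
                "biomass_stem_kg": [100.0], "biomass_branch_kg": [20.0],
                "biomass_foliage_kg": [10.0], "biomass_root_kg": [30.0],
                "cc_stem": [0.47], "cc_branch": [0.48],
                "cc_foliage": [0.49], "cc_root": [0.48],
            }
        )

    def test_single_tree(self):
        df = self._one_tree()
        comp = mean_concentrations(df, FactorKind.COMPONENT_MEANS)
        np.testing.assert_allclose(comp.as_array(), [0.47, 0.48, 0.49, 0.48])
        tree = mean_concentrations(df, FactorKind.TREE_MEAN)
        assert tree.stem == pytest.approx(75.9 / 160.0)

    def test_uniform_half_everywhere(self):
        df = self._one_tree()
        for c in ("cc_stem", "cc_branch", "cc_foliage", "cc_root"):
            df[c] = 0.5
        for kind in (FactorKind.TREE_MEAN, FactorKind.COMPONENT_MEANS):
            np.testing.assert_allclose(mean_concentrations(df, kind).as_array(), 0.5)

    def test_study_emulation_recovers_configured_means(self, default_dataset):
        comp = mean_concentrations(default_dataset, FactorKind.COMPONENT_MEANS)
        np.testing.assert_allclose(comp.as_array(), [0.47, 0.48, 0.49, 0.48], atol=0.005)
        tree = mean_concentrations(default_dataset, FactorKind.TREE_MEAN)
        assert tree.stem == pytest.approx(0.475, abs=0.01)

    def test_biomass_weighted_switch_differs_but_agrees_closely(self, default_dataset):
        a = mean_concentrations(default_dataset, FactorKind.TREE_MEAN)
        b = mean_concentrations(default_dataset, FactorKind.TREE_MEAN, biomass_weighted=True)
        assert a.stem != b.stem
        assert a.stem == pytest.approx(b.stem, abs=0.01)

    def test_empty_table_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            mean_concentrations(default_dataset.iloc[:0])


class TestRmseR:
    def test_perfect_predictions_give_zero(self):
        y = np.arange(1.0, 12.0)
        assert rmse_r(y, y, p_params=8) == 0.0

    def test_hand_worked_example(self):
        assert rmse_r([1, 2, 3], [1, 2, 4], p_params=1) == pytest.approx(
            np.sqrt(0.5) / (7 / 3) * 100
        )

    def test_scale_invariance(self, rng):
        y = rng.uniform(1, 50, 30)
        yhat = y * rng.uniform(0.9, 1.1, 30)
        assert rmse_r(y, yhat) == pytest.approx(rmse_r(10 * y, 10 * yhat), rel=1e-12)

    def test_zero_mean_prediction_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rmse_r(np.ones(10), np.zeros(10), p_params=2)


class TestIndirectIdentity:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        W=hnp.arrays(float, 15, elements=st.floats(1.0, 200.0)),
        What=hnp.arrays(float, 15, elements=st.floats(1.0, 200.0)),
        cc=hnp.arrays(float, 15, elements=st.floats(0.40, 0.55)),
        factor=st.floats(0.40, 0.55),
    )
    def test_carbon_form_equals_biomass_form(self, W, What, cc, factor):
        """The indirect-method relative RMSE is the same whether computed on
        the carbon scale or rescaled onto the biomass scale — the
        conversion factor cancels."""
        direct = rmse_r(W * cc, What * factor)
        expanded = rmse_rc_indirect(W, What, cc, factor)
        assert direct == pytest.approx(expanded, rel=1e-10)

    def test_unit_invariance(self, rng):
        W = rng.uniform(5, 300, 20)
        What = W * rng.uniform(0.85, 1.15, 20)
        cc = rng.uniform(0.45, 0.5, 20)
        a = rmse_rc_indirect(W, What, cc, 0.48)
        b = rmse_rc_indirect(W * 10, What * 10, cc, 0.48)
        assert a == pytest.approx(b, rel=1e-12)


@pytest.fixture(scope="module")
def error_matrix(default_dataset, bm1_jackknife, cm3_jackknife):
    return method_error_matrix(default_dataset, bm1_jackknife, cm3_jackknife)


class TestMethodPredictions:
    def test_factor_half_halves_biomass_predictions(self, default_dataset, bm1_jackknife):
        factors = conversion_factors_for_method(2, default_dataset)
        pred = predict_carbon_by_method(2, bm1_jackknife, None, factors)
        np.testing.assert_allclose(pred, bm1_jackknife.loo_pred * 0.5)

    def test_equal_factors_make_methods_coincide(self, default_dataset, bm1_jackknife):
        """Whole-tree and component factors that happen to be identical
        produce identical indirect predictions."""
        f = conversion_factors_for_method(2, default_dataset)
        p3 = predict_carbon_by_method(3, bm1_jackknife, None, f)
        p4 = predict_carbon_by_method(4, bm1_jackknife, None, f)
        np.testing.assert_allclose(p3, p4)

    def test_constant_half_concentrations_link_method2_to_biomass_errors(self):
        """When every true concentration is exactly 0.5, Method 2's carbon
        errors are the biomass-model errors halved."""
        cfg = SimulationConfig(
            n_trees=30, seed=77,
            concentration_means=(0.5, 0.5, 0.5, 0.5),
            concentration_sds=(0.0, 0.0, 0.0, 0.0),
        )
        df = simulate_dataset(cfg)
        bm = CompatibleSystemModel(df, "BM1").fit().jackknife()
        cm = CompatibleSystemModel(df, "CM3").fit().jackknife()
        mat = method_error_matrix(df, bm, cm)
        m2 = mat[(mat["method"] == 2) & (mat["component"] == "stem")]
        biomass_err = df["biomass_stem_kg"].to_numpy() - bm.loo_pred[:, 0]
        np.testing.assert_allclose(m2["error_kg"].to_numpy(), biomass_err / 2, rtol=1e-10)

    def test_matrix_structure(self, error_matrix, default_dataset):
        mat = error_matrix
        assert set(mat["method"]) == {1, 2, 3, 4}
        assert set(mat["component"]) == {"stem", "branch", "foliage", "root", "total"}
        # observed carbon is biomass x concentration; totals sum components
        stem_obs = mat[(mat["method"] == 1) & (mat["component"] == "stem")]
        np.testing.assert_allclose(
            stem_obs.sort_values("tree")["observed_kg"].to_numpy(),
            carbon_matrix(default_dataset)[:, 0],
        )
        for m in (1, 2, 3, 4):
            sl = mat[mat["method"] == m].pivot(index="tree", columns="component",
                                              values="predicted_kg")
            np.testing.assert_allclose(
                sl["total"], sl[["stem", "branch", "foliage", "root"]].sum(axis=1),
                rtol=1e-10,
            )

    def test_mismatched_tree_sets_rejected(self, default_dataset, bm1_jackknife, cm3_jackknife):
        other = simulate_dataset(SimulationConfig(n_trees=89, seed=5))
        with pytest.raises(ValueError):
            method_error_matrix(other, bm1_jackknife, cm3_jackknife)


class TestRmseRcTable:
    def test_values_match_slice_computation(self, error_matrix):
        table = rmse_rc_table(error_matrix)
        assert table.loc["method_2", "stem"] == pytest.approx(
            rmse_rc(error_matrix, 2, "stem")
        )
        assert np.all(table.to_numpy() > 0)

    def test_generic_half_factor_is_worst_for_stem(self, error_matrix):
        """True stem concentration is 0.47, so the 0.5 blanket factor
        carries a systematic bias the empirical factors avoid."""
        t = rmse_rc_table(error_matrix)
        assert t.loc["method_2", "stem"] > t.loc["method_3", "stem"]
        assert t.loc["method_2", "stem"] > t.loc["method_4", "stem"]

    def test_bootstrap_ci_brackets_point_and_is_reproducible(self, error_matrix):
        ci = bootstrap_rmse_rc(error_matrix, n_boot=200, seed=11)
        assert np.all(ci["ci_lower"] <= ci["rmse_rc"] + 1e-9)
        assert np.all(ci["rmse_rc"] <= ci["ci_upper"] + 1e-9)
        ci2 = bootstrap_rmse_rc(error_matrix, n_boot=200, seed=11)
        pd.testing.assert_frame_equal(ci, ci2)
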