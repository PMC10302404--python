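import numpy as np
import pandas as pd
import pytest

from wetconnect.wq import (
    CLASS_PCT_COLS,
    ConnectivityWQModel,
    SingularityError,
    SlopeEstimate,
    StandardizationError,
    TransformError,
    analytic_response_sd,
    drop_censored,
    select_grouping,
    simulate_wq,
    standardize,
    transform_response,
    vif_screen,
)


class TestTransforms:
    def test_natural_log_for_ordinary_constituents(self):
        assert transform_response([np.e], "DOC")[0] == pytest.approx(1.0)

    def test_ph_raised_to_the_fourth(self):
        assert transform_response([2.0], "pH")[0] == pytest.approx(16.0)

    def test_nonpositive_value_on_log_branch_errors_with_rows(self):
        with pytest.raises(TransformError, match=r"rows \[1\]"):
            transform_response([1.0, 0.0, 2.0], "DOC")

    def test_ph_exempt_from_positivity(self):
        assert transform_response([0.0], "pH")[0] == 0.0


class TestCensoredRemoval:
    def table(self, values, name="Al"):
        return pd.DataFrame({name: values, "keep": range(len(values))})

    def test_zeros_removed_and_counted(self):
        data = self.table([0.0] * 12 + [1.0] * 88)
        kept, n = drop_censored(data, "Al")
        assert len(kept) == 88 and n == 12

    def test_declared_detection_limit_also_removed(self):
        data = self.table([0.5, 0.5, 1.0, 2.0], name="TSS")
        kept, n = drop_censored(data, "TSS", {"TSS": 0.5})
        assert len(kept) == 2 and n == 2

    def test_other_constituents_pass_through(self):
        data = self.table([0.0, 1.0], name="DOC")
        kept, n = drop_censored(data, "DOC")
        assert len(kept) == 2 and n == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_kept_rows_equal_row_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.choice([0.0, 0.25, 1.0, 3.0], size=60)
        data = self.table(vals, name="NO3")
        kept, n = drop_censored(data, "NO3", {"NO3": 0.25})
        oracle = [i for i, v in enumerate(vals) if v not in (0.0, 0.25)]
        assert kept.index.tolist() == oracle
        assert n == 60 - len(oracle)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        out, ledger = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert ledger.iloc[0]["mean"] == 2.0

    def test_idempotent_up_to_tolerance(self):
        first, _ = standardize(pd.DataFrame({"x": [3.0, 7.0, 9.0, 1.0]}), ["x"])
        second, _ = standardize(first, ["x"])
        np.testing.assert_allclose(second["x"], first["x"], atol=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(StandardizationError):
            standardize(pd.DataFrame({"x": [2.0, 2.0, 2.0]}), ["x"])


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        x = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        vifs, flag = vif_screen(x)
        assert vifs["a"] == pytest.approx(1.0) and vifs["b"] == pytest.approx(1.0)
        assert not flag

    def test_duplicated_predictor_is_singular(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.raises(SingularityError):
            vif_screen(x)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        b = 0.7 * a + rng.normal(size=200)
        c = rng.normal(size=200)
        x = pd.DataFrame({"a": a, "b": b, "c": c})
        vifs, _ = vif_screen(x)
        for col in x.columns:
            others = x.drop(columns=col).to_numpy()
            design = np.column_stack([np.ones(len(x)), others])
            beta, *_ = np.linalg.lstsq(design, x[col].to_numpy(), rcond=None)
            resid = x[col].to_numpy() - design @ beta
            r2 = 1 - resid.var() / x[col].to_numpy().var()
            assert vifs[col] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestSimulator:
    def test_fixed_seed_reproduces_table(self):
        a, _ = simulate_wq(n_sites=100, n_regions=3, seed=9)
        b, _ = simulate_wq(n_sites=100, n_regions=3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_class_percentages_are_right_skewed_in_range(self):
        data, _ = simulate_wq(n_sites=2000, seed=1)
        for col in CLASS_PCT_COLS:
            vals = data[col]
            assert vals.between(0, 100).all()
            assert vals.mean() > vals.median()  # right skew

    def test_response_variance_matches_analytic_form(self):
        data, truth = simulate_wq(n_sites=4000, n_regions=12, seed=2)
        assert data["y"].std() == pytest.approx(truth["sd_y"], rel=0.1)
        assert truth["sd_y"] == analytic_response_sd(
            (0.4, 0.2, 0.1, -0.2), (0.3,), 0.3, 0.1, 0.7
        )

    def test_noiseless_limit_recovers_slopes_exactly(self):
        data, _ = simulate_wq(
            random_intercept_sd=0.0, random_slope_sd=0.0, resid_sd=0.0,
            n_sites=200, n_regions=3, seed=5,
        )
        model = ConnectivityWQModel.from_dataframe(
            data, "y", standardize_response=False
        )
        res = model.fit(backward_select=False, maximal_random=False)
        slopes = res.slopes().set_index("class")["mean_slope"]
        for cls, want in zip(["Riparian", "NRShw", "NRMid", "NRDeep"],
                             (0.4, 0.2, 0.1, -0.2)):
            assert slopes[cls] == pytest.approx(want, abs=1e-6)


class TestModel:
    def test_single_region_reduces_to_ols(self):
        import statsmodels.api as sm

        data, _ = simulate_wq(n_sites=300, n_regions=2, seed=6)
        data["region"] = 0
        model = ConnectivityWQModel.from_dataframe(data, "y")
        res = model.fit(backward_select=False, maximal_random=False)
        frame = ConnectivityWQModel.from_dataframe(data, "y").prepare()
        X = sm.add_constant(frame[CLASS_PCT_COLS + ["cov1"]])
        ols = sm.OLS(frame["y"], X).fit()
        for col in CLASS_PCT_COLS:
            assert res.params[col] == pytest.approx(ols.params[col], abs=1e-3)

    def test_two_region_recovery_within_two_se(self):
        data, truth = simulate_wq(n_sites=800, n_regions=2, random_slope_sd=0.0,
                                  seed=8)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit(
            backward_select=False, maximal_random=False
        )
        slopes = res.slopes().set_index("class")
        for col in CLASS_PCT_COLS:
            want = truth["slopes_std_response"][col]
            row = slopes.loc[col.removeprefix("pct_")]
            assert abs(row["mean_slope"] - want) <= 2 * row["se"]

    def test_zero_random_slope_variance_estimated_near_zero(self):
        data, _ = simulate_wq(random_slope_sd=0.0, n_sites=1000, n_regions=6,
                              seed=12)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit(
            backward_select=False
        )
        variances = res.random_effect_variances
        slope_vars = [v for k, v in variances.items() if k.startswith("pct_")]
        assert max(slope_vars) < 0.01

    def test_prepare_logs_pipeline_order(self):
        data, _ = simulate_wq(n_sites=100, n_regions=3, seed=0)
        model = ConnectivityWQModel.from_dataframe(data, "y")
        model.prepare()
        assert model.prep_report["order"] == [
            "drop_censored", "transform", "standardize", "vif",
        ]
        assert not model.prep_report["vif_flag"]

    def test_predictor_rescaling_leaves_standardized_slope_unchanged(self):
        data, _ = simulate_wq(n_sites=400, n_regions=4, seed=3)
        base = ConnectivityWQModel.from_dataframe(data, "y").fit(
            backward_select=False, maximal_random=False
        )
        scaled_data = data.assign(pct_NRShw=data["pct_NRShw"] * 17.0)
        scaled = ConnectivityWQModel.from_dataframe(scaled_data, "y").fit(
            backward_select=False, maximal_random=False
        )
        assert scaled.params["pct_NRShw"] == pytest.approx(
            base.params["pct_NRShw"], abs=1e-8
        )


class TestBackwardSelection:
    def test_null_covariate_removed_classes_retained(self):
        data, _ = simulate_wq(covariate_effects=(0.3, 0.0), n_sites=1000,
                              n_regions=6, seed=21)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit()
        assert "cov2" not in res.fixed_terms
        assert all(c in res.fixed_terms for c in CLASS_PCT_COLS)

    def test_true_zero_class_slope_still_present(self):
        data, _ = simulate_wq(slopes=(0.4, 0.2, 0.1, 0.0), n_sites=800,
                              n_regions=6, random_slope_sd=0.0, seed=22)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit()
        assert all(c in res.fixed_terms for c in CLASS_PCT_COLS)
        assert "NRDeep" in res.slopes()["class"].values

    def test_strong_terms_survive_selection(self):
        data, _ = simulate_wq(n_sites=1200, n_regions=8, seed=23)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit()
        assert "cov1" in res.fixed_terms  # true effect 0.3 is kept
        for step in res.selection_trace:
            assert step["term"] not in CLASS_PCT_COLS or step["phase"] == "random"


class TestSlopeInterpretation:
    def test_two_se_rule_arithmetic(self):
        assert not SlopeEstimate("NRMid", 0.1, 0.06, False).significant
        assert SlopeEstimate("NRMid", 0.1, 0.04, False).significant

    def test_summary_mentions_each_class(self):
        data, _ = simulate_wq(n_sites=200, n_regions=3, seed=4)
        res = ConnectivityWQModel.from_dataframe(data, "y").fit(
            backward_select=False, maximal_random=False
        )
        text = res.summary()
        for cls in ("Riparian", "NRShw", "NRMid", "NRDeep"):
            assert cls in text


class TestGroupingSelection:
    def test_true_grouping_beats_shuffled_labels(self):
        data, _ = simulate_wq(random_intercept_sd=1.0, n_sites=800, n_regions=6,
                              seed=31)
        rng = np.random.default_rng(0)
        data["shuffled"] = rng.permutation(data["region"].to_numpy())
        best, table = select_grouping(data, "y", ["region", "shuffled"])
        assert best == "region"
        assert set(table["grouping"]) == {"region", "shuffled"}

    def test_single_candidate_returned_trivially(self):
        data, _ = simulate_wq(n_sites=200, n_regions=3, seed=32)
        best, table = select_grouping(data, "y", ["region"])
        assert best == "region" and len(table) == 1

    def test_identical_groupings_have_equal_aic(self):
        data, _ = simulate_wq(n_sites=200, n_regions=3, seed=33)
        data["region2"] = data["region"]
        best, table = select_grouping(data, "y", ["region", "region2"])
        aics = table.set_index("grouping")["aic"]
        assert aics["region"] == pytest.approx(aics["region2"], abs=1e-4)
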