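"""Logistic cut-offs, multivariable fall-risk fits and repeated-split
cross-validated evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gstride.risk import (
    ModelSpec,
    confusion_from_rates,
    cross_validate,
    cutoff_from_coefficients,
    cutoff_table,
    derive_stats,
    describe_cohort,
    fit_model,
    fit_univariate_cutoff,
    probability_report,
)
from gstride.synthetic import CohortSpec, VariableSpec, default_cohort_spec, generate_cohort


def _two_gaussian_cohort(m1, m0, sd=1.0, n=200, seed=0, name="x"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "faller": np.r_[np.ones(n, int), np.zeros(n, int)],
            name: np.r_[rng.normal(m1, sd, n), rng.normal(m0, sd, n)],
        }
    )


class TestUnivariateCutoff:
    def test_cutoff_from_printed_walk_speed_coefficients(self):
        """The published 4-m walk-speed logistic (intercept 3.68, slope
        -4.33) puts the p=0.5 crossing at 0.849-0.850 m/s."""
        cut = cutoff_from_coefficients(3.68, -4.33)
        assert 0.849 <= cut <= 0.850

    def test_symmetric_coefficients_zero_cutoff(self):
        assert cutoff_from_coefficients(0.0, -1.0) == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cutoff_from_coefficients(1.0, 0.0)

    def test_two_gaussian_cutoff_approaches_midpoint(self):
        """Equal-n, equal-SD Gaussians: the Bayes boundary is the midpoint
        of the means."""
        df = _two_gaussian_cohort(1.0, 0.0, sd=1.0, n=1000, seed=12)
        cut = fit_univariate_cutoff(df, "x")
        assert cut.cutoff == pytest.approx(0.5, abs=0.05)
        assert cut.coefficient > 0

    def test_direction_contract(self):
        """Larger values lowering fall odds fit a negative slope."""
        df = _two_gaussian_cohort(-1.0, 1.0, n=300, seed=3)
        cut = fit_univariate_cutoff(df, "x")
        assert cut.coefficient < 0
        assert cut.p < 1e-6 and cut.z < 0

    def test_constant_variable_rejected(self):
        df = _two_gaussian_cohort(0, 0, n=30, seed=0)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_univariate_cutoff(df, "c")

    def test_single_class_rejected(self):
        df = _two_gaussian_cohort(0, 1, n=30, seed=0)
        with pytest.raises(ValueError):
            fit_univariate_cutoff(df[df.faller == 1], "x")

    def test_complete_separation_flagged_with_finite_cutoff(self):
        df = pd.DataFrame(
            {"faller": [0] * 20 + [1] * 20, "x": list(range(20)) + list(range(30, 50))}
        )
        cut = fit_univariate_cutoff(df, "x")
        assert cut.separation
        assert np.isfinite(cut.cutoff)
        assert 19 <= cut.cutoff <= 31  # inside the separating gap

    @given(st.integers(0, 2000))
    def test_cutoff_equals_probability_threshold_classification(self, seed):
        """Sign-aware cut-off thresholding == fitted probability >= 0.5,
        row-exhaustively."""
        rng = np.random.default_rng(seed)
        d = rng.uniform(0.2, 2.0)
        df = _two_gaussian_cohort(d, 0.0, sd=1.0, n=30, seed=seed)
        cut = fit_univariate_cutoff(df, "x")
        if cut.coefficient == 0:
            return
        p = 1.0 / (1.0 + np.exp(-(cut.intercept + cut.coefficient * df["x"])))
        np.testing.assert_array_equal(cut.classify(df["x"]), (p >= 0.5).astype(int))

    def test_cutoff_table_covers_requested_variables(self, default_cohort):
        tab = cutoff_table(default_cohort, ["Speed_4m_walk", "TUG", "StepSpeed"])
        assert list(tab["variable"]) == ["Speed_4m_walk", "TUG", "StepSpeed"]
        # direction of effect matches the cohort construction
        d = dict(zip(tab["variable"], tab["coefficient"]))
        assert d["Speed_4m_walk"] < 0 and d["StepSpeed"] < 0 and d["TUG"] > 0


class TestMultivariableFit:
    def test_parameter_recovery_within_3_se(self):
        """n=5000 draws from a known logistic model: every fitted term
        within 3 standard errors of the truth."""
        rng = np.random.default_rng(8)
        n = 5000
        beta = {"a": 0.8, "b": -1.2, "c": 0.0}
        df = pd.DataFrame({k: rng.normal(0, 1, n) for k in beta})
        eta = -0.3 + sum(b * df[k] for k, b in beta.items())
        df["faller"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_model(df, ModelSpec("known", list(beta)))
        truth = {"Intercept": -0.3, **beta}
        for term, row in fit.params.iterrows():
            se = (row["ci_high"] - row["ci_low"]) / (2 * 1.959964)
            assert abs(row["coef"] - truth[term]) < 3 * se

    def test_fit_matches_independent_mle(self, default_cohort):
        """Cross-check against an unpenalized scikit-learn fit."""
        from sklearn.linear_model import LogisticRegression

        spec = ModelSpec.canonical("mix")
        fit = fit_model(default_cohort, spec)
        X = default_cohort[spec.predictors].to_numpy(float)
        sk = LogisticRegression(C=1e8, max_iter=5000, tol=1e-10).fit(
            X, default_cohort["faller"]
        )
        ours = fit.params.loc[spec.predictors, "coef"].to_numpy()
        np.testing.assert_allclose(ours, sk.coef_[0], rtol=1e-3, atol=1e-4)
        assert fit.params.loc["Intercept", "coef"] == pytest.approx(
            sk.intercept_[0], rel=1e-3, abs=1e-4
        )

    def test_rank_deficient_design_names_columns(self, default_cohort):
        df = default_cohort.copy()
        df["dead"] = 0.0
        with pytest.raises(ValueError, match="dead"):
            fit_model(df, ModelSpec("bad", ["FES1", "dead"]))

    def test_null_model_intercept_is_logit_prevalence(self, default_cohort):
        fit = fit_model(default_cohort, ModelSpec("null", []))
        p = default_cohort["faller"].mean()
        assert fit.params.loc["Intercept", "coef"] == pytest.approx(
            np.log(p / (1 - p)), abs=1e-6
        )

    def test_ci_brackets_point_estimate(self, default_cohort):
        fit = fit_model(default_cohort, ModelSpec.canonical("conv"))
        assert (fit.params["ci_low"] <= fit.params["coef"]).all()
        assert (fit.params["coef"] <= fit.params["ci_high"]).all()
        assert fit.deviance == pytest.approx(-2 * fit.llf)


class TestDeriveStats:
    def test_printed_model_comparison_column_is_internally_consistent(self):
        """Published Conv column: sens .78, spec .79, prevalence .51 imply
        accuracy .785 (prints as 0.78); with the printed PPV 0.80, F1 is
        0.789 (prints as 0.79); the implied PPV is within 0.01 of 0.80."""
        stats = derive_stats(*confusion_from_rates(0.78, 0.79, 0.51))
        assert round(stats["accuracy"], 2) == 0.78
        assert abs(stats["ppv"] - 0.80) <= 0.01
        f1_printed = 2 * 0.80 * 0.78 / (0.80 + 0.78)
        assert round(f1_printed, 2) == 0.79
        assert abs(stats["f1"] - 0.79) <= 0.01

    def test_uniform_matrix(self):
        stats = derive_stats(10, 10, 10, 10)
        assert stats["accuracy"] == 0.5
        assert stats["sensitivity"] == 0.5
        assert stats["specificity"] == 0.5

    def test_zero_denominator_reported_as_nan(self):
        stats = derive_stats(0, 0, 50, 50)  # nothing predicted positive
        assert np.isnan(stats["ppv"])
        assert stats["sensitivity"] == 0.0

    def test_negative_or_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            derive_stats(-1, 0, 1, 0)
        with pytest.raises(ValueError):
            derive_stats(0, 0, 0, 0)

    @given(
        st.tuples(
            st.floats(0, 500), st.floats(0, 500), st.floats(0, 500), st.floats(0, 500)
        ).filter(lambda m: sum(m) > 0)
    )
    def test_identities_hold_for_any_matrix(self, mat):
        tp, fp, tn, fn = mat
        s = derive_stats(tp, fp, tn, fn)
        if np.isfinite(s["sensitivity"]) and np.isfinite(s["specificity"]):
            acc = s["sensitivity"] * s["prevalence"] + s["specificity"] * (
                1 - s["prevalence"]
            )
            assert s["accuracy"] == pytest.approx(acc, abs=1e-12)
        if np.isfinite(s["f1"]):
            assert s["f1"] == pytest.approx(
                2 * s["ppv"] * s["sensitivity"] / (s["ppv"] + s["sensitivity"]),
                abs=1e-12,
            )


class TestCrossValidation:
    def test_study_sized_bookkeeping(self, default_cohort):
        ev = cross_validate(default_cohort, ModelSpec.canonical("conv"), seed=1)
        assert ev.total_test_observations_nominal == pytest.approx(2445.0)
        assert ev.n_test == 49
        assert ev.total_test_observations == 50 * 49

    def test_separable_cohort_near_perfect(self):
        spec = CohortSpec(
            n_fallers=60, n_nonfallers=60,
            variables={"gap": VariableSpec(10.0, 1.0, 0.0, 1.0)},
        )
        df = generate_cohort(spec, seed=2)
        ev = cross_validate(df, ModelSpec("gap", ["gap"]), seed=3)
        assert ev.accuracy >= 0.99
        assert ev.sensitivity >= 0.99 and ev.specificity >= 0.99

    def test_pure_noise_features_chance_accuracy(self):
        spec = CohortSpec(
            n_fallers=200, n_nonfallers=200,
            variables={"n1": VariableSpec(0, 1, 0, 1), "n2": VariableSpec(0, 1, 0, 1)},
        )
        df = generate_cohort(spec, seed=4)
        ev = cross_validate(df, ModelSpec("noise", ["n1", "n2"]), seed=5)
        assert ev.accuracy == pytest.approx(0.5, abs=0.07)
        assert ev.auc == pytest.approx(0.5, abs=0.1)

    def test_same_seed_identical_stats(self, default_cohort):
        spec = ModelSpec.canonical("mix")
        a = cross_validate(default_cohort, spec, seed=9)
        b = cross_validate(default_cohort, spec, seed=9)
        assert a == b
        c = cross_validate(default_cohort, spec, seed=10)
        assert c != a

    def test_mean_test_prevalence_tracks_cohort(self, default_cohort):
        """Unstratified splits: mean test prevalence within 3 Monte-Carlo
        SDs of the cohort prevalence."""
        ev = cross_validate(default_cohort, ModelSpec.canonical("speed4m"), seed=6)
        prev_cohort = default_cohort["faller"].mean()
        mc_sd = np.sqrt(prev_cohort * (1 - prev_cohort) / ev.n_test / ev.n_repeats)
        assert abs(ev.prevalence - prev_cohort) < 3 * mc_sd

    def test_single_class_train_splits_redrawn(self):
        """A cohort with 3 fallers in 24 rows forces single-class training
        draws; the evaluation must still complete on two-class fits."""
        spec = CohortSpec(
            n_fallers=3, n_nonfallers=21, variables={"x": VariableSpec(1, 1, 0, 1)}
        )
        df = generate_cohort(spec, seed=0)
        ev = cross_validate(df, ModelSpec("x", ["x"]), n_repeats=30,
                            train_fraction=0.3, seed=7)
        assert ev.n_repeats == 30
        assert np.isfinite(ev.accuracy)

    def test_matrix_vs_stats_averaging_modes(self, default_cohort):
        spec = ModelSpec.canonical("sppb")
        m = cross_validate(default_cohort, spec, seed=8, average="matrix")
        s = cross_validate(default_cohort, spec, seed=8, average="stats")
        assert m.accuracy == pytest.approx(s.accuracy, abs=0.02)

    def test_tiny_cohort_rejected(self):
        df = _two_gaussian_cohort(1, 0, n=5, seed=0)
        with pytest.raises(ValueError):
            cross_validate(df, ModelSpec("x", ["x"]), seed=0)


class TestProbabilityReport:
    def test_separable_cohort_mass_splits_at_threshold(self):
        df = _two_gaussian_cohort(8.0, 0.0, sd=0.5, n=50, seed=1)
        tab = probability_report(df, ModelSpec("x", ["x"]))
        mid = len(tab) // 2
        assert tab["fallers"][:mid].sum() == 0
        assert tab["nonfallers"][mid:].sum() == 0

    def test_single_class_input_one_empty_histogram(self):
        df = _two_gaussian_cohort(1.0, 0.0, n=40, seed=2)
        fit = fit_model(df, ModelSpec("x", ["x"]))
        only_fallers = df[df.faller == 1]
        tab = probability_report(only_fallers, ModelSpec("x", ["x"]), fit=fit)
        assert tab["nonfallers"].sum() == 0
        assert tab["fallers"].sum() == len(only_fallers)

    def test_faller_fraction_above_threshold_equals_sensitivity(self, default_cohort):
        spec = ModelSpec.canonical("mix")
        fit = fit_model(default_cohort, spec)
        p = fit.predict(default_cohort)
        y = default_cohort["faller"].to_numpy()
        pred = (p >= 0.5).astype(int)
        from gstride.risk import derive_stats as ds

        stats = ds(
            float(((pred == 1) & (y == 1)).sum()),
            float(((pred == 1) & (y == 0)).sum()),
            float(((pred == 0) & (y == 0)).sum()),
            float(((pred == 0) & (y == 1)).sum()),
        )
        frac = (p[y == 1] >= 0.5).mean()
        assert frac == pytest.approx(stats["sensitivity"])

    def test_figure_written(self, default_cohort, tmp_path):
        out = tmp_path / "hist.png"
        probability_report(default_cohort, ModelSpec.canonical("speed4m"), fig_path=out)
        assert out.stat().st_size > 0


class TestDescribeCohort:
    def test_null_groups_small_t(self):
        """Groups drawn from identical distributions (means AND SDs
        equalized): no continuous variable shows a large t."""
        spec = default_cohort_spec(n_fallers=1000, n_nonfallers=1000, effect_scale=0.0)
        for v in spec.variables.values():
            v.nonfaller_sd = v.faller_sd
        df = generate_cohort(spec, seed=13)
        rep = describe_cohort(df)
        tstats = rep.loc[rep["test"] == "t", "statistic"].abs()
        assert tstats.max() < 3.5  # ~45 null variables; |t|>3.5 is < 0.1% each

    def test_one_sd_shift_highly_significant(self):
        df = _two_gaussian_cohort(1.0, 0.0, sd=1.0, n=250, seed=14)
        rep = describe_cohort(df)
        row = rep[rep.variable == "x"].iloc[0]
        assert row["p"] < 0.001
        assert row["test"] == "t"

    def test_constant_categorical_zero_chi2(self):
        df = _two_gaussian_cohort(1.0, 0.0, n=50, seed=15)
        df["flag"] = 1
        rep = describe_cohort(df, categorical=["flag"])
        row = rep[rep.variable == "flag"].iloc[0]
        assert row["statistic"] == 0.0 and row["test"] == "chi2"

    def test_reports_minmax_mean_sd(self, default_cohort):
        rep = describe_cohort(default_cohort)
        row = rep[rep.variable == "Age"].iloc[0]
        assert row["faller_min"] >= 70 and row["faller_max"] <= 98
        assert row["faller_mean"] > row["nonfaller_mean"]  # fallers older
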