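"""Cohort statistics: the S' regression, agreement statistics
(ICC/TE/CV), the GXT midpoint speed, and the cohort table."""

import numpy as np
import pytest

import critspeed as cs


class TestSprimeRegression:
    def test_exact_linear_data_recovered(self, rng):
        fi = rng.uniform(45, 70, size=12)
        taud = rng.uniform(25, 75, size=12)
        sprime = 5.0 * fi + 2.0 * taud - 100.0
        res = cs.fit_sprime_regression(fi, taud, sprime)
        assert res.beta_fi == pytest.approx(5.0, abs=1e-9)
        assert res.beta_taud == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(-100.0, abs=1e-7)
        assert res.r2 == pytest.approx(1.0)
        assert res.see_m == pytest.approx(0.0, abs=1e-7)

    def test_prediction_at_means_equals_mean_response(self, rng):
        fi = rng.uniform(45, 70, size=14)
        taud = rng.uniform(25, 75, size=14)
        sprime = 4.0 * fi + 1.5 * taud - 80.0 + rng.normal(0, 20, size=14)
        res = cs.fit_sprime_regression(fi, taud, sprime)
        assert res.predict(fi.mean(), taud.mean()) == pytest.approx(
            sprime.mean(), rel=1e-12
        )

    def test_noisy_cohort_betas_within_two_se_most_of_the_time(self, rng):
        # noise scaled to the published SEE% range (~6-13% of mean S');
        # the 2-SE interval should cover the truth in ~95% of cohorts
        import statsmodels.api as sm

        truth = (5.2, 2.8, -200.0)
        hits = np.zeros(3)
        n_rep = 60
        for _ in range(n_rep):
            fi = rng.uniform(45, 70, size=14)
            taud = rng.uniform(25, 75, size=14)
            sprime = truth[0] * fi + truth[1] * taud + truth[2] + rng.normal(0, 20, 14)
            res = cs.fit_sprime_regression(fi, taud, sprime)
            se = sm.OLS(sprime, sm.add_constant(np.column_stack([fi, taud]))).fit().bse
            hits += [
                abs(res.beta_fi - truth[0]) < 2 * se[1],
                abs(res.beta_taud - truth[1]) < 2 * se[2],
                abs(res.intercept - truth[2]) < 2 * se[0],
            ]
        # per-coefficient coverage; ~93% expected with 11 residual df
        assert np.all(hits / n_rep >= 0.80)

    def test_collinear_design_rejected(self):
        fi = np.array([50.0, 55.0, 60.0, 65.0])
        with pytest.raises(ValueError, match="collinear|rank"):
            cs.fit_sprime_regression(fi, 2.0 * fi, np.array([1.0, 2.0, 3.0, 4.0]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cs.fit_sprime_regression([1, 2, 3], [4, 5, 6], [7, 8, 9])


class TestPredictSprime:
    @pytest.mark.parametrize(
        "betas, fi, taud, expected",
        [
            # published coefficients applied at the matching group means
            ((5.21, 2.83, -200.84), 60.34, 43.96, 237.9),
            ((4.71, 0.38, -102.98), 53.50, 50.16, 168.1),
        ],
    )
    def test_published_coefficient_plug_in(self, betas, fi, taud, expected):
        assert cs.predict_sprime(*betas, fi, taud) == pytest.approx(expected, abs=0.1)

    def test_constant_model(self):
        assert cs.predict_sprime(0.0, 0.0, 42.0, 55.0, 44.0) == 42.0


class TestAgreement:
    def test_identical_vectors(self):
        x = np.array([220.0, 240.0, 260.0, 250.0, 210.0])
        res = cs.agreement(x, x)
        assert res.icc_alpha == pytest.approx(1.0)
        assert res.te == pytest.approx(0.0, abs=1e-12)
        assert res.cv_percent == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_keeps_consistency_icc_at_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cs.icc_alpha(x, x + 5.0) == pytest.approx(1.0)
        assert cs.typical_error(x, x + 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_icc_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(4), 2),
                "rater": np.tile(["a", "b"], 4),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        icc = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        # consistency, average-measures form (label varies across versions)
        row = icc[icc["Type"].isin(["ICC3k", "ICC(C,k)"])]
        oracle = float(row["ICC"].iloc[0])
        assert cs.icc_alpha(x, y) == pytest.approx(oracle, abs=1e-9)

    def test_icc_matches_hand_anova_decomposition(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        table = np.column_stack([x, y])
        grand = table.mean()
        ss_rows = 2 * ((table.mean(axis=1) - grand) ** 2).sum()
        ss_cols = 4 * ((table.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((table - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows, ms_err = ss_rows / 3, ss_err / 3
        assert cs.icc_alpha(x, y) == pytest.approx((ms_rows - ms_err) / ms_rows)

    def test_independent_noise_lowers_icc(self, rng):
        x = rng.normal(240.0, 60.0, size=200)
        y_clean = x + rng.normal(0, 1.0, size=200)
        y_noisy = x + rng.normal(0, 60.0, size=200)
        assert cs.icc_alpha(x, y_noisy) < cs.icc_alpha(x, y_clean)

    def test_typical_error_hand_arithmetic(self):
        te = cs.typical_error([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        assert te == pytest.approx(np.std([-1, -1, -2], ddof=1) / np.sqrt(2))
        assert te == pytest.approx(0.408, abs=1e-3)

    def test_typical_error_scales_homogeneously(self, rng):
        x = rng.normal(10, 2, size=20)
        y = x + rng.normal(0, 1, size=20)
        assert cs.typical_error(3 * x, 3 * y) == pytest.approx(3 * cs.typical_error(x, y))

    def test_te_and_cv_symmetric_in_arguments(self, rng):
        x = rng.normal(240, 60, size=14)
        y = x + rng.normal(0, 20, size=14)
        assert cs.typical_error(x, y) == pytest.approx(cs.typical_error(y, x))
        assert cs.cv_percent(x, y) == pytest.approx(cs.cv_percent(y, x))

    def test_cv_is_te_over_grand_mean(self):
        x = np.array([220.0, 230.0, 240.0])
        y = np.array([225.0, 240.0, 228.0])
        expected = 100.0 * cs.typical_error(x, y) / np.concatenate([x, y]).mean()
        assert cs.cv_percent(x, y) == pytest.approx(expected)
        # doubling the measurements halves the CV of a fixed TE
        assert cs.cv_percent(2 * x, 2 * y) == pytest.approx(expected)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cs.icc_alpha([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            cs.typical_error([1.0], [2.0])
        with pytest.raises(ValueError):
            cs.cv_percent([-3.0, -1.0], [-2.0, -2.0])


class TestDelta50:
    def test_published_gxt_speeds(self):
        assert cs.delta50_speed(2.92, 4.07) == pytest.approx(3.495, abs=1e-9)

    @pytest.mark.parametrize("lo, hi, expected", [(2.0, 4.0, 3.0), (3.3, 3.3, 3.3)])
    def test_midpoint_arithmetic(self, lo, hi, expected):
        assert cs.delta50_speed(lo, hi) == pytest.approx(expected)

    def test_inverted_speeds_rejected(self):
        with pytest.raises(ValueError):
            cs.delta50_speed(4.1, 2.9)


class TestCohortTable:
    @pytest.fixture()
    def table(self):
        bouts, _ = cs.generate_cohort(n=6, conditions=("linear",), seed=3, noise_sd=0.1)
        rows = [(s, c, cs.AllOutTest(tr).fit()) for s, c, tr in bouts]
        return cs.CohortTable.from_results(rows)

    def test_csv_round_trip(self, table, tmp_path):
        path = tmp_path / "cohort.csv"
        table.to_csv(path)
        back = cs.CohortTable.from_csv(path)
        for col in ("Smax", "tc", "taud", "Ad", "FI", "S0", "Sprime"):
            assert np.allclose(back.df[col], table.df[col])

    def test_summary_has_means_and_sds_per_condition(self, table):
        summ = table.summary()
        assert "linear" in summ.index
        assert {"Smax", "Smax_sd", "Sprime", "Sprime_sd"} <= set(summ.columns)

    def test_regression_and_agreement_run_end_to_end(self, table):
        reg = table.sprime_regression("linear")
        assert reg.n == 6 and np.isfinite(reg.r2)
        agr = table.dprime_sprime_agreement("linear")
        assert 0.0 < agr.icc_alpha <= 1.0
        assert agr.te >= 0.0

    def test_duplicate_subject_condition_rejected(self, table):
        import pandas as pd

        dup = pd.concat([table.df, table.df.iloc[[0]]])
        with pytest.raises(ValueError):
            cs.CohortTable(dup)
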