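"""Association models: standardization, OLS, LMM, interactions, BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from fwbio.cohort import CohortTruth, make_cohort
from fwbio.models import (biomarker_outcome_grid, fdr_adjust,
                          fit_baseline_model, fit_interaction_model,
                          fit_longitudinal_model, results_to_frame,
                          standardize_predictors)


def bh_oracle(p):
    """Brute-force step-up definition: adj_(i) = min_{j>=i} p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [p[order[r - 1]] * m / r for r in range(rank, m + 1)]
        adj_sorted[rank - 1] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestStandardize:
    def test_zscores_baseline_rows(self):
        df = pd.DataFrame({"visit": [0, 0, 0], "x": [1.0, 2.0, 3.0]})
        out = standardize_predictors(df, ["x"])
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_on_zscores(self):
        df = pd.DataFrame({"visit": [0] * 5, "x": [-1.2, -0.6, 0.0, 0.6, 1.2]})
        once = standardize_predictors(df, ["x"])
        twice = standardize_predictors(once, ["x"])
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_baseline_rows_determine_transform_for_all_visits(self):
        # 2 participants x 2 visits; baseline x = (0, 2) -> mean 1, sd sqrt(2)
        df = pd.DataFrame({"participant_id": ["a", "a", "b", "b"],
                           "visit": [0, 1, 0, 1],
                           "x": [0.0, 0.0, 2.0, 2.0]})
        out = standardize_predictors(df, ["x"])
        sd = np.sqrt(2.0)
        np.testing.assert_allclose(out["x"],
                                   [(0 - 1) / sd, (0 - 1) / sd,
                                    (2 - 1) / sd, (2 - 1) / sd], atol=1e-12)
        assert out.attrs["standardization"]["x"]["mean"] == pytest.approx(1.0)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"visit": [0, 0], "x": [1.0, 1.0]})
        with pytest.raises(ValueError, match="zero variance"):
            standardize_predictors(df, ["x"])


def _baseline_frame(n=200, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)], "visit": 0,
        "age": rng.normal(73, 7, n), "sex": rng.integers(0, 2, n),
        "education": rng.normal(16, 2, n), "race": rng.integers(0, 2, n),
        "apoe4": rng.integers(0, 2, n), "diagnosis": rng.integers(0, 2, n),
        "fsrp": rng.normal(11, 4, n), "bm": rng.normal(0, 1, n),
    })
    return df, rng


class TestBaselineModel:
    def test_exact_fit_recovers_coefficient(self):
        df, rng = _baseline_frame()
        df["y"] = 2.0 * df["bm"]
        res = fit_baseline_model(df, "bm", "y", covariates=("age", "sex"))
        assert res.beta == pytest.approx(2.0, abs=1e-9)

    def test_three_point_textbook_regression(self):
        df = pd.DataFrame({"participant_id": list("abcdefghijklmnopqrst"),
                           "x": np.tile([0.0, 1.0, 2.0], 7)[:20],
                           "y": np.tile([0.0, 1.0, 2.0], 7)[:20]})
        res = fit_baseline_model(df, "x", "y", covariates=())
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.fit.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation_p_values_roughly_uniform(self):
        from scipy import stats
        ps = []
        for s in range(300):
            df, rng = _baseline_frame(n=120, seed=s)
            df["y"] = rng.normal(size=len(df))
            ps.append(fit_baseline_model(df, "bm", "y").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.035)

    def test_rank_deficiency_names_aliased_term(self):
        df, rng = _baseline_frame()
        df["dup"] = df["bm"]
        df["y"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="dup"):
            fit_baseline_model(df, "bm", "y", covariates=("age", "dup"))

    def test_standardization_invertible_on_slope(self):
        df, rng = _baseline_frame(seed=5)
        df["y"] = 1.7 * df["bm"] + rng.normal(0, 0.5, len(df))
        raw = fit_baseline_model(df, "bm", "y", covariates=("age",))
        std = standardize_predictors(df, ["bm"])
        z = fit_baseline_model(std, "bm", "y", covariates=("age",))
        sd = std.attrs["standardization"]["bm"]["sd"]
        assert z.beta / sd == pytest.approx(raw.beta, abs=1e-9)


def _longitudinal_zero_re(n=150, residual_sd=0.0, seed=4):
    truth = CohortTruth(random_intercept_sd=0.0, random_age_slope_sd=0.0,
                        intercept_slope_corr=0.0, residual_sd=residual_sd,
                        attrition_probs=(1.0, 1.0, 1.0, 1.0))
    cohort, bm, _ = make_cohort(n, truth=truth, seed=seed)
    return cohort.merge(bm, on="participant_id"), truth


class TestLongitudinalModel:
    def test_deterministic_limit_recovers_generating_coefficients(self):
        merged, truth = _longitudinal_zero_re(residual_sd=0.0)
        res = fit_longitudinal_model(merged, "hippocampal_fw", "memory_composite")
        assert res.beta == pytest.approx(truth.fixed_effects["biomarker"], abs=1e-6)
        assert res.terms.loc["age_c", "beta"] == pytest.approx(
            truth.fixed_effects["age"], abs=1e-6)

    def test_zero_cluster_variance_matches_pooled_ols(self):
        # small residual noise keeps the REML variance estimates at the
        # boundary, so the GLS weighting collapses to OLS
        import statsmodels.api as sm
        merged, truth = _longitudinal_zero_re(residual_sd=0.005, seed=8)
        res = fit_longitudinal_model(merged, "hippocampal_fw", "memory_composite")
        rows = merged.copy()
        base_age = rows.sort_values("age").groupby("participant_id")["age"].first()
        rows["age_c"] = rows["age"] - base_age.mean()
        X = sm.add_constant(rows[["hippocampal_fw", "age_c", "sex", "education",
                                  "race", "apoe4", "diagnosis", "fsrp"]])
        ols = sm.OLS(rows["memory_composite"], X).fit()
        np.testing.assert_allclose(res.terms["beta"], ols.params,
                                   rtol=1e-3, atol=1e-3)

    def test_single_fit_recovery_within_three_se(self):
        cohort, bm, truth = make_cohort(300, seed=21)
        merged = cohort.merge(bm, on="participant_id")
        res = fit_longitudinal_model(merged, "hippocampal_fw", "memory_composite")
        assert abs(res.beta - truth.fixed_effects["biomarker"]) <= 3 * res.se
        assert res.variance_components["residual_var"] == pytest.approx(
            truth.residual_sd**2, rel=0.5)

    def test_diagnosis_predicts_biomarker_outcome_route(self):
        cohort, bm, truth = make_cohort(250, seed=22)
        merged = cohort.merge(bm, on="participant_id")
        res = fit_longitudinal_model(merged, "diagnosis", "hippocampal_fw",
                                     covariates=("age", "sex"))
        # MCI shifts the latent factor by +0.8 with loading 0.8 -> ~ +0.64
        assert res.beta == pytest.approx(0.64, abs=3 * res.se)


class TestInteractionModel:
    def test_product_coefficient_recovered(self):
        df, rng = _baseline_frame(n=4000, seed=10)
        df["mod"] = rng.normal(size=len(df))
        df["y"] = 0.3 * df["bm"] + 0.2 * df["mod"] + \
            0.5 * df["bm"] * df["mod"] + rng.normal(0, 0.1, len(df))
        res = fit_interaction_model(df, "bm", "mod", "y", covariates=("age",))
        assert res.beta == pytest.approx(0.5, abs=0.01)

    def test_null_interaction_p_uniform(self):
        from scipy import stats
        ps = []
        for s in range(200):
            df, rng = _baseline_frame(n=150, seed=300 + s)
            df["mod"] = rng.normal(size=len(df))
            df["y"] = 0.3 * df["bm"] + 0.2 * df["mod"] + rng.normal(0, 1, len(df))
            ps.append(fit_interaction_model(df, "bm", "mod", "y",
                                            covariates=("age",)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_moderator_rejected(self):
        df, rng = _baseline_frame()
        df["mod"] = 1.0
        df["y"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="constant"):
            fit_interaction_model(df, "bm", "mod", "y")

    def test_age_interaction_uses_longitudinal_model(self):
        cohort, bm, _ = make_cohort(120, seed=30)
        merged = cohort.merge(bm, on="participant_id")
        res = fit_interaction_model(merged, "hippocampal_fw", "age",
                                    "memory_composite")
        assert res.kind == "lmm"
        assert res.predictor == "hippocampal_fw_x_age"


class TestFdrAdjust:
    @pytest.mark.parametrize("p,want", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_known_examples(self, p, want):
        np.testing.assert_allclose(fdr_adjust(p), want, atol=1e-12)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])


class TestGrid:
    def test_counts_and_one_family(self):
        df, rng = _baseline_frame(n=100, seed=40)
        df["bm2"] = rng.normal(size=len(df))
        df["y1"] = rng.normal(size=len(df))
        df["y2"] = rng.normal(size=len(df))
        res = biomarker_outcome_grid(df, ["bm", "bm2"], ["y1", "y2"])
        assert len(res) == 4
        assert all(r.p_fdr is not None for r in res)
        frame = results_to_frame(res)
        assert set(frame["biomarker"]) == {"bm", "bm2"}

    def test_duplicated_biomarker_columns_identical_results(self):
        df, rng = _baseline_frame(n=100, seed=41)
        df["copy"] = df["bm"]
        df["y"] = rng.normal(size=len(df))
        res = biomarker_outcome_grid(df, ["bm", "copy"], ["y"])
        assert res[0].beta == pytest.approx(res[1].beta, abs=1e-12)
        assert res[0].se == pytest.approx(res[1].se, abs=1e-12)

    def test_row_order_invariance(self):
        df, rng = _baseline_frame(n=100, seed=42)
        df["y"] = rng.normal(size=len(df))
        res1 = biomarker_outcome_grid(df, ["bm"], ["y"])
        res2 = biomarker_outcome_grid(df.sample(frac=1, random_state=1),
                                      ["bm"], ["y"])
        assert res1[0].beta == pytest.approx(res2[0].beta, abs=1e-12)

    def test_per_biomarker_family_mode(self):
        df, rng = _baseline_frame(n=100, seed=43)
        df["bm2"] = rng.normal(size=len(df))
        df["y1"] = rng.normal(size=len(df))
        df["y2"] = rng.normal(size=len(df))
        res = biomarker_outcome_grid(df, ["bm", "bm2"], ["y1", "y2"],
                                     fdr_family="per_biomarker")
        for r in res:
            assert r.p_fdr >= r.p - 1e-15
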