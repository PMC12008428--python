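"""Endpoint rules, logistic models, cluster-comparison statistics, ICC."""

import math

import numpy as np
import pandas as pd
import pytest

from octomics.outcomes import (
    InputError,
    POOR_VISION_LOGMAR,
    backward_stepwise_logistic,
    classify_residual_dme,
    compare_clusters,
    dichotomize_bcva,
    dunn_posthoc,
    icc_intra_rater,
    odds_ratio_2x2,
    rdme_label,
    snellen_to_logmar,
    univariate_logistic,
)


class TestEndpoints:
    @pytest.mark.parametrize("num,den,expect", [
        (20, 20, 0.0), (20, 200, 1.0), (20, 63, math.log10(63 / 20)),
    ])
    def test_snellen_to_logmar(self, num, den, expect):
        assert snellen_to_logmar(num, den) == pytest.approx(expect)

    def test_snellen_nonpositive_rejected(self):
        with pytest.raises(InputError):
            snellen_to_logmar(0, 20)

    @pytest.mark.parametrize("base,post,expect", [
        (400, 370, True),    # 7.5% < 10% in the <=400 band
        (500, 420, False),   # 16% >= 15% in the 401-500 band
        (601, 430, False),   # 28.5% >= 25% in the >600 band
        (550, 470, True),    # 14.5% < 20% in the 501-600 band
        (300, 350, True),    # worsening is always residual
    ])
    def test_residual_rule_bands(self, base, post, expect):
        assert classify_residual_dme(base, post) is expect

    def test_residual_rule_exhaustive_grid_with_boundaries(self):
        # closed-form oracle over a dense CMT grid including band edges
        for base in list(range(250, 900, 7)) + [400, 401, 500, 501, 600, 601]:
            thr = 0.10 if base <= 400 else 0.15 if base <= 500 else \
                0.20 if base <= 600 else 0.25
            for frac in np.arange(-0.10, 0.60, 0.013):
                post = base * (1 - frac)
                assert classify_residual_dme(base, post) is bool(
                    (base - post) / base < thr)

    def test_residual_monotone_in_post_cmt(self):
        for base in (380.0, 450.0, 560.0, 700.0):
            labels = [classify_residual_dme(base, post)
                      for post in np.linspace(base * 1.2, base * 0.3, 60)]
            # residual (True) can only switch to False as post decreases
            assert all(not (not a and b) for a, b in zip(labels, labels[1:]))

    def test_nonpositive_cmt_rejected(self):
        with pytest.raises(InputError):
            classify_residual_dme(-1.0, 300.0)

    @pytest.mark.parametrize("res,rec,expect", [
        (False, False, False), (True, False, True), (False, True, True),
    ])
    def test_rdme_label_is_or(self, res, rec, expect):
        assert rdme_label(res, rec) is expect

    def test_bcva_dichotomization_boundary_is_poor(self):
        assert dichotomize_bcva(1.0) is True
        assert dichotomize_bcva(0.0) is False
        assert dichotomize_bcva(POOR_VISION_LOGMAR) is True


class TestLogistic:
    def test_null_feature_or_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 2, 10_000)
        row = univariate_logistic(x, y)
        assert 0.95 < row.odds_ratio < 1.05

    def test_perfect_separation_flagged(self):
        y = np.repeat([0, 1], 20)
        row = univariate_logistic(y.astype(float), y)
        assert row.separation_flag

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        p = 1 / (1 + np.exp(-0.56 * x))
        y = (rng.random(5000) < p).astype(float)
        row = univariate_logistic(x, y)
        assert row.odds_ratio == pytest.approx(np.exp(0.56), rel=0.10)

    def test_ci_consistent_with_beta_se(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(float)
        row = univariate_logistic(x, y)
        assert row.ci_low == pytest.approx(np.exp(row.beta - 1.96 * row.se), rel=1e-9)
        assert row.ci_high == pytest.approx(np.exp(row.beta + 1.96 * row.se), rel=1e-9)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(InputError):
            univariate_logistic(np.arange(10.0), np.arange(10))


class TestStepwise:
    def _data(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.standard_normal((n, 10)),
                         columns=[f"x{i}" for i in range(10)])
        logit = 0.8 * x["x0"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        return x, y

    def test_true_predictor_retained(self):
        x, y = self._data()
        res = backward_stepwise_logistic(x, y)
        assert "x0" in res.retained_features
        for row in res.rows:
            assert row.p < 0.05

    def test_all_null_usually_empty(self):
        kept = 0
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            x = pd.DataFrame(rng.standard_normal((400, 5)),
                             columns=[f"x{i}" for i in range(5)])
            y = rng.integers(0, 2, 400).astype(float)
            res = backward_stepwise_logistic(x, y)
            kept += bool(res.rows)
        assert kept <= 15  # empty final model in the majority of runs

    def test_single_significant_candidate_returned_unchanged(self):
        x, y = self._data(seed=3)
        res = backward_stepwise_logistic(x[["x0"]], y)
        assert res.retained_features == ["x0"]


class TestClusterComparison:
    def _clinical(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([1, 2, 3, 4], n // 4)
        df = pd.DataFrame({
            "age": rng.normal(60, 8, n),
            "cmt": rng.normal(450, 90, n) + 40 * (labels == 3),
            "sex": rng.choice(["m", "f"], n),
            "rdme": rng.integers(0, 2, n),
        })
        return df, labels

    def test_constant_variable_statistic_zero(self):
        df, labels = self._clinical()
        df["const"] = 5.0
        out = compare_clusters(df[["const"]], labels, continuous=["const"],
                              categorical=[])
        assert out.loc["const", "statistic"] == 0.0
        assert out.loc["const", "p"] == 1.0

    def test_cross_product_odds_ratio_closed_form(self):
        orr, (lo, hi) = odds_ratio_2x2(12, 23, 122, 77)
        assert orr == pytest.approx((12 * 77) / (23 * 122))
        assert lo < orr < hi

    def test_fisher_branch_on_sparse_2x2(self):
        labels = np.repeat([1, 2], 12)
        df = pd.DataFrame({"rare": [1] * 2 + [0] * 22})
        out = compare_clusters(df, labels, continuous=[], categorical=["rare"])
        assert out.loc["rare", "test"] == "fisher-exact"

    def test_dunn_flags_the_shifted_cluster(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([1, 2, 3], 40)
        v = rng.normal(0, 1, 120)
        v[labels == 3] += 3.0
        res = dunn_posthoc(v, labels)
        assert res[(1, 3)]["p"] < 0.01
        assert res[(2, 3)]["p"] < 0.01
        assert res[(1, 2)]["p"] > 0.05

    def test_single_cluster_rejected(self):
        df, _ = self._clinical()
        with pytest.raises(InputError):
            compare_clusters(df, np.ones(len(df)))


class TestICC:
    def test_identical_measurements_icc_one(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        icc, _ = icc_intra_rater(a, a)
        assert icc == pytest.approx(1.0, abs=1e-9)

    def test_independent_measurements_icc_near_zero(self):
        rng = np.random.default_rng(6)
        icc, _ = icc_intra_rater(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert abs(icc) <= 0.1

    def test_variance_component_construction_recovers_target(self):
        # true ICC = var_subject / (var_subject + var_error) = 0.94
        rng = np.random.default_rng(7)
        n = 500
        subj = rng.normal(0, 1, n)
        noise_sd = math.sqrt(1 / 0.94 - 1)
        t1 = subj + rng.normal(0, noise_sd, n)
        t2 = subj + rng.normal(0, noise_sd, n)
        icc, (lo, hi) = icc_intra_rater(t1, t2)
        assert icc == pytest.approx(0.94, abs=0.02)
        assert lo < icc < hi

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InputError):
            icc_intra_rater([1.0, 2.0], [1.0, 2.0])
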