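"""Bland-Altman, regression/correlation, proportional bias, ICC, normality."""

import math

import numpy as np
import pandas as pd
import pytest

from sonopupil import (
    PairedSample,
    ReliabilityTable,
    bland_altman,
    compare_modalities,
    icc,
    normality_pvalue,
    ols_and_pearson,
    proportional_bias,
)

from conftest import exact_moment_sample


def _pairs(a, b, name="m"):
    return [PairedSample(str(i), name, float(x), float(y))
            for i, (x, y) in enumerate(zip(a, b))]


class TestBlandAltman:
    def test_identical_methods(self):
        res = bland_altman(_pairs([1, 2, 3], [1, 2, 3]))
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        res = bland_altman(_pairs([4, 6], [3, 5]))
        assert res.bias == pytest.approx(1.0)
        assert res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_bias_is_difference_of_means(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(4, 1, 30), rng.normal(4, 1, 30)
            res = bland_altman(_pairs(a, b))
            assert res.bias == pytest.approx(res.mean_a - res.mean_b, abs=1e-12)
            assert res.loa_low <= res.bias <= res.loa_high

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([1], [1]))

    def test_non_finite_pair_rejected(self):
        with pytest.raises(ValueError):
            PairedSample("e", "m", math.nan, 1.0)


class TestOLSPearson:
    def test_exact_line(self):
        b = np.arange(5.0)
        res = ols_and_pearson(_pairs(2 * b + 1, b))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r_ci_low == res.r_ci_high == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        b = np.arange(5.0)
        res = ols_and_pearson(_pairs(-b, b))
        assert res.pearson_r == pytest.approx(-1.0)

    def test_fisher_ci_hand_computed(self):
        """Frozen values from direct evaluation of the atanh/tanh formulas."""
        res = ols_and_pearson(_pairs([1, 2, 3, 5], [1, 2, 3, 4]))
        assert res.pearson_r == pytest.approx(0.9827076298239908, abs=1e-12)
        assert res.slope == pytest.approx(1.3, abs=1e-12)
        assert res.intercept == pytest.approx(-0.5, abs=1e-12)
        assert res.r_ci_low == pytest.approx(0.3893321871705172, abs=1e-9)
        assert res.r_ci_high == pytest.approx(0.9996539430279581, abs=1e-9)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            b = rng.normal(0, 1, 25)
            a = 0.7 * b + rng.normal(0, 0.5, 25)
            res = ols_and_pearson(_pairs(a, b))
            assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-9)
            assert res.r_ci_low <= res.pearson_r <= res.r_ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ols_and_pearson(_pairs([1, 1, 1, 1], [1, 2, 3, 4]))


class TestProportionalBias:
    def test_constant_offset_has_no_trend(self):
        beta, p = proportional_bias(_pairs([2, 3, 4, 5], [1, 2, 3, 4]))
        assert beta == 0.0
        assert p == 1.0

    def test_perfect_proportionality_is_significant(self):
        rng = np.random.default_rng(1)
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a = b * 1.5 + rng.normal(0, 1e-9, 5)  # d almost exactly proportional to m
        beta, p = proportional_bias(_pairs(a, b))
        assert p < 1e-6

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        a = rng.normal(4, 1, 40)
        b = a + rng.normal(0.1, 0.2, 40)
        beta, _ = proportional_bias(_pairs(a, b))
        d, m = a - b, (a + b) / 2
        X = np.c_[np.ones_like(m), m]
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        assert beta == pytest.approx(coef[1], abs=1e-10)

    def test_zero_mean_variance_rejected(self):
        with pytest.raises(ValueError):
            proportional_bias(_pairs([1, 1, 1, 1], [1, 1, 1, 1]))


def icc_sums_of_squares_oracle(x: np.ndarray, form: str) -> float:
    """Explicit two-way ANOVA decomposition written out long-hand."""
    n, k = x.shape
    gm = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - gm) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - gm) ** 2 for cm in col_means)
    ss_tot = sum((x[i][j] - gm) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "icc_2_1":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        t = ReliabilityTable("m", x)
        assert icc(t, "icc_2_1").icc == pytest.approx(1.0)
        assert icc(t, "icc_3_1").icc == pytest.approx(1.0)

    def test_shifted_columns_consistency_vs_absolute(self):
        """A constant inter-rater shift leaves consistency perfect but
        degrades absolute agreement (hand-computed ANOVA: ICC(2,1)=10/13)."""
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        t = ReliabilityTable("m", x)
        assert icc(t, "icc_3_1").icc == pytest.approx(1.0)
        assert icc(t, "icc_2_1").icc == pytest.approx(0.7692307692307692, abs=1e-12)

    def test_matches_oracle_random_matrix(self):
        rng = np.random.default_rng(21)
        x = rng.normal(4, 1, size=(6, 2))
        t = ReliabilityTable("m", x)
        for form in ("icc_2_1", "icc_3_1"):
            assert icc(t, form).icc == pytest.approx(
                icc_sums_of_squares_oracle(x, form), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.normal(4, 0.6, 8)
        x = subj[:, None] + rng.normal(0, 0.1, (8, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        t = ReliabilityTable("m", x)
        assert icc(t, "icc_2_1").icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc(t, "icc_3_1").icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            ReliabilityTable("m", x)


class TestNormality:
    def test_constant_sample_undefined(self):
        assert math.isnan(normality_pvalue([2.0] * 10))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_pvalue([1.0, 2.0])

    def test_null_and_alternative_behaviour(self):
        rng = np.random.default_rng(17)
        null_hits = sum(normality_pvalue(rng.normal(size=40)) > 0.05 for _ in range(100))
        alt_hits = sum(
            normality_pvalue(rng.exponential(size=200)) < 0.05 for _ in range(100)
        )
        assert null_hits >= 90
        assert alt_hits >= 90


def _metrics_table(n_eyes=40, seed=0, lat_offset_a=0.0):
    """Synthetic session-averaged table for both modalities."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_eyes):
        init = rng.normal(4.05, 0.57)
        delta = rng.normal(0.25, 0.05)
        lat = rng.normal(0.28, 0.03)
        truth = dict(init=init, end=init * (1 - delta), delta=delta, lat=lat,
                     acv=rng.normal(1.46, 0.3), adv=rng.normal(0.78, 0.17))
        noise = dict(init=0.01, end=0.01, delta=0.003, lat=0.005, acv=0.02, adv=0.02)
        a = {k: v + rng.normal(0, noise[k]) for k, v in truth.items()}
        a["lat"] += lat_offset_a
        b = {k: v + rng.normal(0, noise[k]) for k, v in truth.items()}
        rows.append({"eye_id": f"E{i}", "modality": "auto_upa", **a})
        rows.append({"eye_id": f"E{i}", "modality": "ipa", **b})
    return pd.DataFrame(rows)


class TestCompareModalities:
    def test_null_offset_near_zero_bias(self):
        res = compare_modalities(_metrics_table(seed=2), "init")
        assert abs(res.bias) <= 0.02
        assert res.n == 40

    def test_injected_latency_offset_recovered(self):
        res = compare_modalities(_metrics_table(seed=3, lat_offset_a=0.12), "lat")
        assert res.bias == pytest.approx(0.12, abs=0.02)

    def test_single_eye_rejected(self):
        with pytest.raises(ValueError):
            compare_modalities(_metrics_table(n_eyes=1), "init")

    def test_unmatched_eyes_listed(self):
        df = _metrics_table(n_eyes=4)
        df = df.drop(df[(df.eye_id == "E2") & (df.modality == "ipa")].index)
        with pytest.raises(ValueError, match="E2"):
            compare_modalities(df, "init")


class TestFisherCoverage:
    def test_ci_covers_true_correlation(self):
        """95% Fisher-z CI contains rho=0.9 in 93-97% of bivariate draws."""
        rho, n, draws = 0.9, 40, 500
        rng = np.random.default_rng(123)
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for _ in range(draws):
            x = rng.multivariate_normal([0, 0], cov, size=n)
            res = ols_and_pearson(_pairs(x[:, 0], x[:, 1]))
            hits += res.r_ci_low <= rho <= res.r_ci_high
        assert 0.93 <= hits / draws <= 0.97


class TestExactMomentHelper:
    def test_sample_has_requested_moments(self):
        rng = np.random.default_rng(0)
        x = exact_moment_sample(rng, 40, 4.055, 0.583)
        assert x.mean() == pytest.approx(4.055, abs=1e-12)
        assert x.std(ddof=1) == pytest.approx(0.583, abs=1e-12)
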