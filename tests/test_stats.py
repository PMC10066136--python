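"""Reliability statistics against independent oracles.

Every statistic is checked along a second, independent route: brute-force
ANOVA sums for the ICC, pingouin and scikit-learn for ICC/kappa, scipy for
t/OLS, and direct contingency summation for weighted kappa.
"""
import numpy as np
import pytest
from scipy import stats as sps

from alps_reorient.stats import (
    bland_altman,
    f_test_equal_variance,
    icc,
    ols_slope,
    paired_t,
    weighted_kappa,
)


def icc_anova_oracle(table, model):
    """Brute-force ICC from explicit group sums (independent of the package)."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in table)
    ss_cols = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x - grand) ** 2 for x in table.ravel())
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))
    if model == "oneway":
        return (msr - msw) / (msr + (k - 1) * msw)
    if model == "twoway_agreement":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_identical_columns_give_unity(self):
        table = np.column_stack([np.arange(6.0), np.arange(6.0)])
        for model in ("oneway", "twoway_agreement", "twoway_consistency"):
            assert icc(table, model).icc == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(11)
        table = rng.standard_normal((200, 2))
        assert abs(icc(table).icc) <= 0.15

    @pytest.mark.parametrize("model", ["oneway", "twoway_agreement", "twoway_consistency"])
    def test_matches_anova_oracle_on_random_tables(self, model):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            table = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
            assert icc(table, model).icc == pytest.approx(
                icc_anova_oracle(table, model), abs=1e-10
            )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(21)
        table = rng.standard_normal((12, 3)) + 2 * rng.standard_normal((12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": table.ravel(),
            }
        )
        pg = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                      ratings="score").set_index("Type")
        assert icc(table, "oneway").icc == pytest.approx(pg.loc["ICC(1,1)", "ICC"], abs=1e-9)
        assert icc(table, "twoway_agreement").icc == pytest.approx(
            pg.loc["ICC(A,1)", "ICC"], abs=1e-9
        )
        assert icc(table, "twoway_consistency").icc == pytest.approx(
            pg.loc["ICC(C,1)", "ICC"], abs=1e-9
        )

    def test_classification_bands(self):
        rng = np.random.default_rng(3)
        subj = 10.0 * rng.standard_normal((40, 1))
        table = subj + 0.01 * rng.standard_normal((40, 2))
        assert icc(table).classification == "excellent"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.ones((5, 2)))


class TestFTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = f_test_equal_variance(x, x)
        assert res.f_statistic == 1.0 and res.p_value == pytest.approx(1.0)

    def test_exact_variance_ratio(self):
        a = np.array([0.0, 2.0])   # var 2
        b = np.array([0.0, np.sqrt(2.0)])  # var 1
        res = f_test_equal_variance(a, b)
        assert res.f_statistic == pytest.approx(2.0, abs=1e-12)
        assert res.df == (1, 1)

    def test_symmetry_preserves_p(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(20), 2.0 * rng.standard_normal(25)
        fwd = f_test_equal_variance(a, b)
        rev = f_test_equal_variance(b, a)
        assert fwd.f_statistic == pytest.approx(1.0 / rev.f_statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)

    def test_power_at_cohort_scale(self):
        # n = 234 with a true variance ratio of 2.4: the test must reject at
        # p < 0.001 in at least 95% of replicates
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(500):
            a = np.sqrt(2.4) * rng.standard_normal(234)
            b = rng.standard_normal(234)
            res = f_test_equal_variance(a, b)
            hits += res.p_value < 0.001 and res.f_statistic > 1
        assert hits >= 475

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            f_test_equal_variance([1.0, 2.0], [3.0, 3.0])


class TestPairedT:
    def test_identical_pairs_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_balanced_differences_give_t_zero(self):
        d = np.array([0.5, -0.5, 0.5, -0.5])
        res = paired_t(d)
        assert res.t_statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_and_scipy(self):
        a = np.array([3.1, 2.7, 4.5, 3.9, 5.2])
        b = np.array([2.8, 2.9, 4.0, 3.1, 4.6])
        res = paired_t(a, b)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.t_statistic == pytest.approx(t_manual, rel=1e-12)
        ref = sps.ttest_rel(a, b)
        assert res.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_arithmetic_on_two_pairs(self):
        res = bland_altman(np.array([1.1, 0.9]), np.array([1.0, 1.0]))
        sd = np.std([0.1, -0.1], ddof=1)
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        assert res.loa_high == pytest.approx(1.96 * sd, rel=1e-12)
        assert res.loa_low == pytest.approx(-1.96 * sd, rel=1e-12)

    def test_plot_coordinates_follow_mean_difference_convention(self):
        a, b = np.array([2.0, 4.0]), np.array([1.0, 1.0])
        res = bland_altman(a, b)
        np.testing.assert_allclose(res.means, [1.5, 2.5])
        np.testing.assert_allclose(res.differences, [1.0, 3.0])

    def test_loa_covers_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(23)
        a = rng.standard_normal(10_000)
        b = np.zeros(10_000)
        res = bland_altman(a, b)
        inside = np.mean((a >= res.loa_low) & (a <= res.loa_high))
        assert 0.94 <= inside <= 0.96

    def test_doubled_difference_sd_doubles_loa_width(self):
        rng = np.random.default_rng(29)
        widths = {}
        for name, sd in (("x", 0.2), ("z", 0.1)):
            a = sd * rng.standard_normal(4000)
            res = bland_altman(a, np.zeros(4000))
            widths[name] = res.loa_high - res.loa_low
        assert widths["x"] == pytest.approx(2 * widths["z"], rel=0.1)


def kappa_contingency_oracle(r1, r2, weights):
    """Direct summation over the full contingency table."""
    k = int(max(r1.max(), r2.max())) + 1
    obs = np.zeros((k, k))
    for i, j in zip(r1, r2):
        obs[i, j] += 1.0 / len(r1)
    w = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
    if weights == "quadratic":
        w = w**2
    e = np.outer(obs.sum(1), obs.sum(0))
    return 1.0 - (w * obs).sum() / (w * e).sum()


class TestWeightedKappa:
    def test_perfect_agreement(self):
        grades = np.array([0, 1, 2, 0, 1, 2, 1])
        assert weighted_kappa(grades, grades).kappa == pytest.approx(1.0)

    def test_systematic_reversal_is_negative(self):
        r1 = np.array([0, 0, 1, 1, 2, 2])
        assert weighted_kappa(r1, 2 - r1).kappa < 0

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_contingency_oracle_and_sklearn(self, weights):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(31)
        r1 = rng.integers(0, 3, 60)
        r2 = np.clip(r1 + rng.integers(-1, 2, 60), 0, 2)
        res = weighted_kappa(r1, r2, weights=weights)
        assert res.kappa == pytest.approx(kappa_contingency_oracle(r1, r2, weights), abs=1e-12)
        ref = sklearn_metrics.cohen_kappa_score(r1, r2, weights=weights)
        assert res.kappa == pytest.approx(ref, abs=1e-12)

    def test_quadratic_two_categories_equals_unweighted(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(37)
        r1 = rng.integers(0, 2, 50)
        r2 = np.clip(r1 + rng.integers(-1, 2, 50), 0, 1)
        res = weighted_kappa(r1, r2, weights="quadratic", n_categories=2)
        assert res.kappa == pytest.approx(
            sklearn_metrics.cohen_kappa_score(r1, r2, weights=None), abs=1e-12
        )

    def test_paper_band_classification(self):
        rng = np.random.default_rng(41)
        r1 = rng.integers(0, 3, 200)
        assert weighted_kappa(r1, r1.copy()).classification == "very good"

    def test_constant_raters_rejected(self):
        with pytest.raises(ValueError, match="chance"):
            weighted_kappa([1, 1, 1], [1, 1, 1], n_categories=3)


class TestOlsSlope:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = ols_slope(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.p_value < 1e-10

    def test_matches_scipy_on_hand_set(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        res = ols_slope(x, y)
        ref = sps.linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, rel=1e-12)
        assert res.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_slope_distribution(self):
        rng = np.random.default_rng(43)
        slopes, pvals = [], []
        for _ in range(200):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100)
            res = ols_slope(x, y)
            slopes.append(res.slope)
            pvals.append(res.p_value)
        assert abs(np.mean(slopes)) < 0.03
        # p-values roughly uniform: around 5% below 0.05
        assert 0.0 <= np.mean(np.array(pvals) < 0.05) <= 0.12

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
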