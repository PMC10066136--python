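"""The reliability-statistics toolbox on small hand-made data.

Demonstrates ICC (with its classification bands), the variance-ratio F test,
Bland-Altman limits of agreement, weighted kappa for ordinal head-rotation
grades, and the OLS slope test.
"""
import numpy as np

from alps_reorient.stats import (
    bland_altman,
    f_test_equal_variance,
    icc,
    ols_slope,
    weighted_kappa,
)

rng = np.random.default_rng(0)

# two raters measuring 12 subjects with a little disagreement
truth = rng.normal(1.5, 0.2, size=(12, 1))
ratings = truth + rng.normal(0, 0.05, size=(12, 2))
res = icc(ratings)
print(f"ICC(2,1) = {res.icc:.3f} ({res.classification} reliability)")

a = rng.normal(0, 1.5, 200)
b = rng.normal(0, 1.0, 200)
f = f_test_equal_variance(a, b)
print(f"F test: F = {f.f_statistic:.2f}, df = {f.df}, p = {f.p_value:.2g}")

ba = bland_altman(ratings[:, 0], ratings[:, 1])
print(f"Bland-Altman: bias {ba.bias:+.4f}, LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]")

grades1 = np.array([0, 0, 1, 2, 1, 0, 2, 1, 0, 0])  # 0 neutral, 1 mild, 2 moderate
grades2 = np.array([0, 1, 1, 2, 1, 0, 2, 2, 0, 0])
k = weighted_kappa(grades1, grades2)
print(f"weighted kappa = {k.kappa:.3f} ({k.classification} agreement)")

age = rng.uniform(40, 90, 80)
alps = 2.0 - 0.008 * age + rng.normal(0, 0.1, 80)
ols = ols_slope(age, alps)
print(f"ALPS ~ age: slope {ols.slope:+.4f} per year, p = {ols.p_value:.2g}")
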