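"""Cohort experiment: does reorientation shrink the index variance?

Simulates a 30-subject cohort with mixed head poses (40% neutral, the rest
rotated 5-20 deg about x or z), per-subject physiological spread and SNR-30
Rician noise, then compares the variances of the original and reoriented
indices with the F test.  Takes a couple of minutes.
"""
import alps_reorient as ar
from alps_reorient.pipeline import EXPERIMENT_ACQUISITION

template = ar.build_template(acquisition=EXPERIMENT_ACQUISITION)  # 32x32x16 grid
result = ar.run_cohort(ar.CohortSpec(n_subjects=30, seed=7), template=template)

wide = result.table.pivot(index="subject", columns="variant", values="alps")
print(result.table.groupby(["group", "variant"]).alps.agg(["mean", "std", "count"]).round(4))
print(
    f"\nvar(original) = {wide['original'].var():.5f}   "
    f"var(reoriented) = {wide['reoriented'].var():.5f}"
)
print(
    f"F = {result.f_test.f_statistic:.2f} "
    f"(df {result.f_test.df}), two-sided p = {result.f_test.p_value:.2g}"
)
print(
    f"paired t on the means: t = {result.paired_t.t_statistic:.2f}, "
    f"p = {result.paired_t.p_value:.2g}"
)
print(
    "\nHead pose inflates the original index variance (rotation moves the"
    "\nindex by up to ~0.3); the reoriented variance is close to the pure"
    "\nphysiological + noise floor, so the F test rejects equality."
)
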