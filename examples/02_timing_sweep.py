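"""Sweep the second-scan timing over a 16-subject synthetic cohort.

For every dispersion delay d in 0..13.5 s (second scan at t_i/2 + d after
the trigger) the two-scan blood-flow estimates are correlated against the
maximum-slope reference, pooled over both tissues.  The optimum range is
the longest contiguous run of timings with r > 0.90 on ROI means and
r > 0.70 voxelwise.
"""

from ctfpa import optimum_delay_window, run_sweep, sample_cohort

cohort = sample_cohort(16, seed=0)
result = run_sweep(cohort)

print("timing   d (s)   r (ROI means)   r (voxelwise)")
rec = result.fpa1_record
print(f"{'peak':<9}{'-':<8}{rec.r_mean_rois:>10.3f}{rec.r_voxelwise:>15.3f}")
for rec in result.records:
    print(f"{rec.label:<9}{rec.d:<8.1f}{rec.r_mean_rois:>10.3f}{rec.r_voxelwise:>15.3f}")

print(f"\noptimum timings: {result.optimum_range}")
lo, hi = optimum_delay_window(result)
print(f"second-scan delay window after the trigger: {lo:.1f}-{hi:.1f} s")
print("COV across timings (circular ROIs):",
      {k: f"{v:.1f}%" for k, v in result.cov_circular.items()})
print(f"largest carcinoma-vs-parenchyma p value: {result.contrast.p_value.max():.2e}")
# High correlation at every in-window timing and a low COV mean the two-scan
# estimate is robust to the exact acquisition time; the tissue contrast stays
# highly significant throughout.
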