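"""Run the full automated AIF pipeline on a phantom and compare with truth.

Stages: motion correction -> heart detection (SD map + rank voting) ->
intensity correction -> ICA ventricle classification -> bright-pixel AIF
extraction -> timing points and quality metrics.
"""

from aifx import PhantomSpec, compare_aifs, generate_phantom, run_pipeline

series, truth = generate_phantom(PhantomSpec(seed=1))
result = run_pipeline(series)

r, nrmse = compare_aifs(truth.analytic_aif(), result.aif)
print(f"AIF from {int(result.aif.pixel_mask.sum())} bright LV pixels "
      f"(threshold {result.aif.threshold:.1f} a.u. at the "
      f"{result.aif.percentile:.0f}th percentile of the LV intensity range)")
print(f"vs ground truth: Pearson r = {r:.4f}, NRMSE = {nrmse:.2f} % "
      "(r near 1 and NRMSE of a few percent mean the automated curve "
      "reproduces the true bolus)")
tp = result.timing
print(f"timing points: baseline {tp.baseline_time:.1f} s, start {tp.start_time:.1f} s, "
      f"peak {tp.peak_time:.1f} s")
m = result.metrics
print(f"metrics: PV {m.pv:.1f} a.u., TTP {m.ttp:.1f} s, FWHM {m.fwhm:.1f} s, "
      f"upslope {m.upslope:.1f} a.u./s, M {m.m_value:.2f} a.u./s^2")
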