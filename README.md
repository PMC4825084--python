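# aifx — automated arterial input function measurement for perfusion CMR

Quantifying myocardial blood flow (MBF) from first-pass contrast-enhanced
perfusion cardiovascular MR requires the arterial input function (AIF): the
time–signal intensity curve of the gadolinium bolus in the LV blood pool.
Drawing the LV ROI by hand on 45–90 frames is slow and operator-dependent,
and including dark papillary muscles or partial-volume boundary pixels
biases the AIF peak downward — which biases MBF upward.  `aifx` implements
a fully automated AIF measurement pipeline for dynamic perfusion series
(dedicated low-resolution AIF series or standard myocardial series), plus
the downstream MBF quantification needed to study how the AIF ROI choice
propagates into flow estimates.

The pipeline:

1. **Motion correction** — frames are registered to a common
   maximal-intensity reference by composing pairwise subpixel
   phase-correlation estimates (optional optical-flow refinement).
2. **Heart detection** — a pixel-wise temporal standard-deviation map is
   thresholded at mean + 1σ (AIF series) or mean + 2σ (myocardial series);
   connected candidates are filtered (peak < 2× baseline, or peak in the
   first/last 3 frames, are dropped), split regions with curve correlation
   \> 0.75 at sub-radius distance are merged, and a linear rank-voting
   scheme over {area, PV, upslope, M, TTP, FWHM, distance-to-centre,
   distance-to-selected} picks the two ventricle regions and the heart
   bounding box.
3. **Intensity correction** — a polynomial surface fitted to the
   proton-density frames removes coil shading; the pre-contrast baseline is
   subtracted.
4. **Ventricular pixel detection** — ICA separates the RV and LV temporal
   sources from the candidate pixel curves (with a gamma-variate bolus-model
   refinement); every box pixel is Pearson-correlated with both sources and
   labelled RV/LV when the best correlation exceeds 0.7.  The
   earlier-peaking source is the RV.
5. **AIF extraction** — LV pixels whose temporal maximum (MIP) exceeds the
   75th percentile of the LV intensity *range* (`MIPmin + 0.75·(MIPmax −
   MIPmin)`) are averaged per frame; the curve is linearly resampled at
   0.5 s.  Timing points (baseline, contrast start, peak) and the quality
   metrics PV, TTP, FWHM, upslope and `M = PV / (TTP · FWHM)` are computed.
6. **MBF** — per-sector myocardial curves are deconvolved with the AIF
   under a Fermi-function constraint on the tissue impulse response R(t);
   flow is `R(0)` in ml/g/min.

A synthetic dynamic phantom (`aifx.phantom`) with exported ground truth —
true AIF, chamber/myocardium/papillary masks, motion schedule, shading
field and sector flows — validates every stage end to end.

## Worked example

```python
from aifx import PhantomSpec, generate_phantom, run_pipeline, compare_aifs

series, truth = generate_phantom(PhantomSpec(seed=1))
result = run_pipeline(series)
r, nrmse = compare_aifs(truth.analytic_aif(), result.aif)
print(f"r = {r:.4f}, NRMSE = {nrmse:.2f} %")
```

prints (see `examples/02_full_pipeline.py` for the full script):

```
AIF from 167 bright LV pixels (threshold 83.6 a.u. at the 75th percentile
of the LV intensity range)
vs ground truth: Pearson r = 0.9996, NRMSE = 1.39 %
timing points: baseline 3.5 s, start 8.0 s, peak 12.0 s
metrics: PV 99.9 a.u., TTP 4.0 s, FWHM 6.7 s, upslope 34.0 a.u./s, M 3.75 a.u./s^2
```

The extracted AIF reproduces the phantom's true LV bolus almost exactly;
the detected peak falls on the true analytic peak and the metrics describe
a sharp, high-amplitude input function — what a well-placed manual ROI
would measure, without the operator.

The `examples/` directory holds one short narrative script per capability
(phantom generation, full pipeline, MBF quantification, threshold
sensitivity, motion recovery).  A thin CLI wraps the same library calls:

```bash
aifx phantom generate --seed 4 --out ph/
aifx run --input ph/series.nii.gz --pd ph/pd.nii.gz --out-dir out/
aifx compare out/aif.csv other/aif.csv
aifx mbf --aif out/aif.csv --tissue tissue.csv --timing out/timing.json
```

`aifx run` writes `aif.csv`, `timing.json`, `metrics.json` and a QC overlay
figure, and exits with distinct codes for empty-candidate, ICA and timing
failures.

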