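# Methods

This note records the models, numerical choices and open design decisions
behind `aifx`, and what the synthetic phantom does and does not establish
about real data.

## The measurement problem

First-pass perfusion CMR acquires one short-axis frame per cardiac cycle
(R-R interval, here 1 s by default, 60 frames) while a gadolinium bolus
transits the heart.  Quantitative MBF needs the arterial input function —
the LV blood-pool time–signal curve — measured from bright cavity pixels
only: papillary muscles receive essentially no contrast and stay dark, and
boundary pixels mix blood with myocardium (partial volume), so including
either depresses the measured peak and upslope.  Because MBF estimation
divides the tissue response by the AIF, an underestimated AIF peak inflates
flow.  The pipeline automates the ROI choice that a careful operator makes
by hand.

## Pipeline stages and their numerics

**Motion correction.**  Frames are aligned to the frame of maximal total
intensity (near the LV bolus peak — the most feature-rich anchor).  Because
contrast wash-in violates brightness constancy across distant frames,
translations are estimated between *consecutive* frames (subpixel phase
correlation, upsampling factor 20, after Gaussian pre-smoothing with
`sigma_px = 1`) and composed to the reference.  The composition accumulates
a small random-walk drift, removed by a second pass of direct phase
correlation against the reference; direct corrections larger than 1.5 px
are rejected as false matches between dissimilar contrast states (the
residual after the chain is always small).  An optional iterative
Lucas-Kanade optical-flow refinement adds a non-rigid field; it is **off by
default** because bolus wash-in produces spurious flow inside the chambers
that degrades the temporal curves more than residual rigid error does.
Degenerate (constant) frames are skipped with a warning and an identity
field.  Displacement fields map corrected to original coordinates, so the
corrected series lives in the reference frame's coordinates; truth-mask
comparisons on phantoms map masks through the reference frame's known
displacement (`PhantomTruth.mask_in_frame`).

**Heart detection.**  The temporal standard-deviation map uses the
population (1/T) convention — at T = 60 the sample/population difference is
negligible, but one convention is fixed.  The binarisation threshold is
`mean + k·sd` computed over the *whole* map (k = 1 for the AIF series, 2
for the myocardial series); whether the original method restricted the
statistics to a foreground subset is unknown, and the whole-map reading is
the simpler one.  Components are 8-connected; regions below 4 px (AIF
series) / 16 px (myocardial series) are discarded because curve features on
tiny specks are unstable.  A candidate's "baseline intensity" for the 2×
enhancement filter is the mean of its first 3 frames (configurable; the
definition is otherwise unspecified).  In the rank voting, ties within a
feature share the average rank, which preserves the per-feature score sum
N(N+1)/2 and makes the vote invariant to candidate ordering; overall ties
break by larger M-value, then smaller distance to the image centre.  The
distance-to-selected feature participates only in the second voting round,
where it is defined.  Upslope is the maximum least-squares slope over a
sliding 3-sample (1 s) window between contrast start and peak.

**Intensity correction.**  A 2-D polynomial surface (default order 3,
falling back to lower orders on rank deficiency) is weighted-least-squares
fitted to the averaged PD image; pixels above the Otsu threshold weigh 1,
background 0.1 — a deliberate simplification of a hierarchical
foreground/background weighting scheme, recorded as this package's own
choice.  The surface is normalised to mean 1 over the heart box, so
correction never changes the global intensity scale, and division by a
time-constant surface preserves each pixel's temporal shape exactly.
Baseline frames default to those before the detected contrast start of the
whole-image mean curve, with the first 3 frames as fallback.

**Ventricular pixel detection.**  FastICA (fixed-point, whitened, 2
components, fixed seed, up to 5 retry seeds on non-convergence, candidate
mean curves as the final fallback) separates the RV and LV temporal
sources from the candidate pixel-curve matrix.  Decorrelation-based
separation has a structural limit here: the two bolus transits overlap in
time and are therefore *correlated*, while ICA outputs are constrained
uncorrelated, leaving a residual mixing ambiguity of a few percent.  The
default bolus-model refinement resolves it by refitting all candidate
pixel curves as non-negative mixtures of two gamma-variate transits
(shape parameters jointly optimised, per-pixel amplitudes solved linearly,
seeded from the ICA components).  If the two-transit bolus model leaves
more than 20 % relative residual — morphology far from a first pass — the
raw ICA components are kept instead.  Classification uses zero-lag Pearson
correlation ("cross correlation" read as the zero-lag coefficient) with
threshold 0.7, a fixed constant; zero-variance pixel curves get
correlation 0 and become background, so no NaN propagates.  The RV is the
earlier-peaking source; equal peak times raise an explicit ambiguity
error.

**AIF extraction.**  "Percentile of the maximal intensity range" is read
literally as `MIPmin + (q/100)·(MIPmax − MIPmin)` over the LV label map's
temporal maxima — the range reading, not the q-th order statistic (a
`mode="quantile"` switch exists).  The selected-pixel mean curve is
linearly interpolated onto a uniform 0.5 s grid with no extrapolation.
Timing points: the peak is the grid argmax; the baseline sample minimises
the summed absolute difference to its two neighbours before the point of
maximal intensity increase; the start is the curve sample geometrically
closest to the intersection of a least-squares line through the rising
flank (the contiguous run of forward differences above half the maximal
one) with the horizontal baseline level.  "Geometrically closest" is
evaluated in normalised coordinates (time over curve duration, intensity
over peak-minus-baseline) so the notion is scale-free; the normalisation
is this package's choice.  FWHM is measured at baseline + PV/2 with linear
interpolation; a missing right crossing clips at the series end and sets a
flag.  Curve similarity uses Pearson r and NRMSE = RMSE / range of the
reference curve, in percent.

**MBF.**  The tissue impulse response is constrained to a Fermi function
`R(t) = F·(1 + e^{−k·tau}) / (1 + e^{k(t − tau)})` with `R(0) = F` the
flow; this Fermi parameterisation is this package's model-constrained
deconvolution, the standard regularisation in quantitative perfusion CMR.
The discrete convolution uses the rectangle rule on the 0.5 s grid with
the step expressed in minutes, so the fitted amplitude is directly in
ml/g/min and the flow bound F ∈ [0, 10] ml/g/min is meaningful.  Timing
points are an explicit input (never re-detected inside the fit); baseline
levels are subtracted from the AIF and tissue curves and the fit runs from
the start time.  For fixed (k, tau) the model is linear in F, so a
deterministic grid over k ∈ {0.02…1.6} s⁻¹ × tau ∈ {0…6} s with
closed-form amplitudes seeds a bounded L-BFGS-B refinement; there is no
randomness in the fit.  Failed sectors carry NaN flow and a diagnostic
flag.  Homogeneity (scaling the AIF by c scales flows by 1/c) holds to
numerical precision.

## The phantom: what it emulates, and what it does not

`PhantomSpec` defines one synthetic study on a 48 × 64 grid (dedicated AIF
series geometry; 192 × 256 mirrors the myocardial series), 60 frames at a
1 s R-R interval.  Default conditions, chosen to look like a typical
clinical first pass: RV disc amplitude 80 a.u. with gamma-variate onset
4 s, shape α = 2.5, scale β = 1.8 s; LV disc amplitude 100 a.u. delayed by
4 s; myocardial annulus following the convolution of the true AIF with the
default Fermi response (k = 0.15 s⁻¹, tau = 3 s) at 1.1 ml/g/min per
sector; two papillary blobs (~1.2 px radius) at 15 % of the LV dynamics;
surrounding body tissue at 25 a.u. with smooth texture (the anatomy
visible before contrast, without which pre-contrast frames would be
unregistrable — real baseline frames show the chest);
multiplicative coil shading `1 + 0.35·x − 0.25·y` (range ≈ 0.75–1.35);
additive baseline offset 40 a.u.; respiratory-like sinusoidal translation
up to 1.5 px; additive Gaussian noise σ = 2 a.u. (Rician optional), an SNR
chosen to visually match typical series since no quantitative SNR is
published for either sequence.  Frame synthesis follows acquisition
physics: moving anatomy is shifted (bilinear), then multiplied by the
static shading field, offset, and corrupted by noise.  An optional
partial-volume rim replaces the outermost LV ring with a 50/50
blood/myocardium mixture for threshold-sensitivity experiments; rim pixels
are excluded from the true LV mask.  `random_spec` jitters geometry, bolus
timing/shape, noise, motion and shading within physiologically plausible
ranges for the validation batteries.

The phantom does **not** simulate MR signal physics (saturation recovery,
T1 saturation of the blood pool, surface-coil phase effects), recirculation
or contrast dispersion, through-plane motion, or realistic anatomical shape
variation.  Passing the phantom batteries therefore shows that the
algorithmic chain recovers what it is designed to recover under controlled
corruptions — it does not certify performance on clinical images, where
saturation and arrhythmia artefacts dominate the failure modes.

## Validation batteries and problem sizes

`aifx.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: 50 default-condition phantoms for AIF
fidelity (median r, median NRMSE); 100 randomized phantoms for detection
robustness (LV Dice > 0.5); 30 phantoms for papillary exclusion at the
75th percentile; 3 noiseless bolus parameter sets for timing accuracy
(peak against the analytic `t0 + α·β`, start against the same geometric
rule evaluated at 1 ms oversampling); 10 partial-volume-rim phantoms for
the threshold trend; 5 random 2×2 mixtures for ICA recovery; 5 phantoms
with ±4 px translation schedules for motion recovery; and 100 noisy
realisations each at 1.1 and 3.2 ml/g/min for flow recovery at 1 % tissue
noise.  These sizes give stable medians while keeping a full validation
run in the low minutes on a single core.

## Known limitations

- The registration is rigid by default; the elastic phantom mode is only
  checked for non-degradation (sharpness), not sub-pixel elastic recovery.
- The bolus-model ICA refinement assumes two-transit first-pass morphology;
  data dominated by recirculation would fall back to raw ICA components.
- The timing-point geometry assumes a single dominant peak; double-peaked
  or truncated curves raise timing errors rather than guessing.
- MBF units inherit the a.u. intensity scale of the AIF and tissue curves;
  absolute accuracy on real data additionally requires
  signal-to-concentration conversion, which is out of scope here.
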