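# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `bbbkit`. It is written for users who need to judge what the
package's validated behavior on synthetic data does and does not imply about
real recordings.

## Permeability indices from fluorescent angiography

### Clearance-integral PI (clearing tracers)

The clearing-tracer PI is the time average of the extravascular-to-vascular
intensity ratio over the clearance phase,
`PI = (1/T)∫ I_EV/I_VIF dt` on `[t_cr, t_end]`, computed by trapezoidal
quadrature on the native sample grid (no resampling). On smooth curves the
quadrature error is O(Δt²); at 1 Hz sampling of the analytic test curves it
is ~3×10⁻⁵, and proportional curves recover their ratio exactly.

**Clearance-window location.** `t_cr` is the first post-maximum sample at
which the smoothed VIF derivative has *settled* into the band (−1, 0]
a.u./s — operationally, the first in-band sample after the derivative's
last excursion below −1. The settling qualifier matters: the derivative
passes through the band momentarily at the peak itself before the steep
clearance drop, and taking that first crossing would start the window at
the bolus peak. The derivative is central differences on a moving-average
smoothed VIF. `find_clearance_window` defaults to a 5-sample average;
the end-to-end pipeline (`analyze_acquisition`) uses ~5 s of samples,
because at 5 frames/s a 1 s average leaves enough derivative noise to
jitter the crossing time by tens of seconds, while 5 s of smoothing is two
orders of magnitude below the clearance time constant (~100 s) and biases
the detected crossing by well under 1%. The band is applied to the curve in
its native intensity units; peak-normalization is available
(`normalize=True`) but makes the band degenerate for any physiological
clearance constant (the normalized derivative never leaves (−1, 0]).

**Pairing convention.** A baseline/post comparison of one imaged field is
scored with one segmentation and one clearance window, both determined on
the baseline acquisition (`trial_pi_shift`). The compartments and tracer
kinetics of a field do not change between acquisitions; re-estimating them
independently only injects segmentation and window jitter into the shift.
This mirrors analyst practice (one field, one vessel selection).

**Segmentation operators.** Median 3×3 noise filtration → adaptive local
threshold (Gaussian-weighted local mean over a 25-pixel window plus an
offset of 5% of the frame's dynamic range — a bright-object criterion;
document-binarization thresholds like Sauvola assume dark objects on light
background and reject bright vessels) → small-hole filling (≤16 px;
unrestricted hole filling swallows parenchyma islands enclosed by crossing
vessel branches) → speckle removal (<4 px). The extravascular mask excludes
a 2-pixel perivascular guard band: partial-volume boundary pixels whose
compartment assignment would otherwise fluctuate with noise. The
primary-vessel mask (largest connected component, or an explicit ROI
standing in for the protocol's manual selection) is eroded by 1 pixel so the
VIF samples the lumen core at undiluted amplitude — relevant because the
derivative band is in absolute a.u./s.

**Background subtraction.** The mean of the pre-injection frames is
subtracted before curves are formed; a residual offset δ on curves whose
denominator decays produces a time-varying bias δ/I_VIF, so the pipeline
uses all available pre-injection frames (default 2 s if the injection time
is unknown).

### Histogram-rank PI (accumulating tracers)

Per-compartment histograms use 64 equal-width bins spanning the pooled
0.5–99.5 percentile intensity range of both compartments (the raw min/max
ride on single extreme noise pixels and would jitter the bin grid between
acquisitions); empty bins are dropped before ranking. The weighted vectors
`x_i·f_i` (bin center × relative frequency) of the two compartments are
jointly ranked with average ranks, and the PI is the mean-rank ratio
EV/vessel. The statistic is invariant under joint positive rescaling of
intensities and, more generally, under any relabeling that preserves the
rank order of the weighted vectors; it is *not* invariant under affine
shifts, which reweight the products.

### Dysfunction classifier

`classify_exceedance` flags a shift strictly greater than
`sham mean + 3 × sham SD`, with the SD taken as the sample standard
deviation of per-trial sham shifts. Reported sham summaries of the form
"0.8 ± 1.86%" are ambiguous between SD and SEM conventions; this package
treats the spread parameter as the SD of the null, which is the reading
under which a ~18% stimulated shift exceeds a 3-SD threshold. A pixelwise
variant (`pixel_pi_map` + `pixel_bbbd_map`) applies the same rule per pixel
against a pixelwise null for overlay maps.

## ECoG spectral features

Traces are filtered with a 4th-order zero-phase (forward–backward)
Butterworth band-pass, 1–40 Hz. The PSD is estimated by Welch averaging
(2-s Hann segments, 50% overlap, Δf = 0.5 Hz), which for stationary signals
is the practical counterpart of Fourier-transforming the autocorrelation.
Features per interval: MSP (band-average PSD), dominant frequency (argmax
of the PSD, ties broken to the lowest frequency with a warning), and energy
(sum of squared samples; when intervals of unequal length are compared the
energy is normalized per unit time). Quiescence selection is automated —
the contiguous baseline window of the requested length minimizing the
variance of its 1-min sub-interval energies — standing in for manual
selection; baseline features use the whole window rather than averaging its
sub-intervals (the alternative changes results only at the estimator-noise
level). Percent shifts are computed per 1-min post-onset interval;
truncated final intervals are flagged.

## MRI detection

**Brain segmentation** thresholds on histogram supports: a central ellipsoid
seeds the brain histogram (lower support bound only, so hyperintense
pathology stays inside the mask), the outer 2-voxel border shell seeds the
peripheral histogram (excluded band), followed by largest-connected-
component cleanup.

**Rank criterion.** "Exceeds the control by MWU rank" is operationalized as
exceeding the q-th quantile (default q = 0.95) of the control distribution —
for the environmental criterion, the control's own distribution of 3×3
environmental means, so the smoothed statistic is compared against an
equally smoothed null. A per-voxel one-sided MWU test of the 9-sample
environment against the control (normal approximation, vectorized) is
available as `rule="mwu"`. The 3×3 environment is in-plane (8-neighbors +
self), masked to brain voxels.

**DCE regression** runs on the 6 post-contrast enhancement values against
scan index (dimensionless; acquisition intervals are metadata the model does
not need), slope units a.u./scan. p-values come from the slope t-statistic
with n−2 df; degenerate voxels get p = 1 (flat) or p = 0 (exact nonzero
line). Per-voxel p < 0.05 is applied without multiple-testing correction,
matching the per-voxel decision rule the classifier specifies; the BBBD
criteria are conjunctive (significance ∧ positive slope ∧ self rank ∧
environment rank), so loosening any one criterion can only grow the flagged
set. The contralateral T2 control region defaults to the hemisphere on the
low side of the sagittal split; pathology placed inside the control
hemisphere depresses sensitivity — supply an explicit control ROI in that
case. The muscle reference is an explicit ROI (phantoms generate it).

## Synthetic data: what it emulates, and what it does not

All validation runs on generated inputs with recorded ground truth;
every generator is a pure function of (seed, parameters) and emits a
manifest sufficient for bit-identical regeneration.

**Angiography** (`gen_angio_trial`): a branching vessel raster (random
walks, ~1–3 px half-width) on a 128×128 default grid (64×64 in the
recovery simulations; native 512×512 supported); a static log-normal
brightness texture (σ≈0.35, 3-px correlation) shared by both acquisitions
of a trial, representing vessel depth and parenchymal heterogeneity; VIF =
gamma-variate bolus rising to 200 a.u. at 15 s with exponential clearance
(τ = 100 s) for clearing mode, or a 150 a.u. plateau for accumulating mode;
frame rates 5/s and 1/s respectively. The extravascular signal is a
parenchymal bleed-through (8% of the VIF, Gaussian footprint σ = 4 px)
plus extravasation `k·∫VIF dt` with footprint σ = 6 px (clearing; a small
dye stays perivascular on this time scale) or σ = 14 px (accumulating; a
large protein diffuses). Gaussian pixel noise, SD 1.5 a.u.; dark level 5
a.u. A per-acquisition multiplicative drift (SD 0.8%) gives sham trials a
shift SD of ≈1.8 percentage points. The stimulated condition draws its
expected shift from N(17.9, 5.62)% and converts it to a leakage rate
analytically from the generator's own noiseless kinetics
(`k_for_shift`); measurement duration is 240 s in the recovery
simulations (clearance window T ≈ 150 s) and 300 s by default. Not
emulated: motion (frames are born registered; registration is validated
separately on injected shifts), photobleaching, vessel pulsation,
multi-layer vasculature.

**ECoG** (`gen_ecog`): 1/f-weighted noise plus an amplitude-modulated
10 Hz alpha oscillation at 200 Hz, 50 µV RMS; 15 min baseline + 35 min
post; depression window 15–30 min post-onset scales amplitude by √d so the
true power shift is exactly 100(d−1)%. Not emulated: spikes, movement
artifacts, electrode drift, non-stationary background spectra — so the
±3-point recovery demonstrated on this generator bounds estimator error,
not robustness to artifacts.

**MRI** (`gen_mri`): 64³ default grid; brain ellipsoid (intensity 100,
T2) inside a dark CSF-like gap and a bright scalp rim; Rician noise σ = 6
(T2) and σ = 0.5 (DCE). T2 lesion: sphere in the right hemisphere at +5
noise-SD contrast. DCE: brain washout enhancement 10·exp(−(j−1)/3) (fitted
slope negative), leak voxels `1.6·j` (≈3 SD above the observed muscle slope
distribution), muscle slopes N(0, 0.5). The stroke-like preset injects a
radius-8 lesion (≈6.6% of brain) and a radius-9 leak (≈9.4%). Not
emulated: bias fields, partial-volume gradients at tissue boundaries,
anatomical asymmetry (the mirrored-control assumption is exactly true in
the phantom and only approximately true in vivo).

## Numerical and policy choices

- Ties: average ranks everywhere (`scipy.stats.rankdata`).
- Two-sample tests: exact Mann–Whitney null for pooled n ≤ 25 without ties,
  normal approximation with tie correction otherwise; Wilcoxon signed-rank
  for paired data with zero differences dropped; an all-zero difference
  vector returns p = 1 by convention.
- The exceedance rule uses strict inequality; a zero-SD null warns and
  degenerates to comparison against the mean.
- Registration: translation-only phase correlation against the peak-filling
  frame (angiography) or scan 1 (DCE), linear-interpolation resampling;
  frames whose registration error exceeds 0.9 fall back to the identity
  with a warning, all-zero frames raise.
- Quadrature windows use a 10⁻⁹-relative tolerance at the edges so grid
  points generated by floating-point arithmetic are not dropped.
- Problem sizes in the test suite and acceptance script (64×64 angiography
  at 240 s, 64³ MRI, 100 trials per classifier condition, 25–50 ECoG seeds)
  are desk-scale choices: large enough that recovery rates and calibration
  are measured with useful precision, small enough to run routinely.

## Known limitations

- The manual steps of the original workflow (primary-vessel choice,
  quiescence selection, muscle ROI) are automated stand-ins; their
  selections are recorded in provenance but may differ from an analyst's.
- The histogram-rank PI is a coarse statistic: with narrow compartment
  distributions only a few bins are occupied and the index moves in
  discrete jumps; it should be read at the group level, not per trial.
- Per-voxel significance is uncorrected by default; the Benjamini–Hochberg
  option (`bbbd_detect(..., fdr_correct=True)`) changes the detector's
  operating point and is off unless requested.
- The sham-null classifier inherits whatever drift the sham trials contain;
  if sham acquisitions are unstable the 3-SD threshold widens and
  sensitivity drops.
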