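# Methods

`mepfm` implements a volumetric multi-echo resting-state fMRI analysis chain —
thermal-noise removal, T2* mapping and optimal echo combination, motion QC,
nuisance regression, functional connectivity, temporal SNR, and permuted
split-half reliability — together with a synthetic multi-echo BOLD generator
that provides ground truth for every stage. This note records the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic validation does and does not establish.

## Signal model and the synthetic generator

A gradient-echo voxel's magnitude at echo time TE follows a monoexponential
transverse decay,

    S(TE) = S0 · exp(−TE / T2*),

with T2* in ms throughout. BOLD activity enters as a modulation of the decay
rate, ΔR2*(v, t) = −A · z(net(v), t), where z are standardized latent network
time series with a prescribed covariance and A (`delta_r2s_amplitude`, default
0.2 s⁻¹) sets the fluctuation scale. To first order the fractional signal
change is TE·A·z, i.e. functional contrast grows linearly with echo time —
the property that both T2*-weighted combination and the echo-time dependence
of thermal-noise impact rest on. At the default A, a voxel at TE = 50 ms
fluctuates by about 1 %, a typical resting-state amplitude at 3 T.

Tissue presets give the per-age marginal T2* distribution (mean/SD in ms):
adult 48.89/12.23, child 59.34/13.96, infant 93.84/27.04. Maps are sampled as
Gaussian fields re-standardized after smoothing with a 1-voxel-SD kernel
(mild spatial autocorrelation; the marginal moments are preserved) and
clipped to [5, 200] ms. A subject's tissue maps are drawn once and shared by
all of that subject's runs; resampling them per run would let run-mean
offsets dominate any cross-run statistic.

The default network model partitions an ellipsoidal brain into a CSF shell, a
white-matter core, and a gray ribbon split into six slab networks. The
network correlation matrix is mixed-sign (paired couplings +0.6, −0.5, +0.3
and two weak ±0.2 cross-links). The sign mixture matters: with an all-positive
covariance, short-segment sample correlations all shrink toward a shared
positive pattern and split-half reliability becomes non-monotone in data
amount — an artifact of the generator, not of the estimator. Real
connectomes contain anticorrelations.

Noise and physiology per run: independent complex Gaussian thermal noise
with per-channel SD `thermal_sigma` (default 20 against S0 = 1000, i.e.
first-echo SNR ≈ 40) added to real and imaginary channels before the
magnitude is taken; a respiratory sinusoid (default 15 breaths/min, 1 % of
S0, smooth spatial phase); a linear drift (1 % of S0); and motion. Motion is
generated as parameter traces whose per-frame displacement deltas have L1
norm equal to a designed FD series — baseline jitter ~0.04 mm plus spikes of
0.6 mm with probability 0.05 per frame — so censoring logic can be verified
against exact ground truth. Spike frames also receive a transient signal
artifact (5 % of S0). Rigid-body resampling of the volumes themselves is not
simulated: the QC logic operates on FD, and that is what the synthetic data
exercise. Trailing noise frames (default 3) contain thermal noise only.
Phase is a smooth static spatial map; its role is to make the complex-valued
denoising path honest, not to model scanner phase dynamics.

What the generator does *not* emulate: spatially varying coil sensitivity
(g-factor), susceptibility dropout and distortion, slice timing, spatially
structured physiological noise beyond the single respiratory mode,
heteroscedastic motion artifacts, and surface geometry (published
"grayordinate" distributions are treated as in-mask voxel distributions).
Passing tests therefore establish internal correctness and the direction and
rough magnitude of method effects, not real-data performance figures.

## Thermal denoising

Each echo of each run is denoised independently. The complex volume
magnitude·exp(i·phase) is cut into overlapping cubic patches; each patch's
Casorati matrix (patch voxels × frames) is hard-thresholded in its singular
values at the level of the largest singular value a pure-noise matrix of the
same size would produce, and voxels are averaged over the patches covering
them (uniform weights by coverage count). The threshold is estimated by
Monte Carlo (default 10 seeded draws of an m×n complex Gaussian matrix) and
agrees with the asymptotic edge √2·σ·(√m+√n) to a few percent at the patch
sizes used; the analytic edge is kept as a cross-check in the tests, the
empirical edge is what the pipeline uses. Convention: σ is the per-channel
(real/imaginary) SD, so a complex matrix entry has SD √2·σ.

σ comes from the appended noise frames: pooled SD of real and imaginary
parts when phase is available, or √(⟨mag²⟩/2) (Rayleigh second moment) for
magnitude-only data. Without noise frames the caller must explicitly request
the theoretical fallback, 1/√2 times a robust SD of the darkest decile of the
mean image, recorded with `source="theoretical"`. Noise frames are never
denoised and never counted in tSNR. Magnitude-only denoising is supported
with a logged warning (the residual noise is then non-Gaussian) and flagged
in the QC sidecar.

Patch geometry defaults to the smallest cube with volume ≥ 11× the frame
count, stride half the patch edge; desk-scale analyses in the tests use
explicit 5³–6³ patches. A g-factor map, if supplied, pre-normalizes the data;
estimating one is out of scope.

A note on "smoothness": an ACF-based FWHM estimate on this synthetic rises
after denoising not because the method blurs, but because the raw estimate
is pinned at the one-voxel floor by the white thermal noise that denoising
then removes, leaving the intrinsically smooth simulated signal. The spatial-
precision guarantee is therefore tested directly — a single-voxel S0 impulse
retains its contrast through denoising — rather than via the FWHM difference.

## T2* mapping and optimal combination

Per voxel, ordinary least squares on log S̄(TE) against TE gives −1/T2* and
log S0; the fit uses the temporal mean per echo. Because magnitude noise is
Rician, the naive temporal mean acquires a floor that biases T2* upward once
late-echo SNR approaches 1; when a thermal-noise estimate is available
(automatically from noise frames) the fit instead uses the second-moment
corrected mean √(⟨mag²⟩ − 2σ²), which is exact on noiseless data and keeps
the median bias well under 3 % at first-echo SNR 10 with 200 frames. Echoes
whose corrected mean is non-positive are dropped from the tail
(`n_echoes_used`); voxels left with fewer than two usable echoes are flagged
invalid rather than raising. T2* is clipped to [2, 500] ms — wide enough to
cover the infant 95th percentile (~130 ms) with headroom while suppressing
log-fit blowups; zero-decay voxels land on the upper bound. R2* = 1000/T2*
(1/s).

Combination weights are the contrast-optimal

    w_e ∝ TE_e · exp(−TE_e / T2*),   Σ w_e = 1,

evaluated on the run-average T2* map (not per frame); invalid voxels fall
back to equal weights. At adult T2* the second and third echoes dominate; at
infant T2* the mass shifts to echoes 3–5. `weight_summary` tabulates
mean/median/SD/5th/95th percentiles of the voxelwise weights per echo.

## Motion QC

FD is the Power convention: sum of absolute backward differences of the six
rigid-body parameters, rotations × 50 mm head radius; frame 1 has FD = 0 and
is always retained. Thresholds are strict exactly as stated: censor FD > 0.3
mm for interpolation/run rules, FD > 0.2 mm for connectivity; runs qualify
for tSNR averaging at > 90 % retained, infant runs are excluded at < 30 %
retained. Respiratory band-stop filtering of the motion parameters is a
second-order zero-phase Butterworth notch with the band given in breaths/min
(÷60 to Hz); when the band reaches the Nyquist frequency of the TR — infant
respiration at 30–60 bpm against TR ≈ 1.5 s — the filter is skipped with a
logged reason rather than silently misapplied.

## Nuisance regression and connectivity

The confound model is the 36-parameter set: 6 motion parameters, mean
global/white-matter/CSF signals, backward-difference derivatives of those 9
(zero at frame 1), and squares of all 18. "Mean grayordinate signal" is
implemented as the mean over the analysis mask; the mask is configuration,
not a guess about any particular pipeline's grayordinate set. Cleaning runs
interpolate → filter → regress: frames censored at 0.3 mm are linearly
interpolated from the nearest retained neighbors (edges held) in both data
and confounds, a zero-phase Butterworth bandpass (0.009–0.08 Hz) is applied
identically to both, and voxelwise OLS residuals are returned with the mean
restored. Interpolating the confounds as well as the data is a deliberate
choice: a censored motion spike left in a regressor would leak through the
zero-phase filter into neighboring frames. Linear rather than spectral
interpolation is used for simplicity. Censored-at-0.2-mm frames are excluded
again when correlations are computed, so interpolated values never enter a
connectivity estimate.

Connectivity is Pearson correlation over retained frames, dense (every
in-mask voxel a node) or parcellated (label means first). Constant-series
nodes are flagged and zeroed, not NaN-propagated. Fisher z is available for
averaging/correlating matrices and is not used for displayed r values.

## Split-half reliability

Runs are split in half by run (the extra run of an odd count goes to the
held-out half), the run order is permuted (default 100×, seeded), and the
matrix from the first m minutes of retained frames (floor(m·60/TR) frames,
concatenated in permuted order, each run demeaned per node first) is
compared against the matrix from the entire held-out half. Reliability at m
is the mean over nodes of the Pearson correlation between corresponding
matrix rows, diagonal excluded, raw r by default with a Fisher-z variant
behind a flag. The curve reports mean ± SD across permutations. Absolute
values depend on how much held-out data anchors the curve; comparisons are
meaningful within a fixed split geometry.
`reliability_equivalent_minutes` inverts a curve by linear interpolation to
express one condition's reliability level in another's scan time.

## The conditions grid

`run_pipeline` reproduces the standard 2×2 comparison — single-echo vs
multi-echo × raw vs denoised — on one synthetic subject. The single-echo
condition uses TE = 37 ms with the same TR and the same latent
network/motion/tissue realizations as the multi-echo condition, so contrasts
isolate acquisition and denoising effects; matching TR (unlike typical
real-protocol pairs) keeps minutes-based reliability comparisons clean.
Desk-scale defaults: 24³ voxels, 4 runs × 120 frames (≈3.5 min at
TR 1.761 s), 25 permutations, parcel (network-level) reliability nodes.
Expected orderings on this grid: denoising raises mean gray-matter tSNR
within each acquisition, and denoised multi-echo reliability exceeds raw
single-echo at every matched data amount. Because the synthetic single-echo
condition sits near the adult optimum TE with matched TR, its denoised tSNR
can exceed the multi-echo condition's — the multi-echo benefit here shows in
functional contrast and reliability, not necessarily in raw tSNR.

## tSNR and smoothness

tSNR is the voxelwise temporal mean over temporal SD on un-censored signal
frames; zero-variance voxels are flagged undefined and excluded from
summaries. Run averages use the > 90 % low-motion rule; summary SD is across
voxels (brain locations), not runs. Percent difference is directional:
100·(after − before)/before, 2 decimals.

Smoothness uses a Gaussian-only ACF model (no mixed exponential+Gaussian
term): lag-1 neighbor correlation of linearly detrended residuals per axis,
interpreted as the ACF of Gaussian-smoothed white noise, r(d) =
exp(−d²/4σ²), yielding the kernel-equivalent FWHM = √(8 ln 2)·σ (Forman
convention — the ACF width is √2× the kernel width, and the reported number
is the kernel's). Estimates are floored at one voxel, the sampling
resolution; `smooth_to_fwhm` adds σ in quadrature using the unfloored
estimate and reaches targets within ~10 %. The numbers are comparative
between conditions, not calibrated against any external smoothness tool.

## Numerical conventions and degenerate inputs

Units: TE and T2* in ms, TR in s, rates converted bpm→Hz as ÷60, FD in mm,
R2* in 1/s. All randomness flows through seeded `numpy` generators; identical
seeds give bit-identical outputs everywhere. Degenerate cases are explicit:
zero-variance noise frames raise; all-censored runs raise; constant
connectivity nodes are flagged; unreachable reliability grid points are
dropped with a warning; empty run selections warn and return empty.

## Problem sizes used in validation

Test and acceptance runs use 12³–24³ grids, 60–400 frames, 2–4 runs, and
25–50 permutations; the large-sample oracles use up to 10⁴ frames (voxel
grids) or 6×10⁴ frames (latent series). These sizes were chosen so each
check's sampling error is well inside its asserted tolerance.
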