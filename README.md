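# mepfm

Multi-echo BOLD fMRI analysis for precision functional mapping: NORDIC-style
thermal-noise removal, voxelwise T2* mapping with T2*-weighted optimal echo
combination, framewise-displacement motion QC, 36-parameter nuisance
regression, dense and parcellated functional connectivity, temporal SNR, and
permuted split-half reliability — plus a synthetic multi-echo generator with
full ground truth, so the whole chain is verifiable without scanner data.

## Who this is for

Researchers doing individual-level ("precision") resting-state fMRI,
particularly in developmental populations where scan time is scarce and
signal properties differ sharply from adults: infant cortical T2* is both
much longer (≈94 ms vs ≈49 ms at 3 T) and more variable, which changes which
echoes of a multi-echo acquisition carry the most BOLD contrast.

## The core models

**Decay and combination.** A voxel's signal decays monoexponentially across
echo times, S(TE) = S0·exp(−TE/T2*). Fitting log S̄(TE) by least squares per
voxel gives T2* and S0 (with a Rician noise-floor correction when a thermal
noise estimate is available). Echoes are then averaged with the
contrast-optimal weights

    w_e ∝ TE_e · exp(−TE_e / T2*),  normalized to Σ w_e = 1,

which peak near TE ≈ T2*: late echoes dominate in infants, middle echoes in
adults. R2* = 1/T2* is exposed as an iron-sensitive tissue measure.

**Thermal denoising.** Each echo's complex-valued series (magnitude + phase)
is split into overlapping patches; each patch's voxels-by-frames Casorati
matrix is hard-thresholded in its singular values at the level a pure-noise
matrix of that size would reach (Monte-Carlo estimate of the edge
√2·σ·(√m+√n), σ estimated from appended noise-only frames, or 1/√2 of a
robust signal estimate as fallback). Components indistinguishable from
zero-mean thermal noise are removed; structured signal is untouched, so tSNR
rises without spatial smoothing.

**QC, cleaning, reliability.** FD = Σ|Δtrans| + 50 mm·Σ|Δrot| with strict
censoring at 0.2 mm (connectivity) and 0.3 mm (interpolation, run rules:
runs > 90 % low-motion qualify for tSNR averaging, infant runs < 30 %
retained are excluded). Cleaning regresses the 36-parameter confound set
after identical bandpass filtering (0.009–0.08 Hz) of data and regressors.
Split-half reliability permutes run order (default 100×), grows one half in
minutes of retained data against the full held-out half, and reports the
mean per-node correlation of connectivity-matrix rows.

## Worked example

```python
import numpy as np
import mepfm as m

acq = m.AcquisitionParams(echo_times=(14.2, 38.93, 63.66, 88.39, 113.12),
                          n_frames=120, grid_shape=(16, 16, 16), n_noise_frames=3)
net = m.make_network_model(acq.grid_shape)
series, motion, truth = m.simulate_run(
    acq, m.TISSUE_PRESETS["infant"], net, m.NoiseAndMotionModel(), seed=0)

sigma = m.estimate_noise_sigma(series)
den, qc = m.nordic_denoise_run(
    series, m.PatchConfig(patch_shape=(5, 5, 5), stride=3, seed=0), sigma)
t2map = m.fit_t2star(den, mask=net.brain_mask)
gm = net.gray_mask
print(f"thermal sigma: {sigma.sigma:.2f} ({sigma.source})")
print(f"median gray-matter T2*: {np.median(t2map.t2star[gm]):.1f} ms "
      f"(truth {np.median(truth.t2star_map[gm]):.1f} ms)")
print(m.weight_summary(t2map, acq.echo_times, mask=gm).round(3))

combined = m.optimal_combine(den, t2map)
fd = m.framewise_displacement(motion)
print(f"retained {m.censor(fd, 0.3).pct_retained:.1f}% of frames at FD 0.3 mm")
print(f"mean gray-matter tSNR: {m.tsnr_map(combined).values[gm].mean():.1f}")
```

Output:

```
thermal sigma: 19.96 (noise_frames)
median gray-matter T2*: 100.2 ms (truth 100.0 ms)
              T2*     e1     e2     e3     e4     e5
mean      101.515  0.087  0.183  0.232  0.250  0.249
median    100.153  0.085  0.181  0.232  0.251  0.251
SD         20.590  0.012  0.014  0.005  0.009  0.022
5th pct    69.291  0.072  0.165  0.225  0.233  0.209
95th pct  137.195  0.109  0.209  0.240  0.261  0.278
retained 95.8% of frames at FD 0.3 mm
mean gray-matter tSNR: 37.8
```

The noise estimate recovers the generator's σ = 20 from the three appended
noise frames; the denoised T2* map recovers the infant preset's median to
0.2 %; and the weight table shows the infant signature — echoes 3–5 carry
the heaviest weights, with echo 1 down near 0.09. On an adult preset the
same table peaks at echoes 2–3 instead.

The conditions-grid experiment (single-echo vs multi-echo × raw vs denoised
on one synthetic subject) runs end to end with

```bash
mepfm run --seed 1 --out results/grid
```

writing tSNR tables, per-condition reliability curves, echo-weight
summaries, and a JSON provenance file. `mepfm simulate`, `denoise`, `t2map`,
`combine`, `qc`, and `fc` expose the individual stages on NIfTI/TSV files.

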