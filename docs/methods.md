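# Methods

## Signal model

An MRF-EPI slice acquisition plays `n = 35` spoiled gradient-echo readouts
with a per-time-point flip angle, echo time and repetition time.  Under
ideal spoiling (no transverse coherence survives a TR) the signal of a
tissue with longitudinal relaxation time T1, effective transverse
relaxation time T2\* and flip-angle efficiency B1+ follows the recursion

    alpha_i  = B1+ * FA_i
    s_i      = Mz_i * sin(alpha_i) * exp(-TE_i / T2*)
    Mz_{i+1} = M0 + (Mz_i * cos(alpha_i) - M0) * exp(-TR_i / T1)

starting from thermal equilibrium `Mz_0 = M0`.  Magnitude signals are
returned; a single pass through the schedule is simulated (an optional
`n_prep_cycles` replays the schedule before recording for steady-state
variants, off by default).  The per-time-point schedule values are not
standardized; the default schedule linearly ramps FA 34->86 deg, TE
21->81.5 ms and TR 3530->6570 ms over the 35 points, and site-specific
schedules can be loaded from a 3-column text file.

A consequence of second-scale repetition times worth stating explicitly:
for T1 much shorter than TR the magnetization recovers essentially
completely between excitations, so fingerprints become independent of T1.
Numerically, 2%-spaced T1 neighbours below ~500 ms are identical to
float64 resolution under the default schedule, while neighbours at
500 ms and above are separated by 1-cos of 1e-11 or more.  All
reduced-scale studies in this package therefore use T1 grids starting at
500 ms (see "Problem sizes" below); the full 100-4000 ms grid remains the
configuration default for dictionary generation.

## Dictionaries, matching and noise

Dictionaries enumerate a geometric T1 grid x geometric T2\* grid
(constant fractional increment, 2% default, starting exactly at the lower
bound) x a linear B1+ grid (0.6-1.4, step 0.05 default), excluding
non-physical entries with T1 < T2\*.  Every fingerprint is stored
L2-normalized, making inner-product matching equivalent to cosine
similarity; argmax ties break toward the lowest row index for
determinism.  Voxels outside the brain mask, and zero-norm voxels, are
written as 0 (index -1) and counted.

The per-voxel SNR follows `10*log10(sum s_i^2 / sum n_i^2)` where `s` is
the *matched* dictionary fingerprint — the matched entry is treated as the
noise-free version of the scan — and `n` is the residual between the
normalized scan signal and that entry.  The same convention is applied
before and after denoising, so the denoising gain is measured exactly as
the reference reconstruction would see it.  Residual vectors pooled over
voxels form the noise bank; because the temporal order of a residual
carries no information for this purpose, sampling from the bank either
draws scalars i.i.d. from the pooled amplitudes (`pooled_iid`, default)
or draws a stored row and permutes its order (`permuted_vector`).

## Stage I: residual-learning denoiser

A 1D DnCNN predicts the noise component of a fingerprint; subtracting the
prediction denoises it.  Architecture: conv(k=3, pad=1, 64 ch) + ReLU,
32 middle units of conv + batch norm + ReLU, and a final conv to one
channel.  The final layer starts at zero so the untrained model is the
identity denoiser.  Training corrupts each unit-norm dictionary
fingerprint with a freshly sampled bank residual every epoch, minimizes
`10000 * MSE(true residual, predicted residual)`, and keeps the epoch
checkpoint with the lowest *training* loss (no validation split is used
for stage I; model selection on training error is deliberate and mirrors
the reference workflow, but is unconventional and worth knowing about).
Batch-norm inference uses running statistics frozen at the selected
checkpoint.

## Stage II: pyramidal dual-path attention regressor

A shared backbone of three valid (no padding, stride 1) convolution
blocks — kernels 17/11/7, channels 128/256/512, each followed by ReLU and
dropout p=0.2 — turns a 35-point fingerprint into pyramid scales of
length 19, 9 and 3.  Two independent paths (T1 and T2\*) each tap all
three scales.  Per scale and path: multi-head self-attention (8 heads,
per-head d_s = channels/8, contiguous channel slicing, scaled dot-product
`softmax(Q K^T / sqrt(d_s)) V`, concat + output projection), a gated
residual `Y = gamma * Xa + X` with the scalar `gamma` learned from an
initial value of 0 (the attention branch starts closed, so at
initialization the network is exactly its attention-free counterpart),
then flatten -> FC(128) -> ReLU -> FC(3).  The three per-scale 3-vectors
are combined as `sum_i gamma_i X_i` with per-scale weights initialized to
1/3 (an average, so the signal path is never zeroed), and a final FC(3->1)
emits the relaxation time in milliseconds.  Targets are regressed in raw
ms; the loss `mean|y - yp| + 100 * mean(|y - yp|/y)` balances the
kilo-scale T1 against the tens-scale T2\* through its relative term.

Ablation variants: PDCNN removes attention and all gammas (plain sum over
scales); DCNNkeeps only the third scale; SCNN is DCNN with a single path
whose final FC emits both values.  Whether the two paths share attention
weights is an open design point; they are independent here.

Training uses clean dictionary fingerprints as inputs, selects the
checkpoint with the lowest validation loss (dropout disabled during
evaluation), and records L1 and MAPE per epoch for both splits.  For the
two-stage predictor the stage-I weights are frozen and voxel fingerprints
are normalized, denoised, then regressed.

Two conditioning measures matter at this scale.  First, unit-norm
fingerprints vary by only ~1% along T1, so inputs are standardized per
time point (center/scale fitted on the training split and stored with
the model); the scale is floored at 0.5x the largest per-time-point
spread, because unfloored scales amplify residual measurement noise on
low-variance time points by two orders of magnitude and make the
clean-trained network collapse on denoised scans (the floor improved
both clean interpolation error and noisy-phantom error in the
calibration runs).  Second, each path's output bias initializes to the
mean training target, and predictions clamp to the training target range
at inference — like the matcher, the regressor cannot return
out-of-dictionary values.

## Synthetic phantom

The phantom arranges concentric smoothed ellipses — CSF ventricle core,
WM interior, GM cortical ribbon — plus round lesions placed only inside
WM, on a grid of at least 16x16 (default 32x32).  Per-voxel truth is
drawn from tissue-specific normal distributions; defaults are typical 3T
values for GM/WM/CSF and MS lesions (T1 1286/825/3003/1284 ms, T2\*
53/54/268/86 ms, with the corresponding reported spreads), clipped to the
dictionary ranges and constrained to T2\* <= T1.  B1+ is uniform 1.0 by
default; a smooth low-order cosine field (peak deviation 10%) is
available.  Rendering simulates each voxel, normalizes, and adds noise
calibrated so the expected residual energy matches a target SNR (default
21.78 dB, the reported whole-brain testing value of the emulated
acquisition); Gaussian, heavy-tailed Student-t (dof 5) and empirical-bank
noise models are provided.  What the phantom does *not* emulate: EPI
distortion, coil sensitivity, partial-volume mixing at tissue borders,
spatially correlated noise, and the slice-to-slice schedule differences
of a real acquisition — so passing phantom tests demonstrates the
correctness of the reconstruction machinery, not clinical performance.

## Problem sizes and optimizer settings at desk scale

The reference workflow trains on 598,842-entry dictionaries (about 1,200
Adam steps per epoch at batch 500) for 60 slices.  This package's tests
and acceptance studies run one synthetic slice at reduced scale, chosen
once as follows:

- Reduced 2% dictionary: T1 500-2500 ms x T2* 30-300 ms, B1+ = 1.0
  (9,594 entries) — the well-encoded region containing all phantom
  tissues except CSF.
- Stage-I training dictionary: same ranges at 4.5% increment
  (1,961 entries ~ "2,000 signals"), synthetic Gaussian bank at 20 dB;
  batch 25, lr 0.005, 30 epochs (2,400 steps — preserving the order of
  magnitude of reference steps rather than the batch size).
- Stage-II: interval-2 split of the reduced 2% dictionary (2,419 training
  entries); batch 100, lr 0.02, 60 epochs (1,500 steps), with a
  1,000-entry validation subsample for per-epoch checkpoint selection.
- Extrapolation study: 6% dictionary over the full T1/T2* ranges with the
  500-2500 / 50-1500 ms training box (1,453 in-box training entries).
- End-to-end: 32x32 phantom at 20 dB Gaussian noise.

Numerical choices: float32 for network training, float64 for simulation,
matching and metrics; matching processes dictionaries in 20,000-row
blocks with strict-improvement updates so ties keep the lowest row index;
SNR returns +inf for zero residuals; MAPE requires strictly positive
references; the ICC is the two-way random-effects, absolute-agreement,
single-measure form (ICC(A,1)) by default, with the form configurable
because the emulated analysis does not pin it down; Bland-Altman
statistics are computed voxelwise (difference = reference - prediction),
with the correlation flagged NaN for degenerate series.

## Known limitations

- The Bloch model ignores slice profiles, preparation pulses,
  magnetization transfer and flow; with second-scale TRs it cannot
  encode T1 below ~500 ms (see above).
- The entry count of a full-scale per-slice dictionary depends on
  slice-specific schedule details that are not standardized here; grid
  conventions are configurable and no particular count is assumed.
- Stage networks are trained on one synthetic slice; nothing is claimed
  about transfer across slices or scanners.
- Training runs single-threaded on CPU; the implementation favours
  reproducibility (fully seeded, bit-deterministic inference) over speed.
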