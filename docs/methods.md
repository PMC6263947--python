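# Methods

## Problem and pipeline

`eecgnet` performs closed-set biometric identification from ECG: given
records from a known set of subjects, assign each held-out record to its
subject. The pipeline has three parts — beat-image construction, an
eigen-filter-bank feature network, and a linear classifier — plus baselines
and a synthetic cohort generator that makes every stage testable without
clinical data.

## Synthetic cohort generator

Each subject is a `SubjectTemplate`: five Gaussian bumps (P, Q, R, S, T)
with centers (seconds relative to the R peak), amplitudes (mV) and widths
(seconds) drawn uniformly from fixed physiological-looking ranges, e.g. the
R amplitude from 1.1–1.8 mV, the mean RR interval from 0.7–1.0 s (60–86 bpm)
with 0.02 s Gaussian beat-to-beat jitter. The R range strictly dominates the
other amplitude ranges, so the R peak is always the largest positive
deflection and peak detection is well posed. A record is the sum of the
per-beat Gaussians at jittered beat times (the first R sits at RR/2 so a
duration of `k·RR` holds `k` whole beats), plus three artifact classes:
sinusoidal baseline wander (default 0.1 mV at 0.25 Hz), white noise (default
0.05 mV sd, ~3–5% of the R amplitude), and sparse ±0.5 mV spikes at 0.1/s.
Two cohort shapes are emulated: one lead at 500 Hz and two leads at 360 Hz.
The second lead is the clean wave train rebuilt with the P and T components
inverted and scaled 0.6×, plus its own independent noise: a plain global
sign flip would invert the R peak and contradict the per-lead peak-detection
contract, while flipping only the low-amplitude waves preserves QRS polarity
and still gives imperfect inter-lead correlation.

What the generator does *not* emulate: arrhythmia and disease morphologies,
respiration coupling, electrode-motion artifacts with realistic spectra,
within-subject morphology drift across sessions. Passing tests therefore
show the pipeline's algebra and its robustness to stationary additive noise,
not performance on clinical recordings.

Splits are alternating by record index within subject (even → train), so the
split fraction is exactly 0.5 and deterministic. All draws flow from a
single integer seed through `numpy.random.default_rng`.

## Preprocessing

Per lead: (1) subtract a width-500 centered moving average (baseline
estimate); (2) smooth with a width-10 moving average; (3) detect R peaks as
local maxima at ≥ 0.5 of the global maximum, greedily keeping the larger of
any two candidates within a 0.3 s refractory window (earlier index wins
ties; the global maximum is always kept); (4) average the 400-sample windows
centered on each peak (window/2 samples before the peak, remainder after;
boundary-crossing peaks discarded); (5) concatenate the per-lead averages,
linearly resample to the target length (784 → 28×28 for one-lead cohorts,
1600 → 40×40 for two-lead ones) and normalize to zero mean and unit max-abs.

Numerical choices: moving-average edges use truncated (shrinking) windows
rather than zero padding, which would fabricate edge transients in the
baseline estimate; even widths put the extra window sample after the center;
the resampling is linear interpolation (the length contract is exact by
construction); normalization is optional (`normalize=False`) because the
classifier can scale.

## The filter-bank network

Stage 1 extracts every `k1×k2` patch of every zero-padded training image
(one patch per original pixel), removes each patch's own mean, and takes the
top-`L1` eigenvectors of the pooled scatter matrix as convolution kernels.
Stage 2 repeats the construction on all `N·L1` stage-1 maps, yielding one
bank of `L2` kernels shared across channels. The output stage binarizes
(Heaviside, with H(0)=0) and collapses the `L2` maps per channel into one
integer image with weights `2^{ϑ-1}`, slides `h1×h2` blocks at stride
`round((1−R)·h)` (round-half-up, floored at 1), and histograms each block
over `2^{L2}` bins; features are raw counts, concatenated block-major then
channel-major, length `(2^{L2})·L1·B`, summing to `L1·B·h1·h2`.

Pinned conventions (all observable, all tested):

- Patch and block vectorization is column-major within the patch; kernels
  are reshaped with the inverse map, so the pair is consistent.
- Convolution is true 2-D convolution (kernel flipped), zero-padded to
  "same" size; the delta-kernel identity test pins this jointly with the
  vectorization order.
- Each eigenvector's sign is fixed so its largest-magnitude coefficient is
  positive — deterministic across linear-algebra backends. Exact eigenvalue
  ties are broken by a stable sort and are documented as unstable.
- Scatter matrices are accumulated per image (`Σ X̄X̄ᵀ`), algebraically
  identical to the pooled-matrix eigenproblem but without materializing the
  `k1k2 × Nmn` pool.
- The block count is computed on the decimal image's actual dimensions; by
  default (`pad_before_blocks=True`) the decimal image is first zero-padded
  by `(k−1)/2` per side so the count follows the padded-grid arithmetic
  `B = (1+⌊(m+k1−1−h1)/stride⌋)·(1+⌊(n+k2−1−h2)/stride⌋)`. The bracket is
  read as floor (the only reading for which every counted block fits) and
  stride 0 is meaningless, hence the floor at 1.
- A degenerate training set whose patch scatter is zero after mean removal
  (e.g. a single all-zero image) raises an error rather than returning
  arbitrary kernels. Note a *nonzero* constant image is not degenerate: its
  zero-padded border patches still carry variance.
- Patch dims must be odd (required for the symmetric zero-padding and the
  centered kernel identity); the sweep harness skips even-`k` grid points
  with a logged reason.

Defaults `k1=k2=7, L1=L2=8, h1=h2=7, R=0.5` give `B=49` on a 28×28 image
and a feature length of 100352. Features are returned as a sparse CSR
matrix: at `2^{L2}=256` bins most counts are zero (~6% density at the
defaults).

## Classifier and baselines

The classifier contract is a multi-class linear max-margin model
(one-vs-rest, `C=1.0` default), satisfied by `sklearn.svm.LinearSVC` with a
pinned random state; the ~10^5-dimensional histogram features make kernels
redundant. Features are passed unscaled (raw counts) by default.

Baselines consume the 784-sample averaged-beat vectors directly:

- **eigen-PCA** — mean and eigenvectors estimated on the training split
  only; both splits projected on the top components (default 40) and fed to
  the same linear classifier.
- **ELM** — input weights and biases uniform(−1,1) from a seed, activation
  in {sigmoid, relu, sin}, minimum-norm least-squares readout to one-hot
  targets. Hidden width defaults to 1000 (unstated in the problem
  definition; exposed in config).
- **EELM** — one ELM per (seed × activation), majority vote, ties to the
  lowest class id, minimum 3 members.

Identification accuracy is `100·correct/total`; per-class one-vs-rest
(TP, TN, FP, FN) tables are emitted alongside, and micro-averaged OvR
recall/precision reduces to the same number on single-label data.

## Fidelity metrics

For an original `Xs` and reconstruction `Xr`: `CR = B0/Bc`,
`PRD = 100·√(Σ(Xs−Xr)²/ΣXs²)`, `PRDN` with the mean-removed denominator,
`RMS = 100·√(Σ(Xs−Xr)²/(N−1))`, `SNR = 10·log10(Σ(Xs−X̄)²/Σ(Xs−Xr)²)` dB
(base-10 is the dB convention and the only reading for which the
(1,−1)/(0,0) case gives exactly 0 dB). Degenerate denominators raise
errors, never infinities.

## Problem sizes and design scope

The end-to-end checks use 20-subject × 20-record cohorts of 10 s records at
500 Hz with the default noise model, median over 5 seeds — large enough that
chance is 5% and a defective stage is unmistakable, small enough to run
interactively. Unit tests use 6–8 subject cohorts. The WFDB reader is
read-only and minimal (header + signal formats 212 and 16-bit), sufficient
for MIT-BIH-style fixtures; annotation files, multi-file records and live
acquisition are out of scope, as are LDA/CCA/quaternion filter-bank
variants, more than two stages, and learned (backpropagated) kernels.

Known limitations: on easy synthetic cohorts all methods saturate at 100%,
so ordering comparisons among them are tie-heavy; the one-lead 784-sample
target length is produced by resampling the 400-sample averaged beat, one of
several defensible readings of "connecting" lead averages, kept behind a
single parameter (`target_len`); and the generator's noise is stationary, so
robustness results do not transfer to non-stationary clinical artifacts.
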