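# Methods

This note records the models, parameter choices and numerical decisions
behind `jwave`, and what the synthetic validation does and does not
establish.

## Synthetic ECG model

Each beat is a sum of Gaussian bumps — one per P, Q, R, S, T wave, each
parameterized by (amplitude mV, offset s relative to the R center, width
s as a Gaussian SD).  Defaults (P 0.12 mV @ −170 ms, Q −0.08 @ −25 ms,
R 1.10 @ 0, S −0.22 @ +25 ms, T 0.30 @ +300 ms) give a plausible lead-II
morphology.  A J-wave-positive beat adds one more bump of 0.15 mV
(log-normal spread across records), centered 50 ms after R with a 12 ms
SD — consistent with the clinical picture of a 0.1–0.2 mV deflection on
the terminal QRS downslope, 40–60 ms after the R peak and 8–15 ms wide.
These J parameters are stipulated, not fitted: no public cohort
documents the amplitude/duration distribution, so they are fixed once
and treated as the study condition.

The R peak sits at 35% of each RR interval.  For cycles shorter than
0.9 s the P and T offsets are compressed proportionally (a crude
rate-dependent PR/QT shortening) so beats always decay to baseline at
their edges.  Records concatenate beats with RR drawn as
(60/HR)·(1 + 0.05·N(0,1)), clipped to 0.4–2.0 s; record mean heart rates
are drawn N(60, 5) bpm.  The record mean is subtracted (AC-coupled
acquisition — real ECG front-ends carry no DC), then three artifact
terms are added: baseline wander (0.05 mV sine at 0.25 Hz, random
phase), powerline interference (0.02 mV at 50 Hz) and white noise
(0.02 mV SD).  Noise defaults are small enough that R-detection recall
on denoised records stays ≥ 99% — the generator's purpose is to stress
the full chain, not to defeat it.

Cohorts are built at the record level: every record receives a
log-normal gain (σ = 0.10) on all amplitudes, and every positive record
its own J amplitude (mean 0.15·separation mV, log-normal σ = 0.15).
`separation` is the single effect-size dial; at 0 the positive class
collapses exactly onto the negative distribution, giving a clean null
experiment.  The train/test split assigns whole records
(round(0.6·n) per class to training, mirroring an 18/15-train,
12/10-test layout at the default 30 + 25 records of ~1200 beats), so
generalization is across subjects, never within.

What the generator does **not** emulate: multi-lead geometry, arrhythmic
or ectopic beats, morphology drift within a record, electrode motion
artifacts, or the true clinical variety of J-wave shapes (notches,
slurs).  A classifier that is perfect here has only been shown to detect
an additive terminal-QRS bump under mild stationary noise; clinical
performance claims require clinical data.

## Preprocessing

Denoising decomposes the record with an 8-level db6 wavelet transform.
Details are soft-thresholded with the universal threshold σ√(2 ln N),
σ estimated as MAD/0.6745 of the finest detail level.  The level-8
approximation (0–0.98 Hz at 500 Hz) is not zeroed: zeroing would also
remove the ~1 Hz beat-train fundamental (a 20% RMS distortion on clean
signals).  Instead the approximation coefficient sequence (rate
fs/2⁸ ≈ 2 Hz) is high-pass filtered at 0.5 Hz with a zero-phase
second-order Butterworth, which removes wander (≥ 28 dB at 0.25 Hz)
while passing the cardiac fundamental.  Measured on clean synthetic
records the whole denoiser is a near-identity (RMSE < 2.5% of signal
RMS) and idempotent to < 1%.

R detection follows the classical Pan-Tompkins cascade adapted to
500 Hz: zero-phase Butterworth band-pass 5–15 Hz, five-point derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise levels
(threshold = noise + 0.25·(signal − noise), learning phase on the first
2 s), 200 ms refractory period and a search-back at half threshold after
1.66× the running RR estimate.  Zero-phase filtering means no group
delay to compensate; accepted integration peaks are refined to the
band-passed maximum within ±100 ms.  All thresholds are data-relative,
so detection is invariant to a global gain.

Beat windows are the 120 samples *after* the R peak (exclusive of the R
sample itself, since the J wave lives on the terminal downslope/ST
segment; `include_r=True` shifts the convention by one sample).  Windows
running past the record tail are dropped and counted.

## Synchrosqueezed transform

The mother wavelet is an analytic Morlet specified in physical units:
ψ̂(ξ) = exp(−τ₀²(ξ − 2πf_c)²/2) for ξ > 0, with center frequency
f_c = 35 Hz and reference envelope width τ₀ = 25 ms, minus the standard
admissibility correction so ψ̂(0) = 0 exactly.  The dimensionless
quality factor is 2πf_c·τ₀ ≈ 5.5 at the default — comfortably
admissible — and sweeping f_c over 25/35/45 Hz genuinely changes the
time–bandwidth trade-off (Q ≈ 3.9–7.1), which is what makes the
wavelet-robustness property of synchrosqueezing worth testing rather
than a tautology.  Scales map to frequency as f = f_c/a, log-spaced at
32 voices/octave over 0.5–250 Hz (≈ 288 scales).

The CWT uses L2 normalization (a^{−1/2}) and is evaluated per scale as
ifft(fft(x)·√a·ψ̂(aξ)); windows are symmetrically extended by their own
length and cropped afterwards, since 0.24 s windows otherwise suffer
severe edge effects.  Below ~4 Hz the wavelet support exceeds even the
extended window and coefficients are boundary-dominated; ridge and
feature extraction operate above this in practice.

Instantaneous frequency is the phase derivative Im[∂_b W/W] with a
centered second-order difference (one-sided at the ends).  Entries with
|W| below γ = 10⁻⁴·max|W| (per window), non-finite ratios, or
non-positive estimates are masked.  Squeezing reassigns
W(a_k,b)·a_k^{−3/2}·Δa_k into the uniform frequency bin (0.5 Hz to fs/2,
one bin per scale, Δω ≈ 0.87 Hz) nearest the IF estimate, ties toward
the lower bin, scaled by Δω^{−1}.

Ridges are extracted by iterative peeling: a Viterbi pass maximizes
per-time normalized band energy minus a smoothness penalty
0.2·(Δbin/4)², jumps capped at ±10 bins per sample; the winning path's
±4-bin band is zeroed and the search repeats K = 5 times.  Tracks are
returned in decreasing captured-energy order, so "mode 1" is always the
dominant component.  The penalty/jump defaults track a 20 Hz/s chirp to
within ~1.5 bins while keeping tone ridges flat.

Reconstruction inverts over a narrow band: f_k(t) = 2·Re[(2π/R_ψ)·
Σ_{|ω_l−φ'_k(t)|≤bw} T(ω_l,t)·Δω], with bw = 4Δω and each bin assigned
to the nearest ridge where bands overlap.  R_ψ = 2π∫ψ̂(ζ)ζ⁻¹dζ is
evaluated by trapezoidal quadrature (cross-checked against adaptive
QUADPACK quadrature to < 0.1%); the extra 2π in the reconstruction
factor is the bookkeeping of the Fourier convention used here (forward
transform without, inverse with, the 1/2π) and is validated empirically:
a unit pure tone reconstructs with < 2% central RMSE, and two tones at
5 and 20 Hz separate with < 2% error each despite sharing the plane.

## Features

Per beat window (35 values):

* **Time–frequency descriptor (20)** — the squeezed energy |T|² is split
  into 10 uniform frequency bands; each contributes its energy share and
  its temporal centroid on a [0, 1] scale.  Normalization makes the
  descriptor gain-invariant.
* **Mode Renyi entropy (5)** — order-3 Renyi entropy (log2, bits) of the
  normalized |T|² restricted to each mode's ridge band.  Order 3 is the
  operating point; α→1 recovers Shannon entropy (verified numerically).
  Note a reassignment subtlety: squeezed white noise is *sparse* in the
  plane, so its band entropy is lower, not higher, than a steady tone's
  — the feature measures time–frequency uniformity of the band, not
  classical waveform irregularity.
* **Approximate/sample entropy (5 + 5)** — standard Pincus and
  Richman–Moorman formulations (natural log, Chebyshev distance,
  self-matches included/excluded respectively) on each reconstructed
  mode series, m = 2 and r = 0.2× the SD of the analyzed series.  "SD of
  the analyzed series" is the operative reading of the tolerance rule on
  120-sample beat windows, where inter-beat (NN) intervals do not exist.
  Both are exactly equal to O(N²) brute-force template counting (tested
  property-wise), affine-invariant through the relative tolerance, and
  SampEn returns a flagged NaN (never ±inf) when no template pair
  matches; the classifier imputes such entries with training-column
  medians.

## Classifier and statistics

A 150-tree random forest (bootstrap bagging, √d features per split,
unlimited depth, fixed seed) scores each beat by the fraction of trees
voting positive.  Metrics are computed beat-wise from the confusion
counts — Se, Sp, Acc in percent and MCC, with MCC flagged undefined
(not 0) when a marginal is empty — and AUC by the Mann–Whitney rank
statistic with tie correction, which equals the trapezoidal ROC area to
10⁻⁹.  A record-level majority vote is reported alongside.  Per-feature
Welch t-tests (unequal variance, Welch–Satterthwaite df, two-tailed) are
run on the training split only, with a Bonferroni-adjusted column next
to the raw p-values.  The record-level split is enforced at evaluation
time: a record id appearing in both splits raises an error.

## Problem sizes and numerical checks

The reduced validation cohort is 10 + 10 records × 200 beats (6 + 6
train, 4 + 4 test after the 60/40 record split) — chosen so the full
chain (≈ 8000 beat-level SST analyses across the default and null
cohorts) completes in minutes while still leaving record identity, not
beat identity, as the generalization axis.  On this cohort the held-out
beat-level AUC is ≥ 0.99 at the default separation; with separation 0
the AUC sits near 0.5.  The null band used in testing (|AUC − 0.5| ≤
0.30) is the ~2 SD record-resampling Monte-Carlo error of a U-statistic
over 4 × 4 test records with strongly correlated within-record beats —
beat counts alone would suggest a far tighter band that record-level
correlation does not support.

Degenerate inputs are defined everywhere: zero windows produce zero
planes, zero modes and zero TF descriptors (with warnings); flat-line
records yield empty R-peak lists rather than exceptions; all-zero
energy distributions raise on entropy evaluation; constant series have
ApEn = SampEn = 0 via the machine-epsilon tolerance floor.

## Known limitations

* The SST plane below ~4 Hz is boundary-dominated for 0.24 s windows;
  features there carry little information.
* Ridge peeling assumes K = 5 separable components; on noise-only
  windows trailing ridges track residual energy (logged, not fatal).
  A fixed-band mode assignment is a possible alternative the current
  implementation does not provide.
* The synthetic J wave is a single additive Gaussian; notched or slurred
  J morphologies, and pathologies that mimic them (early repolarization,
  Brugada patterns), are outside the generator's vocabulary.
* Welch p-values on thousands of correlated beats are anti-conservative:
  beats within a record are not independent samples, so the t-tests
  describe feature separation on this cohort, not population-level
  significance.
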