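# Methods

This note documents the model, the synthetic study conditions, the numerical
choices and the known limitations of `tapromp`.

## The analysis problem

A finger-tapping stimulation study records six acceleration channels (hand
and wrist, x/y/z) at 2000 Hz while a subject taps repetitively between two
instrumented pads. The question is whether a transcranial current
stimulation (tDCS, tACS, tRNS, or a Sham placebo) changes the motion
pattern between a pre-stimulation baseline run (*Prae*) and three
post-stimulation runs (*Post1–3*), across 10 participants and 8 tapping
patterns — 10 × 4 × 5 × 8 = 1,600 recordings including the familiarization
run (*Erst*).

Rather than hand-designed kinematic features, each set of strokes is
summarized by a probability distribution over trajectories, and conditions
are compared by a divergence between those distributions.

## Probabilistic movement primitives

Strokes are phase-normalized to z ∈ [0, 1] on a T-point grid (default
T = 100; the protocol never fixes T, and results are insensitive to it once
T well exceeds the number of basis functions). Each stroke is expanded in
M normalized Gaussian radial basis functions of the phase,

    φ_i(z) = exp(−(z − c_i)² / (2 h)),   rows normalized to sum to 1,

with centers c_i uniform on [0, 1] and bandwidth h = 0.2·(c_{i+1} − c_i)²,
which keeps neighbouring bumps overlapping for any M (at M = 20 this is
0.2·(20−1)⁻²). Per-stroke weights over all six channels are the ridge
solution

    W* = (AᵀA + λI)⁻¹ Aᵀ τ,

where A = diag(Φ, …, Φ) is the block-diagonal stack of the T×M basis matrix
(one block per channel, channel-major vectorization) and λ = 1e−6 by
default. The ridge term exists because duplicated or poorly varied
demonstrations make AᵀA singular; λ = 0 is accepted only when A has full
column rank.

Collapsing the n demonstrations gives the weight distribution
N(μ_w, Σ_w) (column mean, unbiased sample covariance). Marginalizing the
weights yields the trajectory distribution

    p(τ) = N(τ | Φ μ_w, Φ Σ_w Φᵀ + Σ_y),

of which only the per-phase-point, per-channel marginals (mean, std) are
consumed downstream. Σ_y is diagonal with one scalar per channel, estimated
as the RMS reconstruction residual; cross-channel noise correlation is not
modeled. With n = 20 and M·D = 120 the sample covariance Σ_w is singular;
a diagonal jitter of max(1e−9·trace/dim, 1e−12) keeps it PSD after
rounding, which is harmless because only the quadratic forms
φ_t Σ_w^{(dd)} φ_tᵀ enter the marginals. Expectation–maximization fitting
is not implemented; ridge regression is the operative estimator.

## Symmetric KL divergence

Two trajectory distributions are compared by the symmetrized
Kullback–Leibler divergence of their univariate Gaussian marginals,

    D_KLS = ¼ [ σ₁²/σ₂² + σ₂²/σ₁² + (μ₁−μ₂)²(1/σ₁² + 1/σ₂²) − 2 ],

averaged over all T phase points and the six channels. A 6-dimensional
multivariate divergence would be an alternative reading of the trajectory
formula; the per-channel average is the operative definition here, and the
multivariate variant is out of scope. Standard deviations are floored at
1e−8 on distribution construction so degenerate variances (duplicated
strokes) cannot blow up the ratio terms; whether and how the original
analysis regularized near-zero variances is unknown, so the floor is a
declared choice.

A sliding window (default 1/10 of the phase, stride one grid step,
window contributions *averaged* so values are comparable across window
sizes) localizes where along the movement two distributions differ.

The reconstruction loss is the mean divergence between each cell's
empirical per-phase distribution and its ProMP reconstruction, averaged
over cells; it is the model-selection criterion for M and decreases
monotonically in M on smooth data.

## Preprocessing

Pad contacts are detected per pad channel as the first crossing of
0.5 × the channel's absolute maximum, with a 100 ms refractory window; the
original study states only that pad-accelerometer statistics were used, so
threshold and refractory are declared defaults. Same-pad double contacts
keep the first event of the run (with a warning) instead of failing.
Consecutive events delimit strokes; the pad order maps to
inward/outward via a configurable convention, because the anatomical
definition (elbow angle decreasing = inward) is not computable from the
signals alone. Per direction, the 20 strokes from the last-twenty-first to
the last-but-one are kept (the final stroke is contaminated by the stop
signal). Each stroke's time axis is rescaled to [0, 1] and linearly
interpolated onto the grid; linear interpolation is the simplest monotone
scheme and its error vanishes as the sampling rate grows. An optional
zero-phase 20 Hz Butterworth low-pass is available but off by default: the
basis expansion itself suppresses high-frequency noise, and the fitted
means with and without filtering agree closely.

## Study pipeline

All 1,600 cells are fitted per direction; *Erst* is fitted for completeness
but never enters statistics (the configuration refuses to include it).
Divergences are computed between the ProMP-reconstructed Prae and Post
distributions per (participant, stimulation, experiment, direction).
Outliers are excluded one-sidedly: pooling all comparisons and both
directions, a comparison unit is dropped when either direction's value
exceeds μ_D + 3σ_D; unusually low values are valid. The pooling scope
(across comparisons and directions) is a configuration-level choice — the
source analysis does not specify it. Manual exclusions (e.g. after video
review of a sensor mishap) go through a config blacklist; the 3σ rule is
the only automatic mechanism. Aggregation reports mean ± std per
(stimulation, comparison, direction) and overall per direction; no
hypothesis tests are attached, as the analysis is descriptive.

## Synthetic study conditions

Because no recorded dataset is distributed, a seeded generator provides the
study conditions end to end:

* **Stroke template** — minimum-jerk acceleration a(u) = 60u − 180u² + 120u³
  per channel, scaled by per-channel amplitudes (hand x/y/z = 2.0/0.5/1.0,
  wrist half of that, in units where the hand peak is ≈ 11.5 m/s²): smooth
  and biphasic like real tapping strokes, but a declared stand-in, not a
  claim about the real waveforms. Outward strokes are the time-reversed,
  sign-flipped counterpart of inward strokes, so mirrored statistics hold
  by construction.
* **Timing** — 30 tapping cycles at 1.5 taps/s (twice that for the "rapid"
  patterns); each inter-contact interval is log-normal with 5% relative
  std; the finger dwells on the pad for the first 20% of each interval.
  Pads emit a 20 ms rectangular pulse at each contact (2 × 30 pulses per
  recording).
* **Stroke-to-stroke variability** — per-channel amplitude factors with
  10% CV *plus* smooth shape perturbations (8 Gaussian bumps over the
  motion phase, coefficient std 8% of the channel's peak acceleration).
  The shape term matters: a pure scale factor would give each channel a
  rank-one inter-trial covariance, i.e. a single degree of freedom, which
  both trivializes the weight covariance the model is supposed to estimate
  and makes the null divergence heavy-tailed in a way repeated human
  movements are not.
* **Sensor noise** — iid Gaussian, std 0.2 (≈ 2% of the hand peak) on all
  motion samples.
* **Design** — participants get a stable ±10% amplitude factor; the eight
  patterns combine tapping axis (swapping x/y amplitudes), speed and hand.
  Every recording draws from a substream hashed from (seed, participant,
  stimulation, phase, experiment), so any cell reproduces bit-identically
  regardless of generation order or design subsetting.
* **Effects and anomalies** — optional stimulation effects (per-channel
  mean shift on a phase sub-interval, amplitude scaling, restricted to
  chosen phases) and sensor-misplacement anomalies (axis flips/swaps
  targeting one recording) support power and detection checks.

What the generator does **not** emulate: gravity components and initial-pose
drift, within-stroke tempo drift, non-Gaussian or autocorrelated sensor
noise, genuine neurophysiological stimulation effects, and real stroke
waveforms. Passing tests therefore demonstrate the correctness and
calibration of the *method* under controlled conditions, not conclusions
about real stimulation data. In particular the synthetic null divergence
level (≈ 0.08 with these settings) is far below the ≈ 1 level seen in real
recordings, whose inter-trial variability is larger and less homogeneous;
both sit well below the 2.5 insignificance threshold.

## Problem sizes and determinism

Study-scale runs in the test-suite and in `scripts/acceptance.py` use a
250 Hz sampling rate (the generator's default stays at the protocol's
2000 Hz): segmentation is exact at any rate with clean pad pulses, and
phase normalization makes the fit indifferent to the raw rate once strokes
span a few hundred samples. The full 1,600-cell study then runs in well
under a minute on one core. All randomness flows from explicit seeds;
identical configuration and seed give byte-identical result tables.

## Known limitations

* Only acceleration is modeled; velocity/displacement reconstruction by
  integrating IMU data is deliberately out of scope (double integration
  drifts).
* Duration information is discarded by phase normalization, so effects on
  stroke *timing* are invisible to the divergence.
* The divergence treats channels and phase points as independent Gaussians;
  correlated deviations are summarized but not exploited.
* The 3σ rule is applied to a right-skewed statistic; on large pooled
  tables it flags roughly the expected upper-tail fraction (~1%) even
  under the null, which is inherent to the rule, not a defect of the
  implementation.
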