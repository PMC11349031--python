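# Methods

## Estimators

**SWPC.** The sliding-window Pearson correlation uses a centered rectangular
window of N = 2Δ + 1 samples, valid windows only: the output has T − 2Δ
values and window index i (0-based) centers at sample i + Δ.  No edge
padding and no Fisher-z transform are applied anywhere.  A window in which
either series has zero variance yields a flagged missing value (NaN) plus a
runtime warning; downstream stages drop or mean-fill flagged windows
explicitly (and say so), never silently.  Only the rectangular taper is
validated; `WindowSpec.shape` is a hook, not a feature.

**SSB modulation.** The analytic signal is computed with the FFT-based
Hilbert transform on the full series (no segmenting), multiplied by
e^{+j2πf_m t}, and the real part is taken.  The **positive** exponent is a
deliberate choice: only an upward shift moves signal content out of the
window high-pass's stopband, and it matches the frequency-domain picture of
the method (positive band up, negative band down, spectrum kept symmetric
so the output stays real).  For a band-limited input with a positive band
floor and no Nyquist wrap, the modulation preserves power to well within
1%.  Wrapping past Nyquist raises `AliasingError` unless explicitly
overridden, in which case a warning is emitted (the evaluation suites
override it on purpose to map the aliasing-degraded regime).

**Cutoff and modulation selection.** The approximate −3 dB corner of
moving-average subtraction is F_cutoff = 0.88·fs/√(N²−1).  Two independent
checks pin this down: it reproduces the published worked value 0.0635 Hz at
(N=7, fs=0.5), and it agrees within 10% with the numerically evaluated −3 dB
point of the zero-phase 1 − Dirichlet response when that point is measured
relative to the high-pass's peak gain (the response overshoots 1, so the
corner must be referenced to the peak, not to unity).  The automatic
modulation rule is f_m = max(0, F_cutoff − f_low) with the aliasing guard
f_m ≤ fs/2 − f_high; infeasible bands raise an error naming the violated
constraint.

**Up-sampling.** By FFT zero-padding (`scipy.signal.resample`), i.e. ideal
band-limited interpolation, chosen because it exactly preserves the original
spectral support — the property that makes up-sampling useful here: a
full-band series at rate fs becomes a band-limited series at rate n·fs,
creating the headroom SSB modulation needs.

## Synthetic scenarios

All generators are bit-reproducible given (config, seed) and return the
exact estimand alongside the data.

**Band-limiting.** White standard-normal noise is low-passed with the
minimum-order Chebyshev type II design for a 3 dB passband / 30 dB stopband
target (`scipy.signal.cheb2ord`), stopband edge at 1.25× the cutoff (the
transition width is not dictated by the design targets; 1.25× keeps the
band tight without inflating the order).  The filter is applied
**zero-phase** (forward-backward, `sosfiltfilt`).  This choice is
load-bearing: a single causal pass leaves equiripple leakage at exactly
−30 dB across the whole wide stopband.  Because the correlation projection
is applied *after* filtering, that broadband leak carries the projected
correlation at high frequencies, where SWPC's high-pass passes it
untouched — artificially propping up the plain-SWPC baseline and roughly
halving the measured SSB+SWPC advantage.  Zero-phase application squares
the response (−60 dB effective), leaving the series genuinely band-limited;
it also introduces no group delay relative to the pointwise truth.

**Sinusoidal-correlation pairs.** Defaults are the studied conditions:
1000 samples at fs = 2 Hz, band [0, 0.1] Hz, C(t) = c_max·cos(2π f_corr t)
with c_max = 0.7 (0.3 and 0 variants configurable).  After filtering, each
series is standardized (sample mean/std) so the closed-form 2×2 upper
Cholesky factor U(t) = [[1, c], [0, √(1−c²)]] of Σ(t) projects the pair to
unit marginal variance and pointwise correlation exactly C(t).  The series
length is not dictated by the scenario itself; 1000 samples matches the
state scenario's stated length.

**Two-state system.** Six nodes, 1000 samples; state 0 correlates nodes
{0,1,2} at 0.7 (identity elsewhere), state 1 the complementary block.
Labels alternate every `state_length` samples; a final partial segment
keeps its state.  Within each segment the (filtered, standardized) series
are projected by the upper Cholesky factor of the active state covariance.
The projection slightly perturbs the spectrum; as in the design this
estimator family assumes, the perturbation is accepted and not corrected.

**White pairs.** iid-in-time bivariate normal draws with time-indexed
covariance c_max·cos(2π f_corr t) at fs = 1 Hz — full-band content by
construction, used to demonstrate that up-sampling makes SSB+SWPC
applicable to signals without a band limit.

**What the generators do not emulate.** Hemodynamic convolution,
physiological noise, motion artifacts, measurement noise, and
between-subject heterogeneity.  Passing tests therefore demonstrate the
estimator's statistical behavior under its own model assumptions
(band-limited Gaussian signals, unit variance, exactly known truth), not
performance on real recordings.

## Evaluation

Estimates are scored against truth sampled at window centers
(t ∈ [Δ, T−Δ−1]) — centered windows make this alignment canonical — by
sample Pearson correlation and RMSE.  Correlation is flagged undefined when
the truth is constant (the zero-correlation null), where RMSE remains the
metric.  Monte-Carlo summaries report the mean with a 99.9%
normal-approximation CI (z ≈ 3.2905); per-realization seeds derive
deterministically from the master seed via `SeedSequence`.  Centroids are
matched to true state vectors by maximizing total correlation — exhaustive
permutation for k ≤ 3, Hungarian assignment otherwise.

## State pipeline

City-block k-means is written in-house: scikit-learn's KMeans is
Euclidean-only, and under the L1 objective the stationary centroid update
is the coordinate-wise **median**, not the mean.  Seeding is k-means++ with
the city-block distance; the best of n_init = 20 restarts (max 500 Lloyd
iterations) by within-cluster sum of L1 distances is kept; empty clusters
are re-seeded at the point farthest from its center.  Rows containing
flagged-missing values are dropped (count recorded in `meta`,
`row_mask` re-aligns labels).  Cluster labels are 0-based.

The elbow criterion fits one least-squares line to each side of every
interior split of the mean within-cluster-distance curve, keeps the split
with the smallest total squared residual, and returns the rounded abscissa
of the two lines' intersection, clamped to the scanned range; a collinear
curve has no elbow and falls back to the smallest k with a warning.

Mean dwell time is the average length of maximal runs of a state's label,
in windows (seconds = windows/fs offered, but all tests run in windows);
never-visited states are missing, not zero.  Group comparison fits a robust
linear model dwell ~ group + age + gender + meanFD per cluster with Tukey
bisquare weights (tuning constant 4.685), covariates mean-centered and
gender as a binary indicator (the coding is our choice), subjects who never
visit a cluster excluded rather than imputed, and Benjamini–Hochberg FDR
correction across clusters.  Null-permutation simulations in the test suite
confirm the realized false-positive rate stays at or below nominal.

## Spectral diagnostics

PSD estimation is Welch averaging of Kaiser-windowed segments: segment
length fs/freq_res (default resolution 0.01 Hz), 50% overlap, one-sided
density normalization (integrated PSD ≈ variance).  The `leakage` control
in [0, 1] maps to the Kaiser shape as β = 26·(1−leakage), so the default
leakage 0.5 gives β = 13 — mid-range between rectangular (β = 0) and a
heavily tapered window.  Absolute PSD values from other implementations of
a leakage-controlled Welch estimate will differ in detail; the power-law
exponent fits are robust to these choices (verified on white and 1/f
processes in the tests).

Power-law fits y = a·f^β run as nonlinear least squares in linear space
("power1" semantics), initialized from a log–log line fit, zero-frequency
bin excluded; the fitting range is the caller's to restrict.  When
recovering β from Welch estimates of shaped noise, the lowest few bins
(inside the Kaiser main lobe, where the density estimate flattens) should
be excluded — the recovery tests skip 3 bins and then recover β = −1 within
±0.15.  Non-convergence flags β as missing with a warning.  The fit is
scale-equivariant (a scales, β invariant).

The window transfer function is the Dirichlet kernel of the length-N
moving average on a dense grid, unity at DC, first null at fs/N; trFNC
spectra from SSB+SWPC at small windows carry less relative power beyond
that first null than SWPC's, and the temporal mean of trFNC is compared
against static (whole-series) correlation by MSE across pairs as a
real-data-style evaluation that needs no ground truth.

## Pipeline and I/O

Series travel as delimited text (declared orientation) or HDF5
(`/values` + `fs`/`band` attrs); trFNC tensors as HDF5 with pair index,
window centers, estimator metadata and a provenance block (config hash,
seed, package version).  The end-to-end run applies a minimum-order
Butterworth band-pass (default (0.01, 0.15) Hz; 3 dB/30 dB targets,
stopband edges at 0.5× the lower and 1.25× the upper passband edge) before
estimation, then optionally clusters.  Every stage failure aborts with a
stage-named error; fixed seeds make outputs deterministic.

## Numerical choices and edge cases

* Correlations are clipped to [−1, 1] to absorb last-bit rounding.
* `ssb_modulate(f_m=0)` returns the input array unchanged (exact identity).
* The aliasing guard uses a 1e-12 tolerance so exact-boundary plans pass.
* `n_samples` not divisible by `state_length` keeps the last state to the
  end; `k` larger than the number of distinct rows is rejected.
* Monte-Carlo suites run at reduced replication (200–300; 1000 for the
  headline grid and ensemble-recovery checks) with seeds derived from fixed
  master seeds; problem sizes are chosen so the estimator comparisons are
  stable at the third decimal.

## Known limitations

* The modulation frequency is an extra free parameter; a poor (aliasing)
  choice degrades the estimate below plain SWPC, as the evaluation suites
  show near Nyquist.
* The method assumes band-limited inputs; for full-band signals the
  up-sampling route applies but adds its own parameter.
* The state pipeline assumes the cluster count is meaningful for the data;
  the elbow selector is a heuristic and degenerates on elbow-free curves.
* Real-recording effects (hemodynamics, noise, motion) are outside the
  synthetic scope; conclusions about real data require the user's own
  validation.
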