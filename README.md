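# ssbswpc

Time-resolved network connectivity from band-limited biological time series,
estimated with **single-sideband modulation + sliding-window Pearson
correlation (SSB+SWPC)**.

## The problem

Sliding-window Pearson correlation (SWPC) is the workhorse estimator of
time-resolved functional network connectivity (trFNC): for node time courses
x(t), y(t) and a centered rectangular window of N = 2Δ + 1 samples,

    r_xy(t; Δ) = Σ_{τ=t−Δ}^{t+Δ} (x(τ) − μ̂_x(t)) (y(τ) − μ̂_y(t)) / (N σ̂_x(t) σ̂_y(t)).

Subtracting the moving average inside each window acts as a high-pass filter
on the inputs with an approximate −3 dB corner

    F_cutoff = 0.88 · Fs / √(N² − 1).

Short windows — needed to resolve fast connectivity dynamics — therefore
discard exactly the low frequencies that carry most of the signal in slow,
band-limited data such as hemodynamic activity.  SSB+SWPC escapes this
trade-off by frequency-shifting both series upward before windowing, using
single-sideband modulation built on the analytic signal:

    x_ssb(t; f_m) = Re{ (x(t) + j·H{x(t)}) · e^{+j2πf_m t} },

which moves the whole band above the window's high-pass stopband while
keeping the series real, then applies SWPC to the modulated pair.  The
recommended modulation is f_m = F_cutoff − f_low, subject to the aliasing
guard f_m ≤ Fs/2 − f_high.

The package provides, as a tested library plus `ssbswpc` CLI:

* the estimators (`swpc`, `ssb_modulate`, `ssb_swpc`, cutoff and
  modulation-frequency selection, ideal up-sampling) behind a
  statsmodels-style `SlidingWindowConnectivity → ConnectivityResults` pair;
* seeded synthetic scenarios with exact ground truth (sinusoidally varying
  pairwise correlation, periodic two-state six-node switching, white pairs
  with time-indexed covariance) in `ssbswpc.simulate`;
* evaluation metrics (correlation/RMSE against truth, Monte-Carlo grids with
  99.9% CIs, centroid-truth matching) in `ssbswpc.evaluate`;
* the connectivity-state pipeline (city-block k-means with median updates,
  two-line elbow selection, mean dwell time, robust bisquare group
  comparison with BH-FDR) in `ssbswpc.states`;
* spectral diagnostics (Kaiser-windowed Welch PSD, 1/f^β power-law fits,
  window transfer function, averaged-trFNC vs static-FNC MSE) in
  `ssbswpc.spectra`.

## Worked example

Estimate a sinusoidally varying correlation C(t) = 0.7·cos(2π·0.005·t) from
a band-limited pair (fs = 2 Hz, band [0, 0.1] Hz) with a 5-sample window:

```python
from ssbswpc import SinusoidalCorrConfig, simulate_sinusoidal_pair, \
    SlidingWindowConnectivity
from ssbswpc.evaluate import align_truth, score_against_truth

sim = simulate_sinusoidal_pair(SinusoidalCorrConfig(f_corr=0.005, seed=0))
res = SlidingWindowConnectivity(sim.series, window=5, f_m=0.5,
                                allow_alias=True).fit()
print(res.summary())
truth = align_truth(sim.true_corr, half_width=2)
print(score_against_truth(res.values[:, 0], truth))
```

prints

```
Sliding-Window Connectivity Results
======================================
estimator:        ssb+swpc
nodes / pairs:    2 / 1
windows (T-2Δ):   996
window length N:  5 samples (2.5 s at fs=2.0 Hz)
f_m:              0.5000 Hz
HP cutoff:        0.3593 Hz
flagged missing:  0
mean |r|:         0.6256
(0.615..., 0.552...)
```

The 5-sample window's high-pass corner (0.359 Hz) sits far above the whole
signal band, so plain SWPC on the same realization scores correlation 0.430
(RMSE 0.808) against the true C(t), while the modulated estimator reaches
0.615 (RMSE 0.552): shifting the band out of the stopband recovers signal
the short window would otherwise discard.

The end-to-end state pipeline is available from the shell:

```
$ ssbswpc demo --seed 0
ssb+swpc: mean centroid-truth correlation 0.783 over 5 realizations
swpc: mean centroid-truth correlation 0.654 over 5 realizations
```

Other subcommands — `simulate`, `estimate`, `compare`, `states`,
`dwell-compare`, `spectra` — chain through HDF5/CSV artifacts; see
`ssbswpc --help`.

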