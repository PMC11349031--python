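"""Spectral diagnostics of estimated connectivity time series.

PSD estimation uses Welch averaging with Kaiser-windowed segments; the
Kaiser shape parameter is derived from a ``leakage`` control in [0, 1]
(1 = rectangular, smaller = heavier taper), mapped as beta = 26*(1-leakage)
so the default leakage 0.5 gives beta = 13.  Scale-free structure is
quantified by fitting a*f^beta to the PSD by nonlinear least squares in
linear space (initialized from a log-log line fit), and the sliding
window's own low-pass transfer function is available for comparison with
trFNC spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import freqz, welch

from .data import ConnectivityTensor, TimeSeriesSet, vectorize_matrix

__all__ = [
    "SpectrumResult",
    "estimate_psd",
    "fit_power_law",
    "window_transfer_function",
    "avg_trfnc_vs_static",
    "trfnc_psd",
]


@dataclass
class SpectrumResult:
    """Per-pair PSDs with optional power-law fits."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_pairs, n_freqs)
    beta: np.ndarray | None = None
    fit_amplitude: np.ndarray | None = None


def _kaiser_beta(leakage: float) -> float:
    if not 0 <= leakage <= 1:
        raise ValueError("leakage must lie in [0, 1]")
    return 26.0 * (1.0 - leakage)


def estimate_psd(
    x: np.ndarray,
    fs: float,
    leakage: float = 0.5,
    freq_res: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Kaiser-windowed segments.

    Segment length is fs/freq_res samples (the requested resolution
    bandwidth); overlap 50%; one-sided density normalization, so the
    integrated PSD approximates the series variance.

    Raises if the series is too short for the requested resolution, naming
    the minimum length.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(fs / freq_res))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"series of length {x.shape[-1]} too short for freq_res={freq_res} Hz "
            f"at fs={fs} Hz; need >= {nperseg} samples"
        )
    beta = _kaiser_beta(leakage)
    return welch(
        x, fs=fs, window=("kaiser", beta), nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant", scaling="density", axis=-1,
    )


def fit_power_law(freqs: np.ndarray, psd: np.ndarray) -> tuple[float, float]:
    """Fit y = a * f^beta to a PSD by nonlinear least squares ("power1").

    The zero-frequency bin is excluded; the fit runs in linear space,
    initialized from a log-log straight-line fit.  On non-convergence a
    warning is emitted and (nan, nan) returned.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    keep = (freqs > 0) & (psd > 0) & np.isfinite(psd)
    f, p = freqs[keep], psd[keep]
    if f.size < 3:
        raise ValueError("need at least 3 positive-frequency PSD points")
    slope, intercept = np.polyfit(np.log(f), np.log(p), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = curve_fit(lambda x, a, b: a * np.power(x, b), f, p, p0=p0, maxfev=20000)
    except RuntimeError:
        warnings.warn("power-law fit did not converge; beta flagged missing",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    return float(popt[0]), float(popt[1])


def window_transfer_function(
    n: int, fs: float, n_freqs: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response of the length-N rectangular moving average.

    Normalized to 1 at zero frequency (Dirichlet kernel); the first null
    sits at fs/N.  The complementary high-pass 1 - MA is the filter whose
    approximate -3 dB corner :func:`ssbswpc.core.hp_cutoff` models.
    """
    if n < 2:
        raise ValueError("window length must be >= 2")
    w, h = freqz(np.ones(n) / n, worN=n_freqs, fs=fs)
    return w, np.abs(h)


def trfnc_psd(
    tensor: ConnectivityTensor,
    fs: float,
    leakage: float = 0.5,
    freq_res: float | None = None,
) -> SpectrumResult:
    """Per-pair Welch PSD of a connectivity tensor, with power-law fits.

    ``freq_res`` defaults to the coarsest resolution the window count
    supports (single segment).  Flagged-missing windows are replaced by the
    pair's temporal mean for spectral estimation only (count warned).
    """
    vals = tensor.values
    if freq_res is None:
        freq_res = fs / vals.shape[0]
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        warnings.warn(f"{n_missing} flagged windows mean-filled for PSD estimation",
                      RuntimeWarning, stacklevel=2)
        vals = np.where(np.isnan(vals), np.nanmean(vals, axis=0, keepdims=True), vals)
    freqs, psd = estimate_psd(vals.T, fs, leakage=leakage, freq_res=freq_res)
    betas = np.empty(psd.shape[0])
    amps = np.empty(psd.shape[0])
    for i, row in enumerate(psd):
        amps[i], betas[i] = fit_power_law(freqs, row)
    return SpectrumResult(freqs=freqs, psd=psd, beta=betas, fit_amplitude=amps)


def avg_trfnc_vs_static(tensor: ConnectivityTensor, series: TimeSeriesSet) -> float:
    """Mean-square distance between time-averaged trFNC and static FNC.

    The temporal mean of the windowed correlations (flagged windows
    excluded) is compared per pair against the whole-series Pearson
    correlation; the MSE runs across pairs.  The closer the two, the better
    the estimator captures the zero-frequency content of connectivity.
    """
    avg = tensor.temporal_mean()
    static = vectorize_matrix(np.corrcoef(series.values))
    if avg.shape != static.shape:
        raise ValueError("tensor pair count does not match the series node count")
    return float(np.mean((avg - static) ** 2))
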