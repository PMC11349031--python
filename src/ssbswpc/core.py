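"""Sliding-window correlation estimators and single-sideband modulation.

Sliding-window Pearson correlation (SWPC) estimates a time-resolved
correlation

    r_{x,y}(t; Δ) = Σ_{τ=t-Δ}^{t+Δ} (x(τ) - μ̂_x(t)) (y(τ) - μ̂_y(t)) / (N σ̂_x(t) σ̂_y(t))

with a centered rectangular window of N = 2Δ + 1 samples.  Subtracting the
moving average acts as a high-pass filter on the inputs: with a short window
it removes exactly the low frequencies that carry most of the signal in
band-limited data (e.g., hemodynamic activity).  Single-sideband (SSB)
modulation shifts the whole band upward by f_m before windowing,

    x^ssb(t; f_m) = Re{ x_a(t) · e^{+j 2π f_m t} },   x_a = x + j H{x},

which moves the signal out of that implicit high-pass stopband while keeping
it real-valued.  SSB+SWPC is SWPC applied to the modulated pair.

The approximate −3 dB cutoff of the moving-average-subtraction high-pass is

    F_cutoff = 0.88 · fs / sqrt(N² − 1)

and the recommended modulation frequency is F_cutoff − f_low, clipped at
zero and subject to the aliasing guard f_m ≤ fs/2 − f_high.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert, resample

from .data import ModulationPlan, WindowSpec

__all__ = [
    "AliasingError",
    "swpc",
    "ssb_modulate",
    "ssb_swpc",
    "hp_cutoff",
    "choose_modulation_frequency",
    "upsample",
]


class AliasingError(ValueError):
    """Raised when a modulation would push signal content past Nyquist."""


def _as_window(window: WindowSpec | int) -> WindowSpec:
    if isinstance(window, WindowSpec):
        return window
    return WindowSpec(half_width=int(window))


def swpc(x: np.ndarray, y: np.ndarray, window: WindowSpec | int) -> np.ndarray:
    """Sliding-window Pearson correlation of two equal-length series.

    Parameters
    ----------
    x, y : ndarray, 1-D
        Input series of equal length T >= 2Δ + 1.
    window : WindowSpec or int
        Centered window; an int is taken as the half-width Δ.

    Returns
    -------
    ndarray, shape (T - 2Δ,)
        Per-window Pearson correlations, indexed by window center
        t in [Δ, T - Δ - 1].  Windows where either series has zero
        variance are flagged NaN and a warning is emitted.
    """
    window = _as_window(window)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("swpc expects 1-D series")
    if x.shape != y.shape:
        raise ValueError(f"series length mismatch: {x.shape[0]} vs {y.shape[0]}")
    n = window.length
    if n > x.shape[0]:
        raise ValueError(f"window length {n} exceeds series length {x.shape[0]}")

    xw = sliding_window_view(x, n)
    yw = sliding_window_view(y, n)
    xm = xw - xw.mean(axis=1, keepdims=True)
    ym = yw - yw.mean(axis=1, keepdims=True)
    sxy = np.einsum("ij,ij->i", xm, ym)
    sxx = np.einsum("ij,ij->i", xm, xm)
    syy = np.einsum("ij,ij->i", ym, ym)
    denom = np.sqrt(sxx * syy)
    bad = denom == 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} window(s) with zero variance flagged as missing",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, np.nan, sxy) / np.where(bad, 1.0, denom)
    # guard against |r| marginally exceeding 1 through rounding
    return np.clip(r, -1.0, 1.0, out=r)


def ssb_modulate(
    x: np.ndarray,
    f_m: float,
    fs: float,
    band_high: float | None = None,
    allow_alias: bool = False,
) -> np.ndarray:
    """Shift the spectrum of a real series outward by ``f_m`` Hz.

    Forms the analytic signal via the (FFT-based) Hilbert transform,
    multiplies by e^{+j 2π f_m t} and takes the real part.  The positive
    band moves up and the negative band down, so the output stays real and
    — for a band-limited input that does not wrap past Nyquist — keeps the
    input's power.

    Parameters
    ----------
    x : ndarray, 1-D real
    f_m : float
        Modulation frequency in Hz, >= 0.  ``f_m = 0`` returns ``x`` exactly.
    fs : float
        Sampling frequency in Hz.
    band_high : float, optional
        Highest frequency of the signal content.  When given, modulations
        with ``f_m + band_high > fs/2`` raise :class:`AliasingError` unless
        ``allow_alias`` is set (then only a warning is emitted).
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise TypeError("ssb_modulate expects a real-valued series")
    x = x.astype(float)
    if f_m < 0:
        raise ValueError(f"modulation frequency must be >= 0, got {f_m}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if band_high is not None and f_m + band_high > fs / 2 + 1e-12:
        msg = (
            f"modulation by {f_m} Hz pushes the band top {band_high} Hz past "
            f"Nyquist {fs / 2} Hz (aliasing)"
        )
        if not allow_alias:
            raise AliasingError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    if f_m == 0:
        return x
    t = np.arange(x.shape[0]) / fs
    return np.real(hilbert(x) * np.exp(2j * np.pi * f_m * t))


def ssb_swpc(
    x: np.ndarray,
    y: np.ndarray,
    window: WindowSpec | int,
    f_m: float,
    fs: float,
    band_high: float | None = None,
    allow_alias: bool = False,
) -> np.ndarray:
    """SWPC of the SSB-modulated pair: modulate both series by ``f_m``, then
    compute the sliding-window Pearson correlation.

    With ``f_m = 0`` this reduces exactly to :func:`swpc`.
    """
    xm = ssb_modulate(x, f_m, fs, band_high=band_high, allow_alias=allow_alias)
    ym = ssb_modulate(y, f_m, fs, band_high=band_high, allow_alias=allow_alias)
    return swpc(xm, ym, window)


def hp_cutoff(n: int, fs: float) -> float:
    """Approximate −3 dB cutoff (Hz) of moving-average subtraction.

    Subtracting a length-N rectangular moving average from a series is a
    high-pass filter; its approximate −3 dB corner is
    0.88 · fs / sqrt(N² − 1).
    """
    if n < 2:
        raise ValueError(f"window length must be >= 2, got {n}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return 0.88 * fs / np.sqrt(n**2 - 1)


def choose_modulation_frequency(
    window: WindowSpec | int,
    fs: float,
    band: tuple[float, float],
) -> ModulationPlan:
    """Pick the modulation frequency that lifts the band's low edge to the
    window high-pass cutoff.

    f_m = max(0, F_cutoff(N, fs) − f_low), where F_cutoff comes from
    :func:`hp_cutoff`.  The plan must respect the aliasing guard
    f_m ≤ fs/2 − f_high; otherwise an :class:`AliasingError` is raised
    naming the violated constraint.
    """
    window = _as_window(window)
    f_low, f_high = band
    if not (0 <= f_low < f_high <= fs / 2 + 1e-12):
        raise ValueError(f"invalid band {band} for fs={fs}")
    cutoff = hp_cutoff(window.length, fs)
    f_m = max(0.0, cutoff - f_low)
    margin = fs / 2 - f_high - f_m
    plan = ModulationPlan(f_m=f_m, f_cutoff=cutoff, alias_margin=margin)
    if not plan.valid:
        raise AliasingError(
            f"no non-aliasing modulation: required f_m = {f_m:.4g} Hz exceeds "
            f"fs/2 - f_high = {fs / 2 - f_high:.4g} Hz for window N={window.length}"
        )
    return plan


def upsample(x: np.ndarray, factor: int, fs: float) -> tuple[np.ndarray, float]:
    """Ideal band-limited up-sampling by an integer factor (FFT zero-padding).

    The returned series has length ``factor * len(x)`` at sampling rate
    ``factor * fs``; its spectral content stays confined to the original
    [−fs/2, fs/2], which creates headroom for SSB modulation of signals
    that were full-band at the original rate.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"up-sampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy(), fs
    return resample(x, factor * x.shape[0]), fs * factor
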