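"""Domain containers for time series, windows and connectivity tensors.

The central objects are :class:`TimeSeriesSet` (a nodes x time matrix with
sampling metadata), :class:`WindowSpec` (the sliding-window half-width) and
:class:`ConnectivityTensor` (windows x node-pair correlation estimates with
full provenance of how they were computed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesSet",
    "WindowSpec",
    "ModulationPlan",
    "ConnectivityTensor",
    "pair_index",
    "n_pairs",
    "vectorize_matrix",
    "matrix_from_vector",
]


def n_pairs(n_nodes: int) -> int:
    """Number of unique node pairs, n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def pair_index(n_nodes: int) -> list[tuple[int, int]]:
    """Ordered (i, j) pairs with i < j, row-major upper triangle."""
    return list(itertools.combinations(range(n_nodes), 2))


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (k=1) of a symmetric matrix, in ``pair_index`` order."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def matrix_from_vector(vec: np.ndarray, n_nodes: int, diag: float = 1.0) -> np.ndarray:
    """Rebuild a symmetric matrix from its ``pair_index``-ordered upper triangle."""
    out = np.full((n_nodes, n_nodes), diag, dtype=float)
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


@dataclass
class TimeSeriesSet:
    """A set of node time courses sampled at a common rate.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_samples)
        Real-valued activity time courses, one node per row.
    fs : float
        Sampling frequency in Hz.
    band : tuple of float, optional
        Known spectral support (f_low, f_high) in Hz; used for aliasing
        guards when choosing a modulation frequency.
    """

    values: np.ndarray
    fs: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.band is not None:
            f_low, f_high = self.band
            if not (0 <= f_low < f_high <= self.fs / 2 + 1e-12):
                raise ValueError(
                    f"band {self.band} must satisfy 0 <= f_low < f_high <= fs/2 = {self.fs / 2}"
                )
            self.band = (float(f_low), float(f_high))

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Centered sliding window of length N = 2*half_width + 1 samples.

    Only the rectangular taper is validated; the ``shape`` hook exists so a
    taper could be plugged in, but all published behaviour assumes a
    rectangular window.
    """

    half_width: int
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError(f"half_width must be >= 1, got {self.half_width}")
        if self.shape != "rectangular":
            raise NotImplementedError("only the rectangular window is supported")

    @property
    def length(self) -> int:
        return 2 * self.half_width + 1

    @classmethod
    def from_length(cls, n: int) -> "WindowSpec":
        """Build from an odd window length N (N = 2Δ + 1)."""
        if n < 3 or n % 2 == 0:
            raise ValueError(f"window length must be odd and >= 3, got {n}")
        return cls(half_width=(n - 1) // 2)


@dataclass(frozen=True)
class ModulationPlan:
    """A chosen modulation frequency and the constraints that justify it.

    ``alias_margin`` is fs/2 - f_high - f_m: the spectral headroom left
    between the top of the shifted band and Nyquist.  A valid plan has a
    non-negative margin.
    """

    f_m: float
    f_cutoff: float
    alias_margin: float

    @property
    def valid(self) -> bool:
        return self.f_m >= 0 and self.alias_margin >= -1e-12


@dataclass
class ConnectivityTensor:
    """Windowed correlation estimates for every node pair.

    ``values`` has shape (n_windows, n_pairs) with n_windows = T - 2Δ.
    Zero-variance windows are flagged as NaN (never silently imputed).
    ``window_times`` gives the center sample index of each window.
    """

    values: np.ndarray
    pair_index: list[tuple[int, int]]
    window_times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def temporal_mean(self) -> np.ndarray:
        """Per-pair mean over windows, excluding flagged-missing windows."""
        return np.nanmean(self.values, axis=0)
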