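"""Series/tensor I/O (delimited text + HDF5), run configuration and the
end-to-end pipeline.

HDF5 layouts:

* series file — dataset ``/values`` (nodes x time) with attrs ``fs`` and
  optionally ``band``; generators add ``/true_corr`` / ``/true_states``.
* trFNC file — datasets ``/trfnc`` (windows x pairs), ``/pair_index``,
  ``/window_times``; estimator metadata and a provenance block as attrs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.signal import butter, buttord, sosfilt

from . import __version__
from .data import TimeSeriesSet
from .model import ConnectivityResults, SlidingWindowConnectivity
from .states import ConnectivityStateModel

__all__ = [
    "load_series",
    "save_series",
    "save_trfnc",
    "load_trfnc",
    "RunConfig",
    "bandpass",
    "run_pipeline",
]


def load_series(
    path: str | Path,
    fs: float | None = None,
    band: tuple[float, float] | None = None,
    orientation: str = "nodes-rows",
    delimiter: str | None = None,
) -> TimeSeriesSet:
    """Read a TimeSeriesSet from delimited text or HDF5.

    For text input ``fs`` is required and ``orientation`` declares whether
    nodes are rows or columns.  Non-numeric cells are rejected with their
    location named.
    """
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            fs = float(f["values"].attrs["fs"])
            band_attr = f["values"].attrs.get("band")
            band = tuple(band_attr) if band_attr is not None else None
        return TimeSeriesSet(values, fs=fs, band=band)
    if fs is None:
        raise ValueError("fs is required for text input")
    if delimiter is None:
        delimiter = "\t" if path.suffix in {".tsv", ".txt"} else ","
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            cells = line.strip().split(delimiter)
            row = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                    ) from None
            rows.append(row)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows: row lengths {sorted(lengths)}")
    values = np.asarray(rows)
    if orientation == "nodes-cols":
        values = values.T
    elif orientation != "nodes-rows":
        raise ValueError("orientation must be 'nodes-rows' or 'nodes-cols'")
    return TimeSeriesSet(values, fs=fs, band=band)


def save_series(ts: TimeSeriesSet, path: str | Path, truth=None) -> None:
    """Write a series (and optional simulation truth) to HDF5."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=ts.values)
        d.attrs["fs"] = ts.fs
        if ts.band is not None:
            d.attrs["band"] = ts.band
        if truth is not None:
            f.create_dataset("true_corr", data=np.asarray(truth.true_corr))
            if truth.true_states is not None:
                f.create_dataset("true_states", data=truth.true_states)


def save_trfnc(results: ConnectivityResults, path: str | Path, provenance: dict | None = None) -> None:
    t = results.tensor
    with h5py.File(path, "w") as f:
        d = f.create_dataset("trfnc", data=t.values)
        f.create_dataset("pair_index", data=np.asarray(t.pair_index))
        f.create_dataset("window_times", data=t.window_times)
        for key, val in t.meta.items():
            d.attrs[key] = val
        d.attrs["coordinate_convention"] = "window i (0-based) centers at sample i + half_width"
        d.attrs["package_version"] = __version__
        if provenance:
            d.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_trfnc(path: str | Path):
    """Read back (values, pair_index, window_times, meta) from a trFNC file."""
    with h5py.File(path, "r") as f:
        d = f["trfnc"]
        return (
            d[()],
            [tuple(p) for p in f["pair_index"][()]],
            f["window_times"][()],
            dict(d.attrs),
        )


@dataclass
class RunConfig:
    """Configuration for an end-to-end estimation run."""

    input: str
    fs: float
    window_length: int
    band: tuple[float, float] = (0.01, 0.15)
    f_m: float | str = "auto"
    method: str = "ssb"  # "ssb" | "plain"
    k: int | str | None = None
    seed: int = 0
    out_dir: str = "."
    orientation: str = "nodes-rows"
    bandpass_input: bool = True

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise ValueError(f"window length must be odd and >= 3, got {self.window_length}")
        f_low, f_high = self.band
        if not (0 <= f_low < f_high <= self.fs / 2):
            raise ValueError(f"band {self.band} outside Nyquist range for fs={self.fs}")
        if self.method not in {"ssb", "plain"}:
            raise ValueError("method must be 'ssb' or 'plain'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def bandpass(
    values: np.ndarray,
    fs: float,
    band: tuple[float, float],
    gpass: float = 3.0,
    gstop: float = 30.0,
) -> np.ndarray:
    """Minimum-order Butterworth band-pass (low-pass when f_low = 0).

    Stopband edges at 0.5x the lower passband edge and 1.25x the upper one
    (capped below Nyquist); order from :func:`scipy.signal.buttord`.
    """
    f_low, f_high = band
    nyq = fs / 2
    ws_high = min(1.25 * f_high, 0.99 * nyq)
    if f_low <= 0:
        order, wn = buttord(f_high, ws_high, gpass, gstop, fs=fs)
        sos = butter(order, wn, btype="low", fs=fs, output="sos")
    else:
        order, wn = buttord([f_low, f_high], [0.5 * f_low, ws_high], gpass, gstop, fs=fs)
        sos = butter(order, wn, btype="band", fs=fs, output="sos")
    return sosfilt(sos, np.asarray(values, dtype=float), axis=-1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Band-pass -> estimate -> (optionally) cluster, writing HDF5 artifacts.

    Deterministic given the config seeds; every output carries a provenance
    block (config hash, seed, package version).  Returns a dict of artifact
    paths and fitted objects.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_sha256": cfg.digest(), "seed": cfg.seed, "version": __version__}

    try:
        ts = load_series(cfg.input, fs=cfg.fs, band=cfg.band, orientation=cfg.orientation)
    except Exception as err:
        raise RuntimeError(f"stage 'load' failed: {err}") from err

    if cfg.bandpass_input:
        try:
            ts = TimeSeriesSet(bandpass(ts.values, ts.fs, cfg.band), fs=ts.fs, band=cfg.band)
        except Exception as err:
            raise RuntimeError(f"stage 'bandpass' failed: {err}") from err

    try:
        f_m = 0.0 if cfg.method == "plain" else cfg.f_m
        results = SlidingWindowConnectivity(ts, window=cfg.window_length, f_m=f_m).fit()
    except Exception as err:
        raise RuntimeError(f"stage 'estimate' failed: {err}") from err

    trfnc_path = out_dir / "trfnc.h5"
    save_trfnc(results, trfnc_path, provenance=provenance)
    artifacts = {"trfnc": trfnc_path, "results": results}

    if cfg.k is not None:
        try:
            sm = ConnectivityStateModel(results.values, k=cfg.k)
            states = sm.fit(seed=cfg.seed)
        except Exception as err:
            raise RuntimeError(f"stage 'states' failed: {err}") from err
        states_path = out_dir / "states.h5"
        with h5py.File(states_path, "w") as f:
            f.create_dataset("centroids", data=states.centroids)
            f.create_dataset("labels", data=states.labels)
            f.attrs["k"] = states.states.k
            f.attrs["inertia"] = states.inertia
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)
        artifacts["states"] = states_path
        artifacts["state_results"] = states
    return artifacts
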