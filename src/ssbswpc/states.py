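"""Connectivity-state pipeline: L1 k-means, elbow selection, dwell times,
and robust group comparison of dwell times.

Clustering follows the high-dimensional-connectivity convention: city-block
(Manhattan) distance with k-means++ initialization, the best of ``n_init``
restarts by within-cluster sum of distances, and coordinate-wise-median
centroid updates (the L1-optimal center; a plain mean is not stationary
under the city-block objective).  Group differences in mean dwell time are
tested with a robust linear model (Tukey bisquare weights, tuning constant
4.685) controlling for age, gender and mean framewise displacement, with
Benjamini–Hochberg FDR correction across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StateModel",
    "ConnectivityStateModel",
    "StateResults",
    "cluster_trfnc",
    "elbow_select",
    "mean_dwell_time",
    "group_compare_dwell",
]


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under the city-block distance."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d = cdist(x, centers[:1], metric="cityblock")[:, 0]
    for j in range(1, k):
        total = d.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d / total)
        centers[j] = x[idx]
        d = np.minimum(d, cdist(x, centers[j : j + 1], metric="cityblock")[:, 0])
    return centers


def _lloyd_l1(x: np.ndarray, centers: np.ndarray, max_iter: int, rng: np.random.Generator):
    """Lloyd iterations with L1 assignment and median centroid updates."""
    k = centers.shape[0]
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        dists = cdist(x, centers, metric="cityblock")
        new_labels = dists.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if members.size == 0:
                # re-seed an empty cluster at the point farthest from its center
                far = dists.min(axis=1).argmax()
                centers[j] = x[far]
            else:
                centers[j] = np.median(members, axis=0)
    dists = cdist(x, centers, metric="cityblock")
    labels = dists.argmin(axis=1)
    inertia = float(dists[np.arange(x.shape[0]), labels].sum())
    return centers, labels, inertia


@dataclass
class StateModel:
    """Fitted connectivity states: centroids, per-row labels, inertia."""

    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    k: int
    distance: str = "cityblock"
    n_init: int = 20
    max_iter: int = 500
    seed: int | None = None
    row_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def cluster_trfnc(
    stack: np.ndarray,
    k: int,
    n_init: int = 20,
    max_iter: int = 500,
    seed: int | None = None,
) -> StateModel:
    """City-block k-means over a (rows x pairs) stack of trFNC windows.

    Rows containing flagged-missing (non-finite) values are dropped before
    clustering; their count is reported in the model's ``meta`` and the kept
    rows are recorded in ``row_mask`` so labels can be re-aligned.  The best
    of ``n_init`` k-means++ restarts (lowest within-cluster sum of
    city-block distances) is returned; deterministic given ``seed``.
    """
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    mask = np.all(np.isfinite(stack), axis=1)
    n_dropped = int((~mask).sum())
    x = stack[mask]
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct rows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _kmeans_pp_init(x, k, rng)
        centers, labels, inertia = _lloyd_l1(x, centers.copy(), max_iter, rng)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    centers, labels, inertia = best
    return StateModel(
        centroids=centers,
        labels=labels,
        inertia=inertia,
        k=k,
        n_init=n_init,
        max_iter=max_iter,
        seed=seed,
        row_mask=mask,
        meta={"n_dropped_rows": n_dropped},
    )


def elbow_select(k_values, curve) -> int:
    """Two-line elbow criterion on a within-cluster-distance curve.

    Fits one least-squares line to the left of each interior split point and
    one to the right, keeps the split with the smallest total squared
    residual, and returns the rounded abscissa of the two lines'
    intersection, clamped to the k range.  A degenerate (collinear) curve
    has no elbow: a warning is emitted and the smallest k is returned.
    """
    k_values = np.asarray(list(k_values), dtype=float)
    curve = np.asarray(list(curve), dtype=float)
    if k_values.shape != curve.shape or k_values.size < 4:
        raise ValueError("need >= 4 (k, distance) points")
    best = None
    for s in range(2, k_values.size - 1):
        kl, yl = k_values[:s], curve[:s]
        kr, yr = k_values[s:], curve[s:]
        (m1, b1), res1 = _linefit(kl, yl)
        (m2, b2), res2 = _linefit(kr, yr)
        total = res1 + res2
        if best is None or total < best[0]:
            best = (total, m1, b1, m2, b2)
    _, m1, b1, m2, b2 = best
    scale = max(abs(m1), abs(m2), 1e-12)
    if abs(m1 - m2) < 1e-9 * scale or abs(m1 - m2) < 1e-15:
        warnings.warn("within-cluster distance curve has no elbow (collinear); "
                      "returning the smallest k", RuntimeWarning, stacklevel=2)
        return int(k_values[0])
    x_star = (b2 - b1) / (m1 - m2)
    k_star = int(np.clip(np.rint(x_star), k_values[0], k_values[-1]))
    return k_star


def _linefit(x: np.ndarray, y: np.ndarray):
    coef, res, *_ = np.polyfit(x, y, 1, full=True)
    ss = float(res[0]) if res.size else 0.0
    return (coef[0], coef[1]), ss


def mean_dwell_time(labels: np.ndarray, k: int | None = None) -> dict[int, float]:
    """Mean length (in windows) of maximal runs of each state label.

    States never visited map to NaN when ``k`` is given, and are absent
    otherwise.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change + 1, labels.size]
    run_labels = labels[starts]
    run_lengths = ends - starts
    out: dict[int, float] = {}
    for lab in np.unique(run_labels):
        out[int(lab)] = float(run_lengths[run_labels == lab].mean())
    if k is not None:
        for c in range(k):
            out.setdefault(c, float("nan"))
    return out


def group_compare_dwell(
    dwell: pd.DataFrame,
    alpha: float = 0.05,
    tuning_constant: float = 4.685,
) -> pd.DataFrame:
    """Robust group comparison of per-subject mean dwell times, per cluster.

    ``dwell`` needs columns ``subject, cluster, dwell, group, age, gender,
    meanFD``.  For each cluster a robust linear model
    ``dwell ~ group + age + gender + meanFD`` is fitted with Tukey bisquare
    weights; subjects who never visit the cluster (NaN dwell) are excluded,
    not imputed.  Group p-values are Benjamini–Hochberg adjusted across
    clusters.

    Returns a DataFrame with one row per cluster: effect (group
    coefficient), p, q, significant (q < alpha), and the n used.
    """
    required = {"subject", "cluster", "dwell", "group", "age", "gender", "meanFD"}
    missing = required - set(dwell.columns)
    if missing:
        raise ValueError(f"dwell table missing columns: {sorted(missing)}")
    rows = []
    for cluster, grp in dwell.groupby("cluster"):
        sub = grp.dropna(subset=["dwell"])
        groups = np.unique(sub["group"])
        if len(groups) != 2 or any((sub["group"] == g).sum() < 2 for g in groups):
            raise ValueError(f"cluster {cluster}: need >= 2 subjects per group")
        g = (sub["group"] == groups[1]).astype(float).to_numpy()
        gender = sub["gender"].to_numpy()
        if gender.dtype.kind not in "ifb":
            gender = (gender == np.unique(gender)[1]).astype(float)
        covs = np.column_stack(
            [
                sub["age"].to_numpy(float) - sub["age"].mean(),
                gender - gender.mean(),
                sub["meanFD"].to_numpy(float) - sub["meanFD"].mean(),
            ]
        )
        design = sm.add_constant(np.column_stack([g, covs]))
        rlm = sm.RLM(sub["dwell"].to_numpy(float), design,
                     M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
        res = rlm.fit()
        rows.append(
            dict(cluster=cluster, effect=res.params[1], p=res.pvalues[1],
                 n=len(sub), n_excluded=int(grp["dwell"].isna().sum()))
        )
    out = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    reject, q, *_ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = reject
    return out


class ConnectivityStateModel:
    """Model object wrapping the clustering pipeline for trFNC stacks.

    Parameters
    ----------
    stack : ndarray (rows x pairs) or list of windows x pairs arrays
        Concatenated trFNC windows; a list is stacked and each row tagged
        with its subject of origin.
    k : int or "auto"
        Number of states, or ``"auto"`` to pick k by the two-line elbow
        criterion over ``k_range``.
    """

    def __init__(
        self,
        stack,
        k: int | str = 2,
        n_init: int = 20,
        max_iter: int = 500,
        k_range=range(1, 11),
    ):
        if isinstance(stack, (list, tuple)):
            self.subject_ids = np.concatenate(
                [np.full(np.atleast_2d(s).shape[0], i) for i, s in enumerate(stack)]
            )
            stack = np.vstack([np.atleast_2d(s) for s in stack])
        else:
            stack = np.atleast_2d(np.asarray(stack))
            self.subject_ids = np.zeros(stack.shape[0], dtype=int)
        self.stack = stack
        self.k = k
        self.n_init = n_init
        self.max_iter = max_iter
        self.k_range = list(k_range)

    def fit(self, seed: int | None = None) -> "StateResults":
        if self.k == "auto":
            curve = []
            for k in self.k_range:
                m = cluster_trfnc(self.stack, k, self.n_init, self.max_iter, seed)
                curve.append(m.inertia / self.stack.shape[0])
            k = elbow_select(self.k_range, curve)
        else:
            k = int(self.k)
        model = cluster_trfnc(self.stack, k, self.n_init, self.max_iter, seed)
        return StateResults(self, model)


class StateResults:
    """Fitted states plus dwell-time accessors."""

    def __init__(self, model: ConnectivityStateModel, state_model: StateModel):
        self.model = model
        self.states = state_model

    @property
    def centroids(self) -> np.ndarray:
        return self.states.centroids

    @property
    def labels(self) -> np.ndarray:
        return self.states.labels

    @property
    def inertia(self) -> float:
        return self.states.inertia

    def dwell_table(self) -> pd.DataFrame:
        """Per-(subject, cluster) mean dwell time in windows."""
        subj = self.model.subject_ids[self.states.row_mask]
        rows = []
        for s in np.unique(subj):
            dt = mean_dwell_time(self.labels[subj == s], k=self.states.k)
            for c, v in sorted(dt.items()):
                rows.append(dict(subject=int(s), cluster=int(c), dwell=v))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        counts = np.bincount(self.labels, minlength=self.states.k)
        lines = [
            "Connectivity State Results",
            "=" * 30,
            f"k:            {self.states.k}",
            f"rows:         {self.labels.size} "
            f"(dropped {self.states.meta.get('n_dropped_rows', 0)} flagged)",
            f"inertia (L1): {self.inertia:.4f}",
            "occupancy:    " + ", ".join(f"s{c}={n}" for c, n in enumerate(counts)),
        ]
        return "\n".join(lines)
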