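"""State pipeline tests: L1 k-means, elbow, dwell times, group comparison."""

import numpy as np
import pandas as pd
import pytest

from ssbswpc.states import (
    ConnectivityStateModel,
    cluster_trfnc,
    elbow_select,
    group_compare_dwell,
    mean_dwell_time,
)


def _blobs(rng, n_per=60, d=6, sep=4.0):
    a = rng.standard_normal((n_per, d)) + sep
    b = rng.standard_normal((n_per, d)) - sep
    x = np.vstack([a, b])
    labels = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
    return x, labels


class TestClusterTrfnc:
    def test_separable_blobs_recovered(self, rng):
        x, true = _blobs(rng)
        model = cluster_trfnc(x, k=2, seed=0)
        agreement = max(
            np.mean(model.labels == true), np.mean(model.labels == 1 - true)
        )
        assert agreement == 1.0
        # centroids are coordinate-wise medians of the recovered blobs
        for j in range(2):
            members = x[model.labels == j]
            assert np.allclose(
                model.centroids[j], np.median(members, axis=0), atol=1e-12
            )

    def test_k1_centroid_is_global_median(self, rng):
        x = rng.standard_normal((40, 5))
        model = cluster_trfnc(x, k=1, seed=0)
        assert np.allclose(model.centroids[0], np.median(x, axis=0))

    def test_inertia_is_best_of_restarts_and_decreases_with_k(self, rng):
        x, _ = _blobs(rng, sep=1.0)
        single = cluster_trfnc(x, k=3, n_init=1, seed=5)
        multi = cluster_trfnc(x, k=3, n_init=20, seed=5)
        assert multi.inertia <= single.inertia + 1e-9
        inertias = [cluster_trfnc(x, k=k, seed=0).inertia for k in (1, 2, 3, 4)]
        assert np.all(np.diff(inertias) < 0)

    def test_flagged_rows_dropped(self, rng):
        x, _ = _blobs(rng)
        x[3, 0] = np.nan
        model = cluster_trfnc(x, k=2, seed=0)
        assert model.meta["n_dropped_rows"] == 1
        assert model.labels.size == x.shape[0] - 1
        assert model.row_mask.sum() == x.shape[0] - 1

    def test_deterministic_given_seed(self, rng):
        x, _ = _blobs(rng, sep=0.5)
        a = cluster_trfnc(x, k=3, seed=11)
        b = cluster_trfnc(x, k=3, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_k_exceeding_distinct_rows(self):
        x = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            cluster_trfnc(x, k=2, seed=0)


class TestElbowSelect:
    @staticmethod
    def _piecewise(ks, brk=4.0, s1=-3.0, s2=-0.3):
        ks = np.asarray(ks, float)
        y0 = 20.0
        return np.where(
            ks <= brk, y0 + s1 * (ks - ks[0]), y0 + s1 * (brk - ks[0]) + s2 * (ks - brk)
        )

    def test_exact_breakpoint_recovered(self):
        ks = np.arange(1, 11)
        assert elbow_select(ks, self._piecewise(ks)) == 4

    def test_straight_line_warns_and_returns_smallest(self):
        ks = np.arange(1, 11)
        with pytest.warns(RuntimeWarning, match="no elbow"):
            assert elbow_select(ks, 10.0 - 0.5 * ks) == 1

    def test_noisy_breakpoint_modal_answer(self):
        ks = np.arange(1, 11)
        base = self._piecewise(ks)
        sigma = 0.02 * np.ptp(base)
        answers = [
            elbow_select(ks, base + np.random.default_rng(s).normal(0, sigma, ks.size))
            for s in range(100)
        ]
        vals, counts = np.unique(answers, return_counts=True)
        assert vals[np.argmax(counts)] == 4

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            elbow_select([1, 2, 3], [3, 2, 1])


class TestMeanDwellTime:
    def test_single_state(self):
        assert mean_dwell_time(np.zeros(12, int), k=2) == {0: 12.0, 1: pytest.approx(np.nan, nan_ok=True)}

    def test_alternating(self):
        labels = np.tile([0, 1], 10)
        out = mean_dwell_time(labels)
        assert out == {0: 1.0, 1: 1.0}

    def test_run_length_enumeration(self):
        out = mean_dwell_time(np.array([0, 0, 1, 1, 1, 0]))
        assert out[0] == 1.5 and out[1] == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_dwell_time(np.array([]))


def _dwell_frame(rng, n_per_group=40, shift=0.0, k=3, age_effect=0.0, sigma=2.0):
    rows = []
    for subj in range(2 * n_per_group):
        group = "A" if subj < n_per_group else "B"
        age = rng.normal(35, 10)
        gender = int(rng.integers(2))
        fd = rng.normal(0.2, 0.05)
        for c in range(k):
            dwell = rng.normal(10, sigma) + age_effect * (age - 35)
            if group == "B":
                dwell += shift
            rows.append(
                dict(subject=subj, cluster=c, dwell=dwell, group=group,
                     age=age, gender=gender, meanFD=fd)
            )
    return pd.DataFrame(rows)


class TestGroupCompareDwell:
    def test_shift_detected(self, rng):
        table = group_compare_dwell(_dwell_frame(rng, shift=5.0))
        assert (table["q"] < 0.05).all()
        assert np.all(table["effect"] > 3)

    def test_covariate_only_effect_not_attributed_to_group(self):
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            table = group_compare_dwell(_dwell_frame(rng, k=1, age_effect=0.5))
            hits += int(table["significant"].iloc[0])
        assert hits / 200 <= 0.10

    def test_never_visited_subjects_excluded(self, rng):
        df = _dwell_frame(rng, shift=5.0)
        idx = df.index[(df.cluster == 0) & (df.subject < 3)]
        df.loc[idx, "dwell"] = np.nan
        table = group_compare_dwell(df)
        assert table.loc[table.cluster == 0, "n_excluded"].iloc[0] == 3

    def test_bh_adjustment_monotone_in_p(self, rng):
        table = group_compare_dwell(_dwell_frame(rng, shift=0.5, k=6))
        srt = table.sort_values("p")
        assert np.all(np.diff(srt["q"]) >= -1e-12)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            group_compare_dwell(pd.DataFrame({"subject": [], "dwell": []}))


class TestLabelPermutationInvariance:
    def test_dwell_and_group_test_invariant_to_relabeling(self, rng):
        labels = rng.integers(0, 3, 200)
        base = mean_dwell_time(labels, k=3)
        perm = {0: 2, 1: 0, 2: 1}
        permuted = np.vectorize(perm.get)(labels)
        out = mean_dwell_time(permuted, k=3)
        for old, new in perm.items():
            assert base[old] == out[new]


class TestStateModelInterface:
    def test_fit_returns_dwell_table_per_subject(self, rng):
        blocks = [rng.standard_normal((50, 6)) + s for s in range(3)]
        res = ConnectivityStateModel(blocks, k=2).fit(seed=0)
        table = res.dwell_table()
        assert set(table["subject"]) == {0, 1, 2}
        assert set(table["cluster"]) == {0, 1}
        visited = table.dropna(subset=["dwell"])
        assert (visited["dwell"] >= 1).all()
        assert "k:            2" in res.summary()

    def test_auto_k_uses_elbow(self, rng):
        x, _ = _blobs(rng, sep=6.0)
        res = ConnectivityStateModel(x, k="auto", k_range=range(1, 8), n_init=5).fit(seed=0)
        assert 2 <= res.states.k <= 3
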