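"""Rates, weight-change triggered averages, features, regression, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spnplast import analysis as an
from spnplast import morphology as mo


class TestInstantaneousRate:
    def test_empty_train_gives_zero_series(self):
        _, rate = an.instantaneous_rate(np.empty(0), (0.0, 1.0))
        assert np.all(rate == 0)

    def test_integral_equals_spike_count(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1, 37))
        grid, rate = an.instantaneous_rate(times, (0.0, 1.0), grid_step=0.002)
        integral = rate.sum() * 0.002
        assert integral == pytest.approx(37, rel=0.01)

    def test_poisson_level_recovered(self):
        """100 averaged 20 Hz Poisson trains sit at 20 Hz."""
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(100):
            n = rng.poisson(20)
            times = np.sort(rng.uniform(0, 1, n))
            _, r = an.instantaneous_rate(times, (0.0, 1.0))
            rates.append(r)
        assert np.mean(rates) == pytest.approx(20.0, rel=0.05)

    def test_oversized_grid_step_rejected(self):
        with pytest.raises(ValueError):
            an.instantaneous_rate(np.array([0.5]), (0.0, 1.0), grid_step=0.02)


class TestWCTA:
    def test_one_member_per_bin_returns_member_series(self):
        dw = np.array([-0.3, -0.15, -0.02, 0.0, 0.02, 0.15, 0.3])
        series = np.arange(7 * 4, dtype=float).reshape(7, 4)
        edges = np.array([-np.inf, -0.2, -0.1, -0.01, 0.01, 0.1, 0.2, np.inf])
        res = an.weight_change_triggered_average(dw, series, edges=edges)
        assert np.array_equal(res.counts, np.ones(7, dtype=int) * [1, 1, 1, 1, 1, 1, 1])
        # the near-zero bin holds members 3 (0.0)... each bin one member
        for b in range(7):
            assert np.allclose(res.means[b], series[b]) or res.counts[b] == 1

    def test_opposite_series_cancel_within_bin(self):
        dw = np.array([0.5, 0.5])
        s = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        res = an.weight_change_triggered_average(dw, s, edges=np.array([-np.inf, np.inf]))
        assert np.allclose(res.means[0], 0.0)

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(2)
        dw = rng.normal(0, 0.1, 200)
        series = rng.normal(0, 1, (200, 10))
        res = an.weight_change_triggered_average(dw, series)
        which = np.digitize(dw, res.edges[1:-1])
        df = pd.DataFrame(series)
        df["bin"] = which
        expected = df.groupby("bin").mean()
        for b in expected.index:
            assert np.allclose(res.means[b], expected.loc[b].to_numpy())

    def test_partition_invariants(self):
        rng = np.random.default_rng(3)
        dw = rng.normal(0, 0.1, 300)
        series = rng.normal(0, 1, (300, 5))
        res = an.weight_change_triggered_average(dw, series)
        assert res.counts.sum() == 300
        overall = series.mean(axis=0)
        weighted = np.nansum(
            res.means * res.counts[:, None], axis=0
        ) / res.counts.sum()
        assert np.allclose(weighted, overall)

    def test_degenerate_constant_dw_flagged(self):
        res = an.weight_change_triggered_average(
            np.zeros(10), np.ones((10, 3))
        )
        assert res.degenerate
        assert res.counts.sum() == 10


@pytest.fixture(scope="module")
def mapping(dense_spines):
    return mo.assign_clusters(
        dense_spines, np.arange(40), mo.ClusterConfig(5, 20.0, seed=2)
    )


class TestNeighborCombinedRate:
    def test_combined_rate_equals_merged_train_rate(self, mapping):
        rng = np.random.default_rng(4)
        trains = {
            int(s): np.sort(rng.uniform(0, 1, rng.integers(0, 30)))
            for s in mapping.spine_ids
        }
        sid = int(mapping.spine_ids[0])
        grid, rate, n_used, flagged = an.neighbor_combined_rate(
            sid, mapping, trains, (0.0, 1.0), k=19
        )
        assert n_used == 19 and not flagged
        nn = mapping.nearest_neighbors(sid, 19)
        merged = np.sort(np.concatenate([trains[int(s)] for s in nn]))
        _, expected = an.instantaneous_rate(merged, (0.0, 1.0))
        assert np.allclose(rate, expected)
        # combined count: integral check
        assert rate.sum() * 0.01 == pytest.approx(merged.size, rel=0.01)

    def test_empty_single_neighbor_gives_zero_series(self, mapping):
        trains = {int(s): np.empty(0) for s in mapping.spine_ids}
        _, rate, _, _ = an.neighbor_combined_rate(
            int(mapping.spine_ids[0]), mapping, trains, (0.0, 1.0), k=1
        )
        assert np.all(rate == 0)

    def test_fewer_than_k_neighbors_flagged(self, dense_spines):
        m = mo.assign_clusters(
            dense_spines, np.arange(5), mo.ClusterConfig(1, 0.0, seed=0)
        )
        trains = {int(s): np.array([0.5]) for s in m.spine_ids}
        _, _, n_used, flagged = an.neighbor_combined_rate(
            int(m.spine_ids[0]), m, trains, (0.0, 1.0), k=19
        )
        assert flagged and n_used == 4


class TestTimeSampleFeatures:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_constant_series(self, n):
        f = an.time_sample_features(np.full(100, 10.0), n)
        assert f.shape == (n,)
        assert np.allclose(f, 10.0)

    def test_five_samples_are_200ms_interval_means(self):
        series = np.arange(100, dtype=float)  # 1 s at 10 ms
        f = an.time_sample_features(series, 5)
        expected = series.reshape(5, 20).mean(axis=1)
        assert np.allclose(f, expected)

    def test_single_sample_is_mean_of_five(self):
        rng = np.random.default_rng(5)
        series = rng.normal(size=100)
        f1 = an.time_sample_features(series, 1)
        f5 = an.time_sample_features(series, 5)
        assert f1[0] == pytest.approx(f5.mean())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            an.time_sample_features(np.ones(10), 6)


class TestRandomForest:
    @staticmethod
    def _table(rng, n=500, noise=False):
        x1 = rng.uniform(0, 1, n)
        x2 = rng.uniform(0, 1, n)
        y = rng.normal(0, 1, n) if noise else np.sin(3 * x1) + 2 * x1
        return pd.DataFrame({"f1": x1, "f2": x2, "dw": y})

    def test_importances_sum_to_one_every_fit(self):
        rng = np.random.default_rng(6)
        res = an.rf_predict(
            self._table(rng), ["f1", "f2"], seed=0, n_estimators=50
        )
        assert np.allclose(res.importances.sum(axis=1), 1.0)

    def test_noiseless_monotone_signal_is_predicted(self):
        rng = np.random.default_rng(7)
        res = an.rf_predict(
            self._table(rng), ["f1", "f2"], seed=0, n_estimators=100
        )
        assert res.mean_r2 > 0.95
        assert res.mean_importances[0] > 0.9

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(8)
        res = an.rf_predict(
            self._table(rng, noise=True), ["f1", "f2"], seed=0, n_estimators=100
        )
        assert res.mean_r2 <= 0.05

    def test_train_score_beats_test_score(self):
        rng = np.random.default_rng(9)
        res = an.rf_predict(
            self._table(rng), ["f1", "f2"], seed=0, n_estimators=50
        )
        assert res.r2_train.mean() >= res.r2.mean()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        t = self._table(rng)
        a = an.rf_predict(t, ["f1", "f2"], seed=3, n_estimators=30)
        b = an.rf_predict(t, ["f1", "f2"], seed=3, n_estimators=30)
        assert np.array_equal(a.r2, b.r2)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(11)
        t = self._table(rng)
        t["dw"] = 1.0
        with pytest.raises(ValueError):
            an.rf_predict(t, ["f1"], seed=0)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            an.rf_predict(self._table(rng, n=20), ["f1"], seed=0)


class TestCompareFeatureSets:
    def test_identical_groups_give_zero_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        anova, _ = an.compare_feature_sets(g)
        assert anova["F"].iloc[0] == pytest.approx(0.0)

    def test_disjoint_groups_significant_posthoc(self):
        rng = np.random.default_rng(13)
        g = {"low": rng.uniform(0, 0.1, 20), "high": rng.uniform(0.9, 1.0, 20)}
        _, posthoc = an.compare_feature_sets(g)
        assert posthoc["p"].iloc[0] < 0.01

    def test_f_statistic_matches_sum_of_squares(self):
        rng = np.random.default_rng(14)
        g = {k: rng.normal(i, 1.0, 15) for i, k in enumerate("abc")}
        anova, _ = an.compare_feature_sets(g)
        allv = np.concatenate(list(g.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in g.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in g.values())
        f_hand = (ssb / 2) / (ssw / (45 - 3))
        assert anova["F"].iloc[0] == pytest.approx(f_hand)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            an.compare_feature_sets({"only": [1, 2, 3]})


class TestIsiEventFeatures:
    def test_sign_convention(self):
        events = [(0.505, -1, -0.01)]
        df = an.isi_event_features(events, [0.490], [0.500])
        assert df["dt"].iloc[0] == pytest.approx(+0.010)
        assert df["valid"].iloc[0]
        assert not df["valid2"].iloc[0]

    def test_rate_window_counts(self):
        events = [(0.5, 1, 0.01)]
        pre = [0.46, 0.47, 0.48, 0.40]  # three within the last 50 ms
        df = an.isi_event_features(events, pre, [0.49])
        assert df["pre_rate_hz"].iloc[0] == pytest.approx(60.0)

    def test_missing_spikes_flagged(self):
        df = an.isi_event_features([(0.1, 1, 0.01)], [], [])
        assert not df["valid"].iloc[0]

    def test_matches_brute_force_scan(self):
        """Latest-at-or-before selection equals an exhaustive pair scan."""
        rng = np.random.default_rng(15)
        pre = np.sort(rng.uniform(0, 1, 40))
        post = np.sort(rng.uniform(0, 1, 15))
        events = [(t, 1, 0.01) for t in rng.uniform(0.05, 1, 20)]
        df = an.isi_event_features(events, pre, post)
        for (t_e, _, _), row in zip(events, df.itertuples()):
            pre_before = [t for t in pre if t <= t_e]
            post_before = [t for t in post if t <= t_e]
            if pre_before and post_before:
                assert row.dt == pytest.approx(max(post_before) - max(pre_before))
            if len(pre_before) >= 2:
                assert row.pre1_pre2 == pytest.approx(
                    pre_before[-1] - pre_before[-2]
                )


class TestCorrelate:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = an.correlate(x, x)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        res = an.correlate(x, -2 * x + 3)
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(size=(2, 10))
        res = an.correlate(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert res.r == pytest.approx(num / den)
        assert res.n == 10

    def test_zero_variance_flagged(self):
        res = an.correlate(np.ones(5), np.arange(5.0))
        assert not res.valid
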