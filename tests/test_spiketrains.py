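"""Spike-train generation and the trial-to-trial variability transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

from spnplast import spiketrains as st

from conftest import random_trains


def flat_spec(n_trains, rate, duration, seed=0):
    one = lambda t: np.ones_like(np.asarray(t, dtype=float))
    return st.RateEnsembleSpec(
        n_trains=n_trains,
        trial_duration=duration,
        base_rates=np.full(n_trains, rate),
        shared_modulation=one,
        ramp=one,
        seed=seed,
    )


class TestGenerateCorrelatedTrains:
    def test_zero_rates_give_empty_trains(self):
        trains = st.generate_correlated_trains(flat_spec(10, 0.0, 1.0))
        assert all(t.n_spikes == 0 for t in trains)

    def test_constant_rate_recovers_mean_rate(self):
        # 10 Hz, 1000 s aggregate over 10 trains of 100 s
        trains = st.generate_correlated_trains(flat_spec(10, 10.0, 100.0, seed=2))
        total = sum(t.n_spikes for t in trains)
        assert total / 1000.0 == pytest.approx(10.0, rel=0.03)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            flat_spec(5, 1.0, -1.0)

    def test_shared_modulation_induces_positive_correlation(self):
        """Mean pairwise correlation of binned counts beats a circular-shift null."""

        def mod(t):
            t = np.asarray(t, dtype=float)
            return 1.0 + 0.9 * np.sin(2 * np.pi * 3 * t)

        spec = st.RateEnsembleSpec(
            n_trains=60,
            trial_duration=1.0,
            base_rates=np.full(60, 20.0),
            shared_modulation=mod,
            ramp=lambda t: np.ones_like(np.asarray(t, dtype=float)),
            seed=5,
        )
        trains = st.generate_correlated_trains(spec)
        edges = np.arange(0, 1.0001, 0.05)
        counts = np.array([np.histogram(t.times, edges)[0] for t in trains])

        def mean_pairwise_r(mat):
            c = np.corrcoef(mat)
            iu = np.triu_indices_from(c, k=1)
            return np.nanmean(c[iu])

        observed = mean_pairwise_r(counts)
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            rolled = np.array(
                [np.roll(row, rng.integers(1, row.size)) for row in counts]
            )
            null.append(mean_pairwise_r(rolled))
        assert observed > np.percentile(null, 99)

    def test_reproducible_given_seed(self):
        a = st.generate_correlated_trains(flat_spec(5, 8.0, 2.0, seed=7))
        b = st.generate_correlated_trains(flat_spec(5, 8.0, 2.0, seed=7))
        for x, y in zip(a, b):
            assert np.array_equal(x.times, y.times)


class TestJitter:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        trains = random_trains(rng)
        out = st.jitter_trial(trains, 0.0, seed=3)
        for a, b in zip(trains, out):
            assert np.array_equal(a.times, b.times)

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_per_train_counts_preserved(self, seed):
        rng = np.random.default_rng(seed)
        trains = random_trains(rng)
        out = st.jitter_trial(trains, 0.02, seed=seed)
        assert [t.n_spikes for t in out] == [t.n_spikes for t in trains]
        for t in out:
            if t.n_spikes:
                assert np.all(np.diff(t.times) > 0)
                assert t.times[0] >= 0 and t.times[-1] < t.duration

    def test_displacement_sd_matches_truncated_normal(self):
        # spikes mid-trial far from the boundaries: truncation negligible,
        # and tightly packed so the t-z cross term is negligible too
        times = np.linspace(0.499, 0.501, 100000)
        times = np.unique(times)
        tr = st.SpikeTrain(0, times, 0.0, 1.0)
        out = st.jitter_trial([tr], 0.010, seed=4)[0]
        # displacement per spike is not defined after re-sorting; use the
        # variance identity: var(new) = var(old) + sigma^2 for independent jitter
        sd_disp = np.sqrt(np.var(out.times) - np.var(times))
        assert sd_disp == pytest.approx(0.010, rel=0.02)

    def test_large_sigma_approaches_uniform(self):
        times = np.full(20000, 0.5) + np.linspace(0, 1e-6, 20000)
        tr = st.SpikeTrain(0, np.unique(times), 0.0, 1.0)
        out = st.jitter_trial([tr], 50.0, seed=5)[0]
        d, p = stats.kstest(out.times, "uniform")
        assert p > 0.01


class TestMoveSpikes:
    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(2)
        trains = random_trains(rng)
        out = st.move_spikes(trains, 0.0, seed=1)
        for a, b in zip(trains, out):
            assert np.array_equal(a.times, b.times)

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_total_count_conserved(self, seed):
        rng = np.random.default_rng(seed)
        trains = random_trains(rng, n_trains=6)
        out = st.move_spikes(trains, 0.5, seed=seed)
        assert sum(t.n_spikes for t in out) == sum(t.n_spikes for t in trains)

    def test_single_train_rejected(self):
        tr = st.SpikeTrain(0, np.array([0.1, 0.2]), 0.0, 1.0)
        with pytest.raises(ValueError):
            st.move_spikes([tr], 0.5, seed=0)

    def test_destination_frequencies_proportional_to_counts(self):
        """With p=1, pooled destinations follow the count weights (chi-square)."""
        rng = np.random.default_rng(3)
        counts = (10, 20, 70)
        trains = [
            st.SpikeTrain(i, np.unique(rng.uniform(0, 1, n)), 0.0, 1.0)
            for i, n in enumerate(counts)
        ]
        total = np.zeros(3)
        for rep in range(100):
            out = st.move_spikes(trains, 1.0, seed=rep)
            total += [t.n_spikes for t in out]
        expected = np.array(counts) / sum(counts) * total.sum()
        chi2 = ((total - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=2)
        assert p > 0.01


class TestShuffleIsis:
    def test_zero_or_one_spike_identity(self):
        for times in (np.empty(0), np.array([0.3])):
            tr = st.SpikeTrain(0, times, 0.0, 1.0)
            assert st.shuffle_isis(tr, 1) is tr

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_isi_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        times = np.unique(rng.uniform(0, 1, 40))
        if times.size < 2:
            return
        tr = st.SpikeTrain(0, times, 0.0, 1.0)
        out = st.shuffle_isis(tr, seed)
        assert out.n_spikes == tr.n_spikes
        assert out.times[0] == tr.times[0]
        assert np.allclose(
            np.sort(np.diff(out.times)), np.sort(np.diff(tr.times))
        )

    def test_rank_correlation_near_zero_on_average(self):
        rng = np.random.default_rng(9)
        times = np.unique(np.cumsum(rng.exponential(0.01, 100)))
        tr = st.SpikeTrain(0, times, 0.0, float(times[-1]) + 0.01)
        isis = np.diff(tr.times)
        rs = []
        for seed in range(200):
            out = st.shuffle_isis(tr, seed)
            rs.append(stats.spearmanr(isis, np.diff(out.times)).statistic)
        assert abs(np.mean(rs)) < 0.05


class TestPoissonInhibition:
    def test_zero_rate_empty(self):
        assert st.generate_poisson_inhibition(0.0, 10.0, 1).n_spikes == 0

    @pytest.mark.parametrize("rate", [12.0, 8.0])
    def test_rate_recovered(self, rate):
        tr = st.generate_poisson_inhibition(rate, 1000.0, seed=42)
        assert tr.n_spikes / 1000.0 == pytest.approx(rate, rel=0.03)

    def test_isi_cv_near_one(self):
        tr = st.generate_poisson_inhibition(12.0, 1000.0, seed=7)
        isi = np.diff(tr.times)
        assert isi.std() / isi.mean() == pytest.approx(1.0, abs=0.05)


class TestBuildExperiment:
    def test_single_trial_no_variability_is_offset_input(self, small_trial):
        ts = st.build_experiment(small_trial, 1, 1.0, seed=0, lead_in=1.0)
        assert ts.n_trials == 1
        for a, b in zip(small_trial, ts.trains[0]):
            assert np.allclose(b.times, a.times + 1.0)

    def test_zero_jitter_repetitions_identical(self, small_trial):
        var = st.VariabilitySpec("jitter", sigma=0.0, seed=1)
        ts = st.build_experiment(small_trial, 10, 1.0, var, seed=0)
        ref = ts.trains[0]
        for k, (t0, _) in enumerate(ts.trials):
            for a, b in zip(ref, ts.trains[k]):
                assert np.allclose(b.times - t0, a.times - ts.trials[0][0])

    def test_no_spikes_in_intertrial_gaps(self, small_trial):
        var = st.VariabilitySpec("jitter", sigma=0.1, seed=1)
        ts = st.build_experiment(small_trial, 10, 1.0, var, seed=0)
        all_times = np.concatenate(
            [tr.times for trial in ts.trains for tr in trial]
        )
        in_trial = np.zeros(all_times.size, dtype=bool)
        for t0, t1 in ts.trials:
            in_trial |= (all_times >= t0) & (all_times < t1)
        assert in_trial.all()

    def test_default_layout_gives_21_s(self, small_trial):
        ts = st.build_experiment(small_trial, 10, 1.0, seed=0, lead_in=1.0)
        assert ts.total_duration == pytest.approx(21.0)


def test_roundtrip_npz_container(tmp_path, small_trial):
    path = tmp_path / "trains.npz"
    st.write_trains_npz(path, small_trial)
    back = {t.train_id: t for t in st.read_trains_npz(path)}
    for tr in small_trial:
        assert np.array_equal(back[tr.train_id].times, tr.times)


def test_roundtrip_delimited_io(tmp_path, small_trial):
    path = tmp_path / "trains.tsv"
    st.write_trains(path, small_trial)
    back = st.read_trains(path, 0.0, 1.0)
    by_id = {t.train_id: t for t in back}
    for tr in small_trial:
        if tr.n_spikes:
            assert np.allclose(by_id[tr.train_id].times, tr.times)
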