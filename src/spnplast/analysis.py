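"""Statistical analyses relating input patterns to synaptic weight change.

Provides the weight-change triggered average (WCTA) — the average of a
per-synapse time series (presynaptic firing rate or spine calcium) within
bins of per-trial weight change — plus Gaussian-kernel instantaneous firing
rates, neighbour-combined rates, coarse time-sample features, random-forest
regression of weight change with feature importances, one-way ANOVA with
post-hoc Welch t-tests over feature sets, spike-pair features around
instantaneous weight-change events, and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WCTAResult",
    "RFResult",
    "CorrelationResult",
    "instantaneous_rate",
    "weight_change_triggered_average",
    "neighbor_combined_rate",
    "time_sample_features",
    "rf_predict",
    "compare_feature_sets",
    "isi_event_features",
    "correlate",
]


def instantaneous_rate(
    spike_times,
    window: tuple[float, float],
    grid: np.ndarray | None = None,
    sigma: float = 0.05,
    grid_step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel instantaneous firing rate (Hz) on a time grid.

    The kernel (SD ``sigma`` seconds, default 50 ms) is reflected at the
    window edges so the integral of the rate over the window equals the
    spike count.  Returns ``(grid, rate)``.
    """
    t0, t1 = window
    if grid is None:
        if grid_step > 0.010 + 1e-12:
            raise ValueError("grid step must be <= 10 ms")
        grid = np.arange(t0 + grid_step / 2, t1, grid_step)
    times = np.asarray(spike_times, dtype=float)
    times = times[(times >= t0) & (times < t1)]
    if times.size == 0:
        return grid, np.zeros_like(grid)
    # reflect spikes at both edges to conserve kernel mass inside the window
    pts = np.concatenate([times, 2 * t0 - times, 2 * t1 - times])
    d = grid[:, None] - pts[None, :]
    rate = np.exp(-0.5 * (d / sigma) ** 2).sum(axis=1) / (
        sigma * np.sqrt(2 * np.pi)
    )
    return grid, rate


@dataclass(frozen=True)
class WCTAResult:
    """Per-bin mean time series with the bin definition that produced it."""

    edges: np.ndarray       # (n_bins + 1,) weight-change bin edges
    counts: np.ndarray      # (n_bins,) members per bin
    means: np.ndarray       # (n_bins, n_time) NaN where a bin is empty
    t: np.ndarray
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def wcta_bin_edges(dw: np.ndarray, n_bins: int = 7) -> np.ndarray:
    """Symmetric weight-change bin edges with a dedicated near-zero bin.

    The outer scale is the 95th percentile of |dw|; the near-zero band is a
    tenth of it.  With the default 7 bins the edges are
    ``(-inf, -a, -a/2, -z, z, a/2, a, inf)``.
    """
    if n_bins != 7:
        # general fallback: quantile edges
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.quantile(dw, qs)
        edges[0], edges[-1] = -np.inf, np.inf
        return edges
    a = float(np.percentile(np.abs(dw), 95))
    if a <= 0:
        a = max(float(np.abs(dw).max()), 1e-12)
    z = a / 10.0
    return np.array([-np.inf, -a, -a / 2, -z, z, a / 2, a, np.inf])


def weight_change_triggered_average(
    dw: np.ndarray,
    series: np.ndarray,
    t: np.ndarray | None = None,
    n_bins: int = 7,
    edges: np.ndarray | None = None,
) -> WCTAResult:
    """Group synapse-trials into weight-change bins and average their series.

    ``dw`` has one entry per synapse-trial; ``series`` is (n_synapse_trials,
    n_time) on a common grid.  Empty bins are reported with count 0 and NaN
    means.  If every dw is identical the output is a flagged single-bin
    degenerate result.
    """
    dw = np.asarray(dw, dtype=float)
    series = np.asarray(series, dtype=float)
    if series.shape[0] != dw.size:
        raise ValueError("series must have one row per synapse-trial")
    if t is None:
        t = np.arange(series.shape[1], dtype=float)
    if np.all(dw == dw[0]):
        return WCTAResult(
            edges=np.array([-np.inf, np.inf]),
            counts=np.array([dw.size]),
            means=series.mean(axis=0, keepdims=True),
            t=t,
            degenerate=True,
        )
    if edges is None:
        edges = wcta_bin_edges(dw, n_bins)
    which = np.digitize(dw, edges[1:-1])
    nb = len(edges) - 1
    counts = np.bincount(which, minlength=nb)
    means = np.full((nb, series.shape[1]), np.nan)
    for b in range(nb):
        if counts[b]:
            means[b] = series[which == b].mean(axis=0)
    return WCTAResult(edges=np.asarray(edges), counts=counts, means=means, t=t)


def neighbor_combined_rate(
    spine_id: int,
    mapping,
    trains_by_spine: dict,
    window: tuple[float, float],
    k: int = 19,
    sigma: float = 0.05,
    grid_step: float = 0.01,
):
    """Rate of the merged spike train of the k nearest assigned neighbours.

    Neighbours are ordered by dendritic path distance (ties by spine id,
    module cluster_mapping convention).  If fewer than k neighbours exist
    all are used and the result is flagged.  Returns
    ``(grid, rate, n_used, flagged)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nn = mapping.nearest_neighbors(spine_id, k)
    flagged = nn.size < k
    times = [np.asarray(trains_by_spine[int(s)], dtype=float) for s in nn]
    merged = np.sort(np.concatenate(times)) if times else np.empty(0)
    grid, rate = instantaneous_rate(merged, window, sigma=sigma, grid_step=grid_step)
    return grid, rate, int(nn.size), flagged


def time_sample_features(series: np.ndarray, n_samples: int) -> np.ndarray:
    """Mean of the series over ``n_samples`` equal consecutive intervals.

    One sample is the trial mean; five samples are means over consecutive
    200 ms fifths of a 1 s trial.
    """
    if not 1 <= n_samples <= 5:
        raise ValueError("n_samples must be in 1..5")
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n % n_samples == 0:
        return series.reshape(*series.shape[:-1], n_samples, n // n_samples).mean(
            axis=-1
        )
    chunks = np.array_split(series, n_samples, axis=-1)
    return np.stack([c.mean(axis=-1) for c in chunks], axis=-1)


@dataclass(frozen=True)
class RFResult:
    """Random-forest regression scores and importances over repeated splits."""

    feature_names: list
    r2: np.ndarray            # test-set R^2 per split
    r2_train: np.ndarray
    importances: np.ndarray   # (n_splits, n_features), each row sums to 1

    @property
    def mean_r2(self) -> float:
        return float(self.r2.mean())

    @property
    def se_r2(self) -> float:
        return float(self.r2.std(ddof=1) / np.sqrt(self.r2.size))

    @property
    def mean_importances(self) -> np.ndarray:
        return self.importances.mean(axis=0)


def rf_predict(
    table: pd.DataFrame,
    features: list,
    response: str = "dw",
    n_sets: int = 5,
    n_repeats: int = 4,
    test_fraction: float = 0.25,
    seed: int = 0,
    n_estimators: int = 500,
) -> RFResult:
    """Random-forest regression of weight change on the chosen features.

    For each of ``n_sets x n_repeats`` random train/test splits (75/25 by
    default, 20 regressions) a forest is fitted and the test-set coefficient
    of determination and normalised feature importances recorded.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import train_test_split

    if len(table) < 50:
        raise ValueError("need at least 50 rows for the regression")
    y = table[response].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant response: R^2 undefined")
    X = table[list(features)].to_numpy(dtype=float)
    rng = np.random.SeedSequence(seed)
    split_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(n_sets * n_repeats)]
    r2, r2_train, imps = [], [], []
    for s in split_seeds:
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_fraction, random_state=s
        )
        rf = RandomForestRegressor(
            n_estimators=n_estimators, random_state=s, n_jobs=1
        )
        rf.fit(Xtr, ytr)
        r2.append(rf.score(Xte, yte))
        r2_train.append(rf.score(Xtr, ytr))
        imps.append(rf.feature_importances_)
    return RFResult(
        feature_names=list(features),
        r2=np.asarray(r2),
        r2_train=np.asarray(r2_train),
        importances=np.asarray(imps),
    )


def compare_feature_sets(groups: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA over groups of scores plus pairwise Welch t-tests.

    ``groups`` maps a label to a vector of prediction scores.  Post-hoc
    tests are Welch t-tests without multiplicity correction (reported as
    such).  Returns ``(anova_table, posthoc_table)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    anova = pd.DataFrame(
        {
            "F": [f],
            "p": [p],
            "df_between": [len(arrays) - 1],
            "df_within": [n_total - len(arrays)],
        }
    )
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, pp = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
            rows.append((names[i], names[j], t, pp))
    posthoc = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    return anova, posthoc


def isi_event_features(
    events,
    pre_times,
    post_times,
    rate_window: float = 0.05,
) -> pd.DataFrame:
    """Spike-pair features around instantaneous weight-change events.

    Per event at time ``t_e`` (seconds): dt = t_post - t_pre with the latest
    pre- and post-synaptic spikes at or before the event (positive when pre
    precedes post); dt2 using the second-latest pre spike; the pre1-pre2
    interval; and the presynaptic rate over the ``rate_window`` before the
    event.  Events without the required spikes are flagged (``valid`` /
    ``valid2``) so downstream regressions can exclude them.
    """
    pre = np.sort(np.asarray(pre_times, dtype=float))
    post = np.sort(np.asarray(post_times, dtype=float))
    rows = []
    for ev in events:
        t_e, direction, magnitude = ev
        ip = np.searchsorted(pre, t_e, side="right") - 1
        io = np.searchsorted(post, t_e, side="right") - 1
        pre1 = pre[ip] if ip >= 0 else np.nan
        pre2 = pre[ip - 1] if ip >= 1 else np.nan
        post1 = post[io] if io >= 0 else np.nan
        dt = post1 - pre1 if ip >= 0 and io >= 0 else np.nan
        dt2 = post1 - pre2 if ip >= 1 and io >= 0 else np.nan
        pre12 = pre1 - pre2 if ip >= 1 else np.nan
        n_rate = np.count_nonzero((pre > t_e - rate_window) & (pre <= t_e))
        rows.append(
            {
                "t_event": t_e,
                "direction": direction,
                "magnitude": magnitude,
                "dt": dt,
                "dt2": dt2,
                "pre1_pre2": pre12,
                "pre_rate_hz": n_rate / rate_window,
                "valid": bool(ip >= 0 and io >= 0),
                "valid2": bool(ip >= 1 and io >= 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    valid: bool = True


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p-value and sample size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with N >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, int(x.size), valid=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))
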