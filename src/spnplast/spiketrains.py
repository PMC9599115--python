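"""In-vivo-like cortical spike trains and trial-to-trial variability transforms.

A single behavioural trial is represented as a list of :class:`SpikeTrain`
objects over a common window.  Excitatory trains emulate anterior lateral
motor cortex activity: heterogeneous (log-normal) per-train mean rates, one
shared multiplicative rate modulation that induces within-trial correlations
between trains, and an optional late-trial rate ramp consistent with motor
preparatory activity.  Three surrogate transforms produce controlled
trial-to-trial variability — spike-time jitter from a truncated normal,
moving spikes between trains, and interspike-interval shuffling — plus
homogeneous Poisson inhibitory trains (fast-spiking and low-threshold-spiking
interneuron inputs at 12 and 8 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "SpikeTrain",
    "TrialSet",
    "RateEnsembleSpec",
    "VariabilitySpec",
    "generate_correlated_trains",
    "jitter_trial",
    "move_spikes",
    "shuffle_isis",
    "generate_poisson_inhibition",
    "build_experiment",
    "default_ensemble_spec",
    "write_trains",
    "read_trains",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) of one presynaptic input, confined to [t_start, t_stop)."""

    train_id: int
    times: np.ndarray
    t_start: float = 0.0
    t_stop: float = 1.0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < self.t_start or times[-1] >= self.t_stop:
                raise ValueError(
                    f"spikes outside window [{self.t_start}, {self.t_stop}) "
                    f"in train {self.train_id}"
                )
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must exceed t_start")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def shifted(self, offset: float) -> "SpikeTrain":
        return SpikeTrain(
            self.train_id,
            self.times + offset,
            self.t_start + offset,
            self.t_stop + offset,
        )


@dataclass(frozen=True)
class TrialSet:
    """Repeated trials on a global timeline, each holding one list of trains.

    ``trials[k]`` is the window (start, stop) of repetition k; ``trains[k]``
    are the spike trains of that repetition, already offset onto the global
    timeline.  Consecutive trials are separated by ``intertrial_interval``
    seconds of silence (during which only inhibition is active).
    """

    trials: tuple
    trains: tuple
    intertrial_interval: float

    def __post_init__(self):
        prev_stop = -np.inf
        for (t0, t1), trial_trains in zip(self.trials, self.trains):
            if t0 < prev_stop:
                raise ValueError("trial windows must be ordered and non-overlapping")
            prev_stop = t1
            for tr in trial_trains:
                if tr.times.size and (tr.times[0] < t0 or tr.times[-1] >= t1):
                    raise ValueError("train spikes outside its trial window")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_duration(self) -> float:
        return self.trials[-1][1] + self.intertrial_interval if self.trials else 0.0


@dataclass(frozen=True)
class RateEnsembleSpec:
    """Specification of the correlated inhomogeneous-Poisson train ensemble.

    Rate of train i at time t is ``base_rates[i] * shared_modulation(t) * ramp(t)``;
    the shared profiles are common to all trains, which is what induces the
    pairwise correlations between them.
    """

    n_trains: int
    trial_duration: float
    base_rates: np.ndarray
    shared_modulation: Callable[[np.ndarray], np.ndarray]
    ramp: Callable[[np.ndarray], np.ndarray]
    seed: int

    def __post_init__(self):
        rates = np.asarray(self.base_rates, dtype=float)
        object.__setattr__(self, "base_rates", rates)
        if self.trial_duration <= 0:
            raise ValueError("trial duration must be positive")
        if rates.shape != (self.n_trains,):
            raise ValueError("base_rates must have length n_trains")
        if np.any(rates < 0):
            raise ValueError("base rates must be non-negative")


@dataclass(frozen=True)
class VariabilitySpec:
    """One trial-to-trial variability transform with its parameters."""

    kind: str  # 'jitter' | 'move' | 'shuffle_isi' | 'none'
    sigma: float = 0.0       # jitter SD (s)
    p_move: float = 0.0      # move probability
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("jitter", "move", "shuffle_isi", "none"):
            raise ValueError(f"unknown variability kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.p_move <= 1.0:
            raise ValueError("p_move must lie in [0, 1]")


def _raised_cosine_bump(center: float, width: float, amplitude: float):
    """Multiplier profile: 1 everywhere, plus a raised-cosine bump of given
    extra amplitude centred at `center` with full width `width`."""

    def profile(t):
        t = np.asarray(t, dtype=float)
        x = (t - center) / (width / 2.0)
        bump = np.where(np.abs(x) < 1.0, 0.5 * (1 + np.cos(np.pi * x)), 0.0)
        return 1.0 + amplitude * bump

    return profile


def default_ensemble_spec(
    n_trains: int = 200,
    trial_duration: float = 1.0,
    seed: int = 0,
    median_rate: float = 4.0,
    rate_sigma: float = 0.8,
    ramp_amplitude: float = 2.0,
    ramp: bool = True,
) -> RateEnsembleSpec:
    """Default in-vivo-like ensemble.

    Per-train mean rates are log-normal (median ``median_rate`` Hz, log-SD
    ``rate_sigma``) so a minority of trains carry most spikes; the shared
    modulation is a slow half-sinusoid (mean 1); the ramp is a raised-cosine
    bump peaking in the last 300 ms of the trial (motor preparatory activity),
    switched off with ``ramp=False``.
    """
    rng = np.random.default_rng(seed)
    base = median_rate * np.exp(rng.normal(0.0, rate_sigma, size=n_trains))

    def shared_modulation(t):
        t = np.asarray(t, dtype=float)
        # slow common fluctuation, strictly positive, mean ~1
        return 1.0 + 0.4 * np.sin(2 * np.pi * t / trial_duration)

    if ramp:
        ramp_fn = _raised_cosine_bump(
            center=trial_duration - 0.15, width=0.3, amplitude=ramp_amplitude
        )
    else:
        ramp_fn = lambda t: np.ones_like(np.asarray(t, dtype=float))

    return RateEnsembleSpec(
        n_trains=n_trains,
        trial_duration=trial_duration,
        base_rates=base,
        shared_modulation=shared_modulation,
        ramp=ramp_fn,
        seed=seed,
    )


def generate_correlated_trains(spec: RateEnsembleSpec) -> list[SpikeTrain]:
    """Draw one trial of correlated trains by thinning a homogeneous Poisson.

    Each train is an inhomogeneous Poisson process with rate
    ``base_rate * shared_modulation(t) * ramp(t)``; correlations between
    trains arise purely from the shared profiles.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.trial_duration
    grid = np.linspace(0.0, T, 2049)
    profile = spec.shared_modulation(grid) * spec.ramp(grid)
    if np.any(profile < 0):
        raise ValueError("shared modulation and ramp must be non-negative")
    pmax = float(profile.max()) if profile.size else 0.0

    trains = []
    for i in range(spec.n_trains):
        lam_max = spec.base_rates[i] * pmax
        if lam_max <= 0:
            trains.append(SpikeTrain(i, np.empty(0), 0.0, T))
            continue
        n_cand = rng.poisson(lam_max * T)
        cand = np.sort(rng.uniform(0.0, T, size=n_cand))
        lam = spec.base_rates[i] * np.interp(cand, grid, profile)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam
        times = np.unique(cand[keep])
        trains.append(SpikeTrain(i, times, 0.0, T))
    return trains


def jitter_trial(
    trains: Sequence[SpikeTrain], sigma: float, seed: int
) -> list[SpikeTrain]:
    """Jitter every spike by a truncated normal(0, sigma) kept inside the window.

    Sampling is by inverse CDF on the truncated interval so the draw is exact
    and reproducible; per-train spike counts are preserved and output times
    are re-sorted.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return list(trains)
    rng = np.random.default_rng(seed)
    out = []
    for tr in trains:
        t = tr.times
        if t.size == 0:
            out.append(tr)
            continue
        a = (tr.t_start - t) / sigma
        b = (tr.t_stop - t) / sigma
        fa, fb = ndtr(a), ndtr(b)
        u = rng.uniform(size=t.size)
        z = ndtri(fa + u * (fb - fa))
        new = np.sort(t + sigma * z)
        # guard against the open upper bound under float rounding
        new = np.clip(new, tr.t_start, np.nextafter(tr.t_stop, -np.inf))
        new = _strictify(new, tr.t_start, tr.t_stop)
        out.append(SpikeTrain(tr.train_id, new, tr.t_start, tr.t_stop))
    return out


def move_spikes(
    trains: Sequence[SpikeTrain], p_move: float, seed: int
) -> list[SpikeTrain]:
    """Move each spike, with probability ``p_move``, to a train drawn with
    probability proportional to the pre-move spike count of the target train.

    A moved spike keeps its time; the draw is over all trains (a draw of the
    source train leaves the spike in place), so pooled destination frequencies
    are proportional to the pre-move counts.  Total spike count is conserved.
    """
    if not 0.0 <= p_move <= 1.0:
        raise ValueError("p_move must lie in [0, 1]")
    if p_move > 0 and len(trains) < 2:
        raise ValueError("move_spikes needs at least two trains (no valid target)")
    if p_move == 0:
        return list(trains)
    rng = np.random.default_rng(seed)
    counts = np.array([tr.n_spikes for tr in trains], dtype=float)
    if counts.sum() == 0:
        return list(trains)
    weights = counts / counts.sum()
    dest_times: list[list[float]] = [[] for _ in trains]
    for i, tr in enumerate(trains):
        if tr.n_spikes == 0:
            continue
        moved = rng.uniform(size=tr.n_spikes) < p_move
        targets = np.full(tr.n_spikes, i)
        if moved.any():
            targets[moved] = rng.choice(len(trains), size=int(moved.sum()), p=weights)
        for t, j in zip(tr.times, targets):
            dest_times[j].append(t)
    out = []
    for i, tr in enumerate(trains):
        times = np.sort(np.asarray(dest_times[i], dtype=float))
        times = _strictify(times, tr.t_start, tr.t_stop)
        out.append(SpikeTrain(tr.train_id, times, tr.t_start, tr.t_stop))
    return out


def shuffle_isis(train: SpikeTrain, seed: int) -> SpikeTrain:
    """Permute the order of the interspike intervals of one train.

    The first spike stays anchored at its original time, so train start and
    total span are preserved; trains with fewer than two spikes are returned
    unchanged.
    """
    if train.n_spikes < 2:
        return train
    rng = np.random.default_rng(seed)
    isis = np.diff(train.times)
    shuffled = rng.permutation(isis)
    times = train.times[0] + np.concatenate(([0.0], np.cumsum(shuffled)))
    return SpikeTrain(train.train_id, times, train.t_start, train.t_stop)


def generate_poisson_inhibition(
    rate_hz: float, duration: float, seed: int, train_id: int = 0, t_start: float = 0.0
) -> SpikeTrain:
    """Homogeneous Poisson train over the full experiment duration."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration)
    times = t_start + np.sort(rng.uniform(0.0, duration, size=n))
    times = _strictify(times, t_start, t_start + duration)
    return SpikeTrain(train_id, times, t_start, t_start + duration)


def apply_variability(
    trains: Sequence[SpikeTrain], spec: VariabilitySpec, seed: int
) -> list[SpikeTrain]:
    """Apply one variability transform (dispatch on ``spec.kind``)."""
    if spec.kind == "none":
        return list(trains)
    if spec.kind == "jitter":
        return jitter_trial(trains, spec.sigma, seed)
    if spec.kind == "move":
        return move_spikes(trains, spec.p_move, seed)
    if spec.kind == "shuffle_isi":
        ss = np.random.SeedSequence(seed).spawn(len(trains))
        return [
            shuffle_isis(tr, int(s.generate_state(1)[0] % (2**31)))
            for tr, s in zip(trains, ss)
        ]
    raise ValueError(spec.kind)


def build_experiment(
    trial_trains: Sequence[SpikeTrain],
    n_trials: int,
    intertrial_interval: float = 1.0,
    variability: VariabilitySpec | None = None,
    seed: int = 0,
    lead_in: float = 1.0,
) -> TrialSet:
    """Lay out ``n_trials`` repetitions of the initial trial on a global timeline.

    The timeline is ``lead_in`` seconds of silence, then each trial followed by
    ``intertrial_interval`` seconds of silence (10 one-second trials with 1 s
    intervals and a 1 s lead-in give the 21 s experiment duration).  Every
    repetition applies the variability transform to the INITIAL trial, never
    cumulatively.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trial_dur = trial_trains[0].duration if trial_trains else 1.0
    windows = []
    per_trial = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_trials)
    for k in range(n_trials):
        t0 = lead_in + k * (trial_dur + intertrial_interval)
        windows.append((t0, t0 + trial_dur))
        if variability is None or variability.kind == "none":
            rep = list(trial_trains)
        else:
            rep = apply_variability(
                trial_trains,
                variability,
                int(child_seeds[k].generate_state(1)[0] % (2**31)),
            )
        per_trial.append(tuple(tr.shifted(t0 - tr.t_start) for tr in rep))
    return TrialSet(tuple(windows), tuple(per_trial), intertrial_interval)


def _strictify(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Nudge exactly-coincident sorted times apart so ordering is strict."""
    if times.size < 2:
        return times
    out = times.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = np.nextafter(out[i - 1], np.inf)
    if out.size and out[-1] >= t1:
        out = out[out < t1]
    return out


# ---------------------------------------------------------------------------
# I/O: delimited text (train_id, spike_time_s) and a compact npz container
# ---------------------------------------------------------------------------

def write_trains(path, trains: Sequence[SpikeTrain]) -> None:
    """Write trains as UTF-8 TSV with header ``train_id\tspike_time_s``."""
    import pandas as pd

    rows = []
    for tr in trains:
        for t in tr.times:
            rows.append((tr.train_id, t))
    df = pd.DataFrame(rows, columns=["train_id", "spike_time_s"])
    df.to_csv(path, sep="\t", index=False)


def read_trains(path, t_start: float = 0.0, t_stop: float | None = None) -> list[SpikeTrain]:
    """Read the delimited format back into SpikeTrain objects."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if t_stop is None:
        t_stop = float(df["spike_time_s"].max()) + 1e-9 if len(df) else 1.0
    out = []
    for tid, grp in df.groupby("train_id"):
        times = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        out.append(SpikeTrain(int(tid), times, t_start, t_stop))
    return out


def write_trains_npz(path, trains: Sequence[SpikeTrain]) -> None:
    """Compact binary container keyed by train id (runtime output only)."""
    arrays = {f"train_{tr.train_id}": tr.times for tr in trains}
    meta = np.array(
        [[tr.train_id, tr.t_start, tr.t_stop] for tr in trains], dtype=float
    )
    np.savez_compressed(path, __meta__=meta, **arrays)


def read_trains_npz(path) -> list[SpikeTrain]:
    with np.load(path) as z:
        meta = z["__meta__"]
        return [
            SpikeTrain(int(tid), z[f"train_{int(tid)}"], t0, t1)
            for tid, t0, t1 in meta
        ]
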