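"""Dual amplitude/duration calcium-threshold synaptic weight update rule.

Spine calcium must exceed an amplitude threshold continuously for longer than
a duration threshold before the weight moves: a brief, high-amplitude calcium
elevation (above ``t_ap`` = 0.53 µM for more than ``dur_p`` = 3.3 ms)
potentiates, while a prolonged moderate elevation (above ``t_ad`` = 0.33 µM —
but not above ``t_ap`` — for more than ``dur_d`` = 28 ms) depresses.  While a
criterion is met the weight is updated every step with a soft-bounded step::

    LTP:  dw = min(g_p_max, g_p * (Ca - t_ap)) * dt * (1 - (w - w_min)/(w_max - w_min))
    LTD:  dw = -min(g_d_max, g_d * (Ca - t_ad)) * dt * (w - w_min)/(w_max - w_min)

so w asymptotes at ``w_max`` = 2 and ``w_min`` = 0.  Gains are per ms so the
trajectory is step-size invariant on smooth traces.  Threshold and duration
comparisons are strict; the excursion timers reset whenever calcium drops to
or below the corresponding amplitude threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "WeightTrace",
    "update_weights",
    "detect_plasticity_events",
    "amplitude_threshold_scan",
    "duration_threshold_scan",
]

_TIME_TOL = 1e-9  # ms; duration ties at machine precision count as not-exceeded


@dataclass(frozen=True)
class PlasticityParams:
    """Rule constants.  Thresholds in µM, durations in ms, gains per ms.

    The two amplitude thresholds and two duration thresholds are measured
    values; the gains are free constants of the rule, chosen so a 100 ms
    square pulse at 1 µM moves w from 1.0 by about +0.1.
    """

    t_ad: float = 0.33     # µM, LTD amplitude threshold
    t_ap: float = 0.53     # µM, LTP amplitude threshold
    dur_d: float = 28.0    # ms, LTD duration threshold
    dur_p: float = 3.3     # ms, LTP duration threshold
    g_p: float = 0.0044    # 1/(ms µM), potentiation gain
    g_p_max: float = 0.01  # 1/ms, potentiation gain cap
    g_d: float = 0.004     # 1/(ms µM), depression gain
    g_d_max: float = 0.01  # 1/ms, depression gain cap
    w_min: float = 0.0
    w_max: float = 2.0

    def __post_init__(self):
        if not (self.t_ap > self.t_ad > 0):
            raise ValueError("need t_ap > t_ad > 0")
        if self.dur_d <= 0 or self.dur_p <= 0:
            raise ValueError("duration thresholds must be positive")
        if self.w_max <= self.w_min:
            raise ValueError("w_max must exceed w_min")
        if min(self.g_p, self.g_p_max, self.g_d, self.g_d_max) <= 0:
            raise ValueError("gains must be positive")

    def as_tuple(self) -> tuple:
        """Flat float tuple consumed by the compiled kernels."""
        return (
            self.t_ad, self.t_ap, self.dur_d, self.dur_p,
            self.g_p, self.g_p_max, self.g_d, self.g_d_max,
            self.w_min, self.w_max,
        )


class PlasticityState(NamedTuple):
    """Carry-over state between trace chunks (weight and excursion timers)."""

    w: float
    k_ad: int  # consecutive samples with Ca > t_ad
    k_ap: int  # consecutive samples with Ca > t_ap


@dataclass(frozen=True)
class WeightTrace:
    """Weight trajectory produced by the rule on one calcium trace."""

    w: np.ndarray        # weight after each calcium sample
    dt_ms: float
    w0: float
    state: PlasticityState

    @property
    def dw(self) -> np.ndarray:
        return np.diff(np.concatenate(([self.w0], self.w)))

    @property
    def total_change(self) -> float:
        return float(self.w[-1] - self.w0) if self.w.size else 0.0


@njit(cache=True)
def plasticity_step(c, w, k_ad, k_ap, dt, t_ad, t_ap, dur_d, dur_p,
                    g_p, g_p_max, g_d, g_d_max, w_min, w_max):
    """One rule step; shared by the offline runner and the full simulation."""
    if c > t_ad:
        k_ad += 1
    else:
        k_ad = 0
    if c > t_ap:
        k_ap += 1
    else:
        k_ap = 0
    span = w_max - w_min
    if c > t_ap:
        if k_ap * dt > dur_p + _TIME_TOL:
            g = g_p * (c - t_ap)
            if g > g_p_max:
                g = g_p_max
            w = w + g * dt * (1.0 - (w - w_min) / span)
    elif c > t_ad and c < t_ap:
        if k_ad * dt > dur_d + _TIME_TOL:
            g = g_d * (c - t_ad)
            if g > g_d_max:
                g = g_d_max
            w = w - g * dt * (w - w_min) / span
    return w, k_ad, k_ap


@njit(cache=True)
def _run_rule(ca, dt, w0, k_ad0, k_ap0, t_ad, t_ap, dur_d, dur_p,
              g_p, g_p_max, g_d, g_d_max, w_min, w_max):
    n = ca.size
    w_out = np.empty(n)
    w, k_ad, k_ap = w0, k_ad0, k_ap0
    for i in range(n):
        w, k_ad, k_ap = plasticity_step(
            ca[i], w, k_ad, k_ap, dt, t_ad, t_ap, dur_d, dur_p,
            g_p, g_p_max, g_d, g_d_max, w_min, w_max,
        )
        w_out[i] = w
    return w_out, k_ad, k_ap


def update_weights(
    ca_trace: np.ndarray,
    params: PlasticityParams,
    w0: float = 1.0,
    dt_ms: float = 0.05,
    state: PlasticityState | None = None,
) -> WeightTrace:
    """Apply the rule to a spine calcium trace sampled at ``dt_ms``.

    ``state`` carries the weight and excursion timers across chunks (e.g.
    successive trials); when given, its weight supersedes ``w0``.
    """
    ca = np.ascontiguousarray(ca_trace, dtype=float)
    if ca.ndim != 1:
        raise ValueError("calcium trace must be one-dimensional")
    if np.any(ca < 0):
        raise ValueError("calcium trace contains negative concentrations")
    if state is None:
        state = PlasticityState(float(w0), 0, 0)
    if not (params.w_min <= state.w <= params.w_max):
        raise ValueError("initial weight outside [w_min, w_max]")
    w_arr, k_ad, k_ap = _run_rule(
        ca, dt_ms, state.w, state.k_ad, state.k_ap, *params.as_tuple()
    )
    final = PlasticityState(float(w_arr[-1]) if w_arr.size else state.w, k_ad, k_ap)
    return WeightTrace(w_arr, dt_ms, state.w, final)


def detect_plasticity_events(
    ca_trace: np.ndarray,
    params: PlasticityParams,
    w0: float = 1.0,
    dt_ms: float = 0.05,
) -> list[tuple[float, int, float]]:
    """Onsets of contiguous runs of nonzero weight change.

    Returns ``(onset_time_ms, direction, magnitude)`` per event, where
    direction is +1 (potentiation) or -1 (depression), magnitude is the summed
    weight change of the run, and sample k sits at time ``k * dt_ms``.
    """
    trace = update_weights(ca_trace, params, w0=w0, dt_ms=dt_ms)
    dw = trace.dw
    events = []
    in_run = False
    sign = 0
    onset = 0.0
    mag = 0.0
    for k, d in enumerate(dw):
        s = 0 if d == 0.0 else (1 if d > 0 else -1)
        if in_run and s == sign:
            mag += d
        else:
            if in_run:
                events.append((onset, sign, mag))
                in_run = False
            if s != 0:
                in_run, sign, onset, mag = True, s, k * dt_ms, d
    if in_run:
        events.append((onset, sign, mag))
    return events


def _square_pulse(amplitude, duration_ms, dt_ms, baseline=0.05, pad_ms=10.0):
    n_pad = int(round(pad_ms / dt_ms))
    n_pulse = int(round(duration_ms / dt_ms))
    trace = np.full(2 * n_pad + n_pulse, baseline)
    trace[n_pad : n_pad + n_pulse] = amplitude
    return trace


def amplitude_threshold_scan(
    params: PlasticityParams,
    duration_ms: float,
    direction: str,
    amp_step: float = 0.01,
    dt_ms: float = 0.05,
    amp_max: float = 2.0,
    w0: float = 1.0,
) -> float:
    """Estimate an amplitude threshold by scanning square pulses upward.

    Feeds square calcium pulses of fixed ``duration_ms`` at amplitudes
    ``amp_step, 2*amp_step, ...`` and returns the largest amplitude producing
    NO weight change — the scan's estimate of the strict threshold below the
    first amplitude at which the end weight moves in ``direction``
    ('ltp' or 'ltd').
    """
    if direction not in ("ltp", "ltd"):
        raise ValueError("direction must be 'ltp' or 'ltd'")
    prev = 0.0
    k = 1
    while k * amp_step <= amp_max + 1e-12:
        amp = k * amp_step
        trace = _square_pulse(amp, duration_ms, dt_ms)
        w_end = update_weights(trace, params, w0=w0, dt_ms=dt_ms).w[-1]
        moved = w_end < w0 - 1e-9 if direction == "ltd" else w_end > w0 + 1e-9
        if moved:
            return prev
        prev = amp
        k += 1
    raise RuntimeError("no weight change found over the scanned amplitude range")


def duration_threshold_scan(
    params: PlasticityParams,
    amplitude: float,
    direction: str,
    dur_step: float = 1.0,
    dt_ms: float = 0.05,
    dur_max: float = 200.0,
    w0: float = 1.0,
) -> float:
    """Estimate a duration threshold by scanning square-pulse durations upward.

    Returns the largest scanned duration producing NO weight change, i.e. the
    smallest duration strictly above which pulses at ``amplitude`` move the
    weight in ``direction``.
    """
    if direction not in ("ltp", "ltd"):
        raise ValueError("direction must be 'ltp' or 'ltd'")
    prev = 0.0
    k = 1
    while k * dur_step <= dur_max + 1e-12:
        dur = k * dur_step
        trace = _square_pulse(amplitude, dur, dt_ms)
        w_end = update_weights(trace, params, w0=w0, dt_ms=dt_ms).w[-1]
        moved = w_end < w0 - 1e-9 if direction == "ltd" else w_end > w0 + 1e-9
        if moved:
            return prev
        prev = dur
        k += 1
    raise RuntimeError("no weight change found over the scanned duration range")
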