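"""Closed-loop optogenetics protocol accounting.

Simulates the laser schedules used around ingestion and reproduces the
pulse-count bookkeeping:

* open loop — 20 Hz modulation in a repeating 2-s-on / 3-s-off cycle
  (40 pulses per cycle) for the whole session;
* lick-on — every detected lick (re)starts a 2-s stimulation window at the
  modulation frequency; a lick inside an active window restarts the timer
  and the pulse phase, so overlapping windows merge;
* lick-off — the free-running open-loop cycle runs, but every lick
  suppresses pulses for 2 s (the cycle phase is not reset).

Summary formulas: lick-on pulses = total licking time x 20; lick-off
pulses = non-licking time x 8 (40 pulses per 5-s cycle).  Pulse timestamps
are rising edges; the pulse width matters only for the non-overlap check.

Also provides two-bottle preference ratios and intragastric infusion
profiles (piecewise-constant rate -> cumulative volume and its T50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EventTrain
from .intake import t50 as _t50

__all__ = [
    "LaserParams",
    "LaserSchedule",
    "PreferenceResult",
    "InfusionProfile",
    "simulate_laser_schedule",
    "pulse_count_formula",
    "preference_ratio",
    "infusion_profile",
]


@dataclass(frozen=True)
class LaserParams:
    frequency: float = 20.0  # Hz
    on: float = 2.0  # s per cycle (and per lick-triggered window)
    off: float = 3.0  # s per cycle
    pulse_width: float = 0.01  # s
    retrigger_window: float = 2.0  # s of stimulation (lick_on) / suppression (lick_off)

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.on <= 0 or self.off < 0 or self.pulse_width <= 0:
            raise ValueError("laser parameters must be positive (off may be zero)")
        if self.frequency * self.pulse_width >= 1:
            raise ValueError("frequency x pulse_width >= 1: pulses would overlap")


@dataclass(frozen=True)
class LaserSchedule:
    pulse_times: np.ndarray
    mode: str
    params: LaserParams
    session_len: float
    suppressed_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        pulses = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", pulses)
        object.__setattr__(
            self, "suppressed_times", np.asarray(self.suppressed_times, dtype=float)
        )
        if len(pulses):
            if np.any(np.diff(pulses) < self.params.pulse_width - 1e-12):
                raise ValueError("pulses closer than one pulse width")
            if pulses[0] < 0 or pulses[-1] >= self.session_len:
                raise ValueError("pulses outside the session")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times)


def _open_loop_pulses(params: LaserParams, session_len: float) -> np.ndarray:
    period = params.on + params.off
    per_cycle = int(round(params.frequency * params.on))
    cycle_starts = np.arange(0.0, session_len, period)
    offsets = np.arange(per_cycle) / params.frequency
    pulses = (cycle_starts[:, None] + offsets[None, :]).ravel()
    return pulses[pulses < session_len]


def _lick_on_pulses(licks: np.ndarray, params: LaserParams, session_len: float) -> np.ndarray:
    pulses: list[float] = []
    dt = 1.0 / params.frequency
    win = params.retrigger_window
    bounds = np.append(licks, np.inf)
    last_pulse = -np.inf
    for i, t0 in enumerate(licks):
        stop = min(t0 + win, bounds[i + 1], session_len)
        # a retrigger cannot interrupt a pulse already in flight
        t0 = max(t0, last_pulse + params.pulse_width * (1 + 1e-6))
        k = 0
        while t0 + k * dt < stop - 1e-12:
            pulses.append(t0 + k * dt)
            last_pulse = pulses[-1]
            k += 1
    return np.asarray(pulses)


def simulate_laser_schedule(
    train: EventTrain | None,
    mode: str,
    params: LaserParams = LaserParams(),
    session_len: float | None = None,
) -> LaserSchedule:
    """Event-driven simulation of the laser schedule for a session.

    Modes: ``open_loop``, ``lick_on``, ``lick_off`` and
    ``continuous_inhibition`` (lick-triggered continuous light; the emitted
    "pulses" are the merged window onsets).
    """
    if session_len is None:
        if train is None:
            raise ValueError("session_len is required when no train is given")
        session_len = train.session_duration
    licks = train.timestamps if train is not None else np.empty(0)
    if len(licks) and licks[-1] > session_len:
        raise ValueError("train extends beyond session_len")

    if mode == "open_loop":
        pulses = _open_loop_pulses(params, session_len)
        suppressed = np.empty(0)
    elif mode == "lick_on":
        pulses = _lick_on_pulses(licks, params, session_len)
        suppressed = np.empty(0)
    elif mode == "lick_off":
        free = _open_loop_pulses(params, session_len)
        if len(licks):
            idx = np.searchsorted(licks, free, side="right") - 1
            has_prev = idx >= 0
            recent = np.zeros(len(free), dtype=bool)
            recent[has_prev] = free[has_prev] - licks[idx[has_prev]] < params.retrigger_window
        else:
            recent = np.zeros(len(free), dtype=bool)
        pulses, suppressed = free[~recent], free[recent]
    elif mode == "continuous_inhibition":
        starts = []
        win = params.retrigger_window
        current_end = -np.inf
        for t in licks:
            if t > current_end:
                starts.append(t)
            current_end = min(t + win, session_len)
        pulses = np.asarray(starts)
        suppressed = np.empty(0)
    else:
        raise ValueError(f"unknown laser mode {mode!r}")
    return LaserSchedule(pulses, mode, params, float(session_len), suppressed)


def pulse_count_formula(total_lick_time: float, session_len: float, mode: str) -> float:
    """Summary pulse counts from licking time alone.

    lick_on: total licking time (s) x 20 pulses/s.
    lick_off: (session length - licking time) x 8 pulses/s (the 2-s-on /
    3-s-off 20 Hz cycle averages 40 pulses per 5 s).
    """
    if total_lick_time < 0 or session_len < 0:
        raise ValueError("times must be non-negative")
    if total_lick_time > session_len:
        raise ValueError("total_lick_time exceeds session length")
    if mode == "lick_on":
        return total_lick_time * 20.0
    if mode == "lick_off":
        return (session_len - total_lick_time) * 8.0
    raise ValueError(f"no pulse-count formula for mode {mode!r}")


@dataclass(frozen=True)
class PreferenceResult:
    licks_bottle1: int
    licks_bottle2: int
    preference_ratio: float  # NaN when no licks at all
    total_licks: int


def preference_ratio(
    train_bottle1: EventTrain | int, train_bottle2: EventTrain | int
) -> PreferenceResult:
    """Two-bottle preference: licks at bottle 1 over total licks."""
    n1 = train_bottle1 if isinstance(train_bottle1, int) else len(train_bottle1)
    n2 = train_bottle2 if isinstance(train_bottle2, int) else len(train_bottle2)
    if n1 < 0 or n2 < 0:
        raise ValueError("lick counts must be non-negative")
    total = n1 + n2
    ratio = n1 / total if total > 0 else np.nan
    return PreferenceResult(n1, n2, ratio, total)


@dataclass(frozen=True)
class InfusionProfile:
    time_min: np.ndarray
    cumulative_ml: np.ndarray
    total_ml: float
    t50_min: float


def infusion_profile(
    segments: list[tuple[float, float, float]] | float,
    duration_min: float,
    dt_s: float = 1.0,
) -> InfusionProfile:
    """Cumulative infused volume from a piecewise-constant rate schedule.

    ``segments`` is either a constant rate (ul/min over the whole duration)
    or a list of (start_min, end_min, rate_ul_per_min).  T50 is the earliest
    time at which half the total volume has been delivered.
    """
    if isinstance(segments, (int, float)):
        segments = [(0.0, duration_min, float(segments))]
    if any(rate < 0 for _, _, rate in segments):
        raise ValueError("infusion rates must be non-negative")
    t = np.arange(0.0, duration_min * 60.0 + dt_s / 2, dt_s)
    rate = np.zeros_like(t)  # ul/min at each instant
    for start_min, end_min, r in segments:
        rate[(t >= start_min * 60.0) & (t < end_min * 60.0)] = r
    # trapezoid-free exact accumulation for piecewise-constant rates
    vol_ml = np.concatenate([[0.0], np.cumsum(rate[:-1] * dt_s / 60.0) / 1000.0])
    return InfusionProfile(
        time_min=t / 60.0,
        cumulative_ml=vol_ml,
        total_ml=float(vol_ml[-1]),
        t50_min=_t50(t, vol_ml, mode="behavior"),
    )
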