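"""Bout-locked response statistics.

All statistics here re-standardize activity against a bout-local baseline:
the 15 s immediately preceding the first lick of each bout.  The per-bout
response is the mean local z over the first ``response_window`` seconds of
the bout (clipped to the bout's last lick by default when the bout is
shorter), and the per-lick response divides that by the number of licks in
the same window.

Kinetic constants use crossing criteria on the bout-averaged peri-event
trace (PSTH): the rise constant tau is the earliest time at which 63.8% of
the PSTH maximum is reached after the first lick, and the decay constant
lambda is the earliest time after the last lick at which the PSTH has
fallen to 37% of its last-lick value.  The 63.8%/37% constants are the
field's printed criteria and are exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .microstructure import Bout
from .normalize import NormalizedTrace

__all__ = [
    "BoutResponse",
    "KineticsResult",
    "bout_locked_response",
    "bin_by_bout_size",
    "compute_psth",
    "estimate_rise_tau",
    "estimate_decay_lambda",
    "rise_kinetics",
    "decay_kinetics",
    "bout_size_slope",
    "end_of_bout_drop",
    "split_early_late",
    "DEFAULT_SIZE_BINS",
]

DEFAULT_SIZE_BINS = ((5, 25), (26, 50), (51, 75), (76, 100))


@dataclass(frozen=True)
class BoutResponse:
    """Response of one bout, standardized to its own -15 s baseline."""

    bout: Bout
    z_per_bout: float
    z_per_lick: float  # NaN when no licks fall in the response window
    licks_in_window: int
    local_mu: float
    local_sigma: float
    response_window: float
    valid: bool = True
    baseline_overlaps_previous: bool = False


@dataclass(frozen=True)
class KineticsResult:
    value: float  # seconds; NaN when undefined
    defined: bool
    criterion: float
    grid_step: float


def _local_zscore(trace: NormalizedTrace, t0: float, baseline_len: float):
    """Local mean/SD of the trace's z over [t0 - baseline_len, t0)."""
    mask = trace.window_mask((t0 - baseline_len, t0))
    if mask.sum() < 2:
        return np.nan, np.nan
    base = trace.z[mask]
    return float(base.mean()), float(base.std(ddof=1))


def bout_locked_response(
    trace: NormalizedTrace,
    bouts: list[Bout],
    baseline_len: float = 15.0,
    response_window: float = 10.0,
    clip_to_bout: bool = True,
) -> list[BoutResponse]:
    """Per-bout z and per-lick z against each bout's local baseline.

    ``clip_to_bout`` shortens the response window to the bout's last lick
    when the bout is shorter than ``response_window``.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    out: list[BoutResponse] = []
    prev_end = -np.inf
    for bout in bouts:
        mu, sigma = _local_zscore(trace, bout.start, baseline_len)
        win_end = bout.start + response_window
        clipped = clip_to_bout and bout.end < win_end
        if clipped:
            win_end = bout.end
        mask = trace.window_mask((bout.start, win_end))
        valid = np.isfinite(sigma) and sigma > 0 and mask.any()
        if valid:
            z_bout = float((trace.z[mask].mean() - mu) / sigma)
        else:
            z_bout = np.nan
        # the window is half-open except when clipped to the bout's last
        # lick, which then belongs to its own bout
        in_window = (bout.lick_times >= bout.start) & (
            (bout.lick_times <= win_end) if clipped else (bout.lick_times < win_end)
        )
        n_licks = int(np.count_nonzero(in_window))
        z_lick = z_bout / n_licks if (valid and n_licks > 0) else np.nan
        out.append(
            BoutResponse(
                bout=bout,
                z_per_bout=z_bout,
                z_per_lick=z_lick,
                licks_in_window=n_licks,
                local_mu=mu,
                local_sigma=sigma,
                response_window=response_window,
                valid=bool(valid),
                baseline_overlaps_previous=bool(bout.start - baseline_len < prev_end),
            )
        )
        prev_end = bout.end
    return out


def bin_by_bout_size(
    responses: list[BoutResponse], bins=DEFAULT_SIZE_BINS
) -> dict[tuple[int, int], float]:
    """Mean z-per-lick within each bout-size bin (inclusive bounds).

    Bouts outside every bin are excluded; empty bins map to NaN.
    """
    out: dict[tuple[int, int], float] = {}
    for lo, hi in bins:
        vals = [
            r.z_per_lick
            for r in responses
            if lo <= r.bout.size <= hi and np.isfinite(r.z_per_lick)
        ]
        out[(lo, hi)] = float(np.mean(vals)) if vals else np.nan
    return out


def compute_psth(
    trace: NormalizedTrace,
    align_times: np.ndarray,
    window: tuple[float, float],
    baseline_len: float = 15.0,
    local_baseline: bool = True,
    baseline_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-event average of z on the trace's own grid.

    Each event's snippet is sampled by interpolation on a relative grid
    spanning ``window`` at the trace's sampling step, optionally
    re-standardized to a -``baseline_len`` s local baseline, then averaged
    across events.  The baseline is anchored at ``baseline_times`` (e.g.
    bout starts when aligning to last licks); it defaults to the alignment
    times themselves.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    align_times = np.asarray(align_times, dtype=float)
    if baseline_times is None:
        baseline_times = align_times
    baseline_times = np.asarray(baseline_times, dtype=float)
    dt = 1.0 / trace.rate
    rel = np.arange(window[0], window[1] + dt / 2, dt)
    snippets = []
    for t0, tb in zip(align_times, baseline_times):
        snippet = np.interp(rel + t0, trace.time, trace.z, left=np.nan, right=np.nan)
        if local_baseline:
            mu, sigma = _local_zscore(trace, tb, baseline_len)
            if not np.isfinite(sigma) or sigma <= 0:
                continue
            snippet = (snippet - mu) / sigma
        snippets.append(snippet)
    if not snippets:
        return rel, np.full_like(rel, np.nan)
    with np.errstate(invalid="ignore"):
        psth = np.nanmean(np.vstack(snippets), axis=0)
    return rel, psth


def estimate_rise_tau(
    psth_times: np.ndarray, psth: np.ndarray, criterion: float = 0.638
) -> KineticsResult:
    """Earliest PSTH time (from the first lick) at which ``criterion`` of
    the PSTH maximum is reached; undefined when the maximum is not positive."""
    psth_times = np.asarray(psth_times, dtype=float)
    psth = np.asarray(psth, dtype=float)
    dt = float(np.median(np.diff(psth_times))) if len(psth_times) > 1 else np.nan
    valid = np.isfinite(psth)
    if not valid.any() or np.nanmax(psth) <= 0:
        return KineticsResult(np.nan, False, criterion, dt)
    target = criterion * np.nanmax(psth)
    after = valid & (psth_times >= 0)
    hits = np.flatnonzero(after & (psth >= target))
    if len(hits) == 0:
        return KineticsResult(np.nan, False, criterion, dt)
    return KineticsResult(float(psth_times[hits[0]]), True, criterion, dt)


def estimate_decay_lambda(
    psth_times: np.ndarray, psth: np.ndarray, criterion: float = 0.37
) -> KineticsResult:
    """Earliest time after the last lick (t = 0 on the PSTH grid) at which
    the PSTH falls to ``criterion`` of its last-lick value."""
    psth_times = np.asarray(psth_times, dtype=float)
    psth = np.asarray(psth, dtype=float)
    dt = float(np.median(np.diff(psth_times))) if len(psth_times) > 1 else np.nan
    i0 = int(np.argmin(np.abs(psth_times)))
    v0 = psth[i0]
    if not np.isfinite(v0) or v0 <= 0:
        return KineticsResult(np.nan, False, criterion, dt)
    target = criterion * v0
    after = psth_times > 0
    hits = np.flatnonzero(after & (psth <= target))
    if len(hits) == 0:
        return KineticsResult(np.nan, False, criterion, dt)
    return KineticsResult(float(psth_times[hits[0]]), True, criterion, dt)


def rise_kinetics(
    trace: NormalizedTrace,
    bouts: list[Bout],
    extent: float | None = None,
    baseline_len: float = 15.0,
    criterion: float = 0.638,
) -> KineticsResult:
    """Rise constant from the bout-averaged PSTH aligned to first licks.

    The PSTH maximum must be taken within the bout, so ``extent`` defaults
    to the shortest bout's duration (clipped to [5, 30] s) — beyond it some
    bouts have already ended and the average is no longer a rising front.
    """
    if not bouts:
        return KineticsResult(np.nan, False, criterion, np.nan)
    if extent is None:
        extent = float(np.clip(min(b.duration for b in bouts), 5.0, 30.0))
    firsts = np.array([b.start for b in bouts])
    rel, psth = compute_psth(trace, firsts, (0.0, extent), baseline_len=baseline_len)
    return estimate_rise_tau(rel, psth, criterion)


def decay_kinetics(
    trace: NormalizedTrace,
    bouts: list[Bout],
    extent: float = 60.0,
    baseline_len: float = 15.0,
    criterion: float = 0.37,
) -> KineticsResult:
    """Decay constant from the bout-averaged PSTH aligned to last licks.

    Snippets are standardized against each bout's pre-bout baseline (the
    15 s before the *first* lick), so the last-lick value reflects the
    within-bout activation it decays from.
    """
    if not bouts:
        return KineticsResult(np.nan, False, criterion, np.nan)
    lasts = np.array([b.end for b in bouts])
    starts = np.array([b.start for b in bouts])
    rel, psth = compute_psth(
        trace, lasts, (0.0, extent), baseline_len=baseline_len, baseline_times=starts
    )
    return estimate_decay_lambda(rel, psth, criterion)


def bout_size_slope(responses: list[BoutResponse]) -> float:
    """OLS slope of z-per-bout on bout size (z units per additional lick)."""
    pairs = [(r.bout.size, r.z_per_bout) for r in responses if np.isfinite(r.z_per_bout)]
    sizes = np.array([p[0] for p in pairs], dtype=float)
    if len(np.unique(sizes)) < 2:
        raise ValueError("need at least 2 bouts with distinct sizes")
    zs = np.array([p[1] for p in pairs], dtype=float)
    return float(stats.linregress(sizes, zs).slope)


@dataclass(frozen=True)
class EndOfBoutDrop:
    drop: float  # post-mean minus pre-peak, z units
    truncated: bool


def end_of_bout_drop(
    trace: NormalizedTrace, bouts: list[Bout], window: float = 15.0
) -> list[EndOfBoutDrop]:
    """Per bout: (mean z over [0, window) after the last lick) minus
    (peak z over [-window, 0) before the last lick).

    Windows truncated by the session edges are flagged and computed on the
    available span.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    out = []
    t_min, t_max = trace.time[0], trace.time[-1]
    for bout in bouts:
        last = bout.end
        pre = trace.window_mask((last - window, last))
        post = trace.window_mask((last, last + window))
        truncated = (last - window < t_min) or (last + window > t_max)
        if not pre.any() or not post.any():
            out.append(EndOfBoutDrop(np.nan, True))
            continue
        drop = float(trace.z[post].mean() - trace.z[pre].max())
        out.append(EndOfBoutDrop(drop, truncated))
    return out


@dataclass(frozen=True)
class HalfStats:
    responses: list[BoutResponse]
    mean_z_per_bout: float
    mean_z_per_lick: float
    n_bouts: int
    empty: bool


def _half_stats(responses: list[BoutResponse]) -> HalfStats:
    zb = [r.z_per_bout for r in responses if np.isfinite(r.z_per_bout)]
    zl = [r.z_per_lick for r in responses if np.isfinite(r.z_per_lick)]
    return HalfStats(
        responses=responses,
        mean_z_per_bout=float(np.mean(zb)) if zb else np.nan,
        mean_z_per_lick=float(np.mean(zl)) if zl else np.nan,
        n_bouts=len(responses),
        empty=not responses,
    )


def split_early_late(
    trace: NormalizedTrace,
    bouts: list[Bout],
    boundary: float = 15.0,
    **response_kwargs,
) -> tuple[HalfStats, HalfStats]:
    """Bout-locked statistics split at ``boundary`` minutes.

    A bout whose first lick falls at exactly the boundary belongs to the
    late half (half-open convention).
    """
    t_split = boundary * 60.0
    early = [b for b in bouts if b.start < t_split]
    late = [b for b in bouts if b.start >= t_split]
    return (
        _half_stats(bout_locked_response(trace, early, **response_kwargs)),
        _half_stats(bout_locked_response(trace, late, **response_kwargs)),
    )
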