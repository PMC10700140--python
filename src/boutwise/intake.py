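"""Neural activity versus cumulative and recent intake.

Covers lagged lick/activity correlations with shuffled nulls, half-rise
(T50) statistics for neural and behavioural curves, the post-ingestive
index, brief-access trial profiles, and the intake unit conversions
(mass -> kcal, mass -> volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import EventTrain
from .normalize import NormalizedTrace

__all__ = [
    "CorrelationResult",
    "BriefAccessResult",
    "trailing_lick_count",
    "lagged_intake_pcc",
    "t50",
    "post_ingestive_index",
    "brief_access_profile",
    "intake_energy",
    "mass_to_volume",
]

#: default preceding-interval lengths, 10 s to 30 min
DEFAULT_WINDOWS = (10.0, 60.0, 240.0, 600.0, 1800.0)


@dataclass(frozen=True)
class CorrelationResult:
    window_lengths: tuple[float, ...]
    pcc_real: np.ndarray  # one PCC per window
    pcc_shuffled: np.ndarray  # (n_windows, n_shuffles) null values
    n_samples: int
    seed: int

    def shuffled_mean(self) -> np.ndarray:
        return self.pcc_shuffled.mean(axis=1)


def trailing_lick_count(
    lick_times: np.ndarray, sample_times: np.ndarray, window: float
) -> np.ndarray:
    """Number of licks in the trailing half-open window (t - w, t] per sample."""
    lick_times = np.asarray(lick_times, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    hi = np.searchsorted(lick_times, sample_times, side="right")
    lo = np.searchsorted(lick_times, sample_times - window, side="right")
    return (hi - lo).astype(float)


def lagged_intake_pcc(
    trace: NormalizedTrace,
    train: EventTrain,
    windows=DEFAULT_WINDOWS,
    n_shuffles: int = 100,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation between z and trailing lick counts, with a
    permutation null.

    For each window length w the predictor at sample t is the lick count in
    (t - w, t]; the null scrambles the predictor by full random permutation
    (seeded), recomputed per shuffle on the identical sample grid.
    Zero-variance z or predictor yields NaN for that window.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    z = trace.z
    if np.std(z) == 0:
        raise ValueError("trace has zero variance")
    rng = np.random.default_rng(seed)
    real = np.empty(len(windows))
    null = np.empty((len(windows), n_shuffles))
    for i, w in enumerate(windows):
        pred = trailing_lick_count(train.timestamps, trace.time, w)
        if np.std(pred) == 0:
            real[i] = np.nan
            null[i] = np.nan
            continue
        real[i] = np.corrcoef(pred, z)[0, 1]
        for j in range(n_shuffles):
            null[i, j] = np.corrcoef(rng.permutation(pred), z)[0, 1]
    return CorrelationResult(
        window_lengths=tuple(float(w) for w in windows),
        pcc_real=real,
        pcc_shuffled=null,
        n_samples=len(z),
        seed=seed,
    )


def t50(times_s: np.ndarray, values: np.ndarray, mode: str = "neural") -> float:
    """Half-rise time in minutes.

    ``mode="neural"``: earliest time at which the series reaches 50% of its
    maximum.  ``mode="behavior"``: the series is a cumulative intake curve;
    earliest time at which it reaches 50% of its final total.  Returns NaN
    when the maximum (or total) is not positive.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty series")
    if mode == "neural":
        target = 0.5 * np.nanmax(values)
        if not target > 0:
            return np.nan
    elif mode == "behavior":
        total = values[-1]
        if not total > 0:
            return np.nan
        target = 0.5 * total
    else:
        raise ValueError(f"unknown t50 mode {mode!r}")
    hits = np.flatnonzero(values >= target)
    if len(hits) == 0:
        return np.nan
    return float(times_s[hits[0]]) / 60.0


def post_ingestive_index(
    trace: NormalizedTrace,
    access: tuple[float, float] = (0.0, 600.0),
    post: tuple[float, float] = (600.0, 1800.0),
) -> float:
    """100 x (mean z after food removal) / (mean z during access).

    NaN when the ingestive (access-period) response is zero.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    ingestive = float(trace.z[trace.window_mask(access)].mean())
    post_resp = float(trace.z[trace.window_mask(post)].mean())
    if ingestive == 0:
        return np.nan
    return 100.0 * post_resp / ingestive


@dataclass(frozen=True)
class BriefAccessResult:
    per_trial_z: np.ndarray  # NaN for trials without licks
    r_squared: float
    slope: float
    last_trial_mean: float
    access_len: float


def brief_access_profile(
    trace: NormalizedTrace,
    train: EventTrain,
    trial_starts: np.ndarray,
    access_len: float,
) -> BriefAccessResult:
    """Per-trial responses in a brief-access test and their trend.

    The response of a trial is the mean z over [first lick of the trial,
    first lick + access_len); trials without licks are NaN and excluded
    from the OLS of response on trial number.
    """
    if trace.z is None:
        raise ValueError("trace must be z-scored first")
    trial_starts = np.sort(np.asarray(trial_starts, dtype=float))
    per_trial = np.full(len(trial_starts), np.nan)
    bounds = np.append(trial_starts, np.inf)
    for i, t0 in enumerate(trial_starts):
        in_trial = train.timestamps[
            (train.timestamps >= t0) & (train.timestamps < bounds[i + 1])
        ]
        if len(in_trial) == 0:
            continue
        first = in_trial[0]
        mask = trace.window_mask((first, first + access_len))
        if mask.any():
            per_trial[i] = trace.z[mask].mean()
    ok = np.isfinite(per_trial)
    if ok.sum() >= 2:
        if np.ptp(per_trial[ok]) == 0:  # identical responses: no trend
            r2, slope = 0.0, 0.0
        else:
            fit = stats.linregress(np.flatnonzero(ok) + 1.0, per_trial[ok])
            r2, slope = float(fit.rvalue**2), float(fit.slope)
    else:
        r2, slope = np.nan, np.nan
    last = float(per_trial[-1]) if np.isfinite(per_trial[-1]) else np.nan
    return BriefAccessResult(per_trial, r2, slope, last, access_len)


def intake_energy(mass_g: float, density_kcal_per_g: float) -> float:
    """Food intake in kcal: mass consumed times caloric density."""
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    if density_kcal_per_g <= 0:
        raise ValueError("density must be positive")
    return mass_g * density_kcal_per_g


def mass_to_volume(mass_g: float, density_g_per_ml: float) -> float:
    """Consumed volume in ml from consumed mass and solution density."""
    if mass_g < 0:
        raise ValueError("mass must be non-negative")
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    return mass_g / density_g_per_ml
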