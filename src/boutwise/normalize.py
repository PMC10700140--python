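"""Two-channel photometry normalization.

The isosbestic reference channel (~405/415 nm) carries motion and bleaching
but no calcium-dependent fluorescence.  An ordinary least-squares regression
of the signal channel on the reference over a quiet baseline window yields
``F_normalized``, the reference-predicted fluorescence; the residual
``signal - F_normalized`` is the motion/bleach-corrected activity carrier.
Activity is then expressed in baseline standard deviations:

    z = (x - mu) / sigma

where ``mu`` and ``sigma`` are the mean and SD of ``x`` over the baseline
window.  Two conventions for ``x`` are supported:

* ``mode="residual"`` (default): x = signal - F_normalized, the corrected
  activity signal — the convention under which lick-locked transients
  survive normalization;
* ``mode="predicted"``: x = F_normalized itself, the literal reading of the
  printed formula.

Smoothing is presentation-only: statistics in the other modules are always
computed on unsmoothed traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import RawPhotometry

__all__ = ["NormalizedTrace", "fit_isosbestic_baseline", "zscore_trace", "resample_and_smooth"]


@dataclass(frozen=True)
class NormalizedTrace:
    """Baseline-referenced z-scored activity with its provenance.

    ``f_normalized`` is the reference-predicted fluorescence; ``mu`` and
    ``sigma`` are the baseline mean/SD of the carrier chosen by ``mode``.
    ``z`` is ``None`` until :func:`zscore_trace` is applied.
    """

    time: np.ndarray
    signal: np.ndarray
    f_normalized: np.ndarray
    rate: float
    baseline_window: tuple[float, float]
    z: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None
    mode: str = "residual"

    def __len__(self) -> int:
        return len(self.time)

    @property
    def residual(self) -> np.ndarray:
        return self.signal - self.f_normalized

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples in the half-open window [start, end)."""
        return (self.time >= window[0]) & (self.time < window[1])


def fit_isosbestic_baseline(
    raw: RawPhotometry, baseline_window: tuple[float, float]
) -> NormalizedTrace:
    """OLS-fit signal on reference over ``baseline_window``; predict
    ``F_normalized`` over the whole session.

    Requires at least 2 baseline samples and a non-constant reference over
    the window (otherwise the regression is degenerate).
    """
    mask = (raw.time >= baseline_window[0]) & (raw.time < baseline_window[1])
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    ref_b = raw.reference[mask]
    sig_b = raw.signal[mask]
    if np.ptp(ref_b) == 0:
        raise ValueError("degenerate regression: reference is constant over the baseline")
    slope, intercept = np.polyfit(ref_b, sig_b, deg=1)
    f_norm = intercept + slope * raw.reference
    return NormalizedTrace(
        time=raw.time.copy(),
        signal=raw.signal.copy(),
        f_normalized=f_norm,
        rate=raw.rate,
        baseline_window=(float(baseline_window[0]), float(baseline_window[1])),
    )


def zscore_trace(
    trace: NormalizedTrace,
    baseline_window: tuple[float, float] | None = None,
    mode: str | None = None,
) -> NormalizedTrace:
    """Fill ``z`` by standardizing the activity carrier against the baseline.

    The baseline defaults to the window used for the isosbestic fit.  The
    returned trace records ``mu`` and ``sigma`` (sample SD, ddof=1); zero
    baseline variance is an error.
    """
    window = baseline_window if baseline_window is not None else trace.baseline_window
    mode = mode if mode is not None else trace.mode
    if mode == "residual":
        carrier = trace.residual
    elif mode == "predicted":
        carrier = trace.f_normalized
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    mask = trace.window_mask(window)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    mu = float(np.mean(carrier[mask]))
    sigma = float(np.std(carrier[mask], ddof=1))
    if sigma <= 0:
        raise ValueError("zero baseline variance: cannot z-score")
    return replace(
        trace,
        z=(carrier - mu) / sigma,
        mu=mu,
        sigma=sigma,
        mode=mode,
        baseline_window=(float(window[0]), float(window[1])),
    )


def _block_average(values: np.ndarray, block: int) -> np.ndarray:
    n = (len(values) // block) * block
    return values[:n].reshape(-1, block).mean(axis=1)


def resample_and_smooth(
    trace: NormalizedTrace, target_rate: float | None = None, span: int = 1
) -> NormalizedTrace:
    """Block-average downsample to ``target_rate``, then apply a centered
    moving average of ``span`` samples (``span=1`` is the identity).

    The block size is the nearest integer to source_rate/target_rate and the
    trailing remainder is dropped, so e.g. 1017.3 Hz -> 4 Hz uses blocks of
    254 samples.  Smoothing uses shrinking windows at the edges, leaving
    constant traces exactly unchanged.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    time, rate = trace.time, trace.rate
    arrays = {
        "signal": trace.signal,
        "f_normalized": trace.f_normalized,
        "z": trace.z,
    }
    if target_rate is not None and target_rate != rate:
        if target_rate > rate:
            raise ValueError("target_rate must not exceed the source rate")
        block = int(round(rate / target_rate))
        new_rate = rate / block
        t0 = time[0] if len(time) else 0.0
        n_blocks = len(time) // block
        time = t0 + np.arange(n_blocks) / new_rate
        arrays = {
            k: (_block_average(v, block) if v is not None else None)
            for k, v in arrays.items()
        }
        rate = new_rate
    if span > 1:
        arrays = {
            k: (
                pd.Series(v).rolling(span, center=True, min_periods=1).mean().to_numpy()
                if v is not None
                else None
            )
            for k, v in arrays.items()
        }
    return replace(
        trace,
        time=time,
        rate=rate,
        signal=arrays["signal"],
        f_normalized=arrays["f_normalized"],
        z=arrays["z"],
    )
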