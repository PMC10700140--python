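"""Single-cell responder classification and cross-stimulus overlap.

Per-neuron raw calcium traces (``C_raw``, from an upstream cell-extraction
pipeline) share one time base.  Each cell is z-scored against the 10-min
pre-stimulus baseline, classified per bout as activated when its mean local
z over the response window reaches the threshold (>= 1 z by default), and
cross-stimulus overlap is quantified with a two-sided Fisher exact test on
the 2x2 responder table plus the R^2 between per-cell response magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .microstructure import Bout

__all__ = [
    "CellMatrix",
    "ResponderResult",
    "OverlapResult",
    "normalize_cell_traces",
    "classify_bout_responders",
    "population_weighted_z",
    "stimulus_overlap",
    "mean_response",
]


@dataclass(frozen=True)
class CellMatrix:
    """Per-neuron traces (n_cells x n_samples) on a shared time base."""

    cell_ids: tuple[str, ...]
    traces: np.ndarray
    time: np.ndarray
    rate: float
    z: np.ndarray | None = None
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    excluded: np.ndarray | None = None  # True for zero-variance cells
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        object.__setattr__(self, "traces", traces)
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        if traces.shape != (len(self.cell_ids), len(self.time)):
            raise ValueError("traces must be (n_cells, n_samples)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        return (self.time >= window[0]) & (self.time < window[1])


def normalize_cell_traces(
    cells: CellMatrix, baseline_window: tuple[float, float]
) -> CellMatrix:
    """Per-cell z against the pre-stimulus baseline window.

    z_c = (C_raw_c - mu_c) / sigma_c with mu_c/sigma_c the baseline mean
    and SD of that cell.  Cells with zero baseline variance are flagged in
    ``excluded`` (their z stays NaN) rather than aborting the session.
    """
    mask = cells.window_mask(baseline_window)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    base = cells.traces[:, mask]
    mu = base.mean(axis=1)
    sigma = base.std(axis=1, ddof=1)
    excluded = sigma <= 0
    z = np.full_like(cells.traces, np.nan)
    ok = ~excluded
    z[ok] = (cells.traces[ok] - mu[ok, None]) / sigma[ok, None]
    return replace(
        cells,
        z=z,
        mu=mu,
        sigma=sigma,
        excluded=excluded,
        baseline_window=(float(baseline_window[0]), float(baseline_window[1])),
    )


@dataclass(frozen=True)
class ResponderResult:
    flags: np.ndarray  # (n_cells, n_bouts) activation per cell per bout
    window_means: np.ndarray  # local-baseline z means behind the flags
    consistency: np.ndarray  # per cell, number of bouts with activation
    threshold: float
    response_window: float
    truncated_bouts: np.ndarray  # bouts whose response window hit the session end

    @property
    def activated_all_bouts(self) -> np.ndarray:
        return self.consistency == self.flags.shape[1]


def classify_bout_responders(
    cells: CellMatrix,
    bouts: list[Bout],
    response_window: float = 15.0,
    threshold: float = 1.0,
    baseline_len: float = 15.0,
) -> ResponderResult:
    """Flag each cell, per bout, as activated when its mean z over
    [first lick, first lick + response_window) — standardized to the cell's
    own -``baseline_len`` s pre-bout baseline — is >= ``threshold``."""
    if cells.z is None:
        raise ValueError("cells must be normalized first")
    n_bouts = len(bouts)
    means = np.full((cells.n_cells, n_bouts), np.nan)
    truncated = np.zeros(n_bouts, dtype=bool)
    for j, bout in enumerate(bouts):
        base = cells.window_mask((bout.start - baseline_len, bout.start))
        resp = cells.window_mask((bout.start, bout.start + response_window))
        truncated[j] = bout.start + response_window > cells.time[-1]
        if base.sum() < 2 or not resp.any():
            continue
        mu = np.nanmean(cells.z[:, base], axis=1)
        sd = np.nanstd(cells.z[:, base], axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means[:, j] = (np.nanmean(cells.z[:, resp], axis=1) - mu) / sd
    with np.errstate(invalid="ignore"):
        flags = means >= threshold
    return ResponderResult(
        flags=flags,
        window_means=means,
        consistency=flags.sum(axis=1),
        threshold=threshold,
        response_window=response_window,
        truncated_bouts=truncated,
    )


def mean_response(result: ResponderResult) -> np.ndarray:
    """Per-cell mean bout response (z), averaged across bouts."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(result.window_means, axis=1)


def population_weighted_z(result: ResponderResult) -> float:
    """Fraction of cells activated in every bout times the mean response of
    those activated cells; 0 when no cell qualifies."""
    active = result.activated_all_bouts
    if not active.any():
        return 0.0
    fraction = active.mean()
    return float(fraction * np.nanmean(mean_response(result)[active]))


@dataclass(frozen=True)
class OverlapResult:
    categories: np.ndarray  # per-cell: "A-only" | "B-only" | "both" | "none"
    counts: dict[str, int]
    fisher_p: float
    odds_ratio: float
    r_squared: float
    threshold: float

    @property
    def table(self) -> np.ndarray:
        c = self.counts
        return np.array([[c["both"], c["A-only"]], [c["B-only"], c["none"]]])


def stimulus_overlap(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    threshold: float = 1.0,
) -> OverlapResult:
    """Cross-stimulus overlap of single-cell responses.

    Each response vector holds one mean z per cell (e.g. during licking for
    stimulus A, after an injection for stimulus B).  Cells are categorized
    by thresholding each response (>= threshold); chance overlap is tested
    with a two-sided Fisher exact test on the 2x2 table and the linear
    relation between the two magnitudes is reported as R^2.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("response vectors must be 1-D and cover the same cells")
    if len(a) < 2:
        raise ValueError("need at least 2 cells")
    pos_a = a >= threshold
    pos_b = b >= threshold
    categories = np.where(
        pos_a & pos_b, "both", np.where(pos_a, "A-only", np.where(pos_b, "B-only", "none"))
    )
    counts = {k: int(np.sum(categories == k)) for k in ("both", "A-only", "B-only", "none")}
    table = [[counts["both"], counts["A-only"]], [counts["B-only"], counts["none"]]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() >= 2 and np.std(a[ok]) > 0 and np.std(b[ok]) > 0:
        r2 = float(stats.linregress(a[ok], b[ok]).rvalue ** 2)
    else:
        r2 = np.nan
    return OverlapResult(
        categories=categories,
        counts=counts,
        fisher_p=float(p),
        odds_ratio=float(odds),
        r_squared=r2,
        threshold=threshold,
    )
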