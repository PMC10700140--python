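"""Per-animal behavioural encoding model.

Activity at each second of each session is regressed on three behavioural
predictors: the caloric density of the solution on offer (kcal/ml, constant
within a session), the number of licks in the preceding 10 s, and the
instantaneous lick rate (licks in the preceding 1 s).  The model is a
Gaussian-identity linear model with intercept; variance is decomposed by
refitting with each variable removed (delta R^2 against the full model) and
generalization is assessed by repeated random 80/20 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import EventTrain
from .intake import trailing_lick_count
from .normalize import NormalizedTrace

__all__ = [
    "CALORIC_DENSITIES",
    "PREDICTORS",
    "build_design_matrix",
    "fit_encoding_glm",
    "GLMFit",
    "variable_contributions",
    "cross_validate_mse",
]

#: kcal/ml for the solutions used in 30-min sessions
CALORIC_DENSITIES = {
    "intralipid": 2.0,
    "ensure": 0.923,
    "glucose": 0.96,
    "saline": 0.0,
    "water": 0.0,
    "dry": 0.0,
}

PREDICTORS = ("caloric_density", "licks_past_10s", "instantaneous_lick_rate")


def build_design_matrix(
    sessions: list[tuple[EventTrain, NormalizedTrace, float | str]],
) -> pd.DataFrame:
    """Concatenate per-second rows across sessions.

    Each session contributes one row per whole second t = 1..duration with
    licks in (t-10, t], licks in (t-1, t] (the instantaneous rate), the
    session's caloric density (a name from :data:`CALORIC_DENSITIES` or a
    number), and the response ``z`` averaged over the second (t-1, t].
    """
    frames = []
    for idx, (train, trace, density) in enumerate(sessions):
        if trace.z is None:
            raise ValueError("traces must be z-scored first")
        if isinstance(density, str):
            key = density.lower()
            if key not in CALORIC_DENSITIES:
                raise KeyError(f"no caloric density on record for tastant {density!r}")
            density = CALORIC_DENSITIES[key]
        seconds = np.arange(1.0, np.floor(trace.time[-1]) + 1.0)
        licks10 = trailing_lick_count(train.timestamps, seconds, 10.0)
        rate = trailing_lick_count(train.timestamps, seconds, 1.0)
        # mean z within (t-1, t]; trace grid is uniform so bincount over bins
        bin_idx = np.ceil(trace.time - 1e-9).astype(int)  # sample t falls in second ceil(t)
        valid = (bin_idx >= 1) & (bin_idx <= len(seconds))
        sums = np.bincount(bin_idx[valid], weights=trace.z[valid], minlength=len(seconds) + 1)
        counts = np.bincount(bin_idx[valid], minlength=len(seconds) + 1)
        with np.errstate(invalid="ignore"):
            z_sec = sums[1:] / counts[1:]
        frames.append(
            pd.DataFrame(
                {
                    "session": idx,
                    "second": seconds,
                    "caloric_density": float(density),
                    "licks_past_10s": licks10,
                    "instantaneous_lick_rate": rate,
                    "z": z_sec,
                }
            )
        )
    design = pd.concat(frames, ignore_index=True)
    if design[list(PREDICTORS) + ["z"]].isna().any().any():
        design = design.dropna().reset_index(drop=True)
    return design


@dataclass(frozen=True)
class GLMFit:
    coefficients: pd.Series  # includes "const"
    r_squared: float
    adjusted_r_squared: float
    predictors: tuple[str, ...]
    n_rows: int


def _ols(design: pd.DataFrame, predictors) -> sm.regression.linear_model.RegressionResults:
    X = sm.add_constant(design[list(predictors)].to_numpy(), has_constant="add")
    return sm.OLS(design["z"].to_numpy(), X).fit()


def fit_encoding_glm(design: pd.DataFrame, predictors=PREDICTORS) -> GLMFit:
    """Fit the Gaussian-identity encoding model with intercept.

    Raises on rank-deficient designs, naming the collinear columns.
    """
    predictors = tuple(predictors)
    if len(design) < 10 * (len(predictors) + 1):
        raise ValueError("need at least 10 rows per fitted parameter")
    X = design[list(predictors)].to_numpy()
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < len(predictors) + 1:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design; most collinear columns: "
            f"{predictors[i]!r}, {predictors[j]!r}"
        )
    res = _ols(design, predictors)
    coefs = pd.Series(res.params, index=["const", *predictors])
    return GLMFit(
        coefficients=coefs,
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        predictors=predictors,
        n_rows=len(design),
    )


def variable_contributions(design: pd.DataFrame, full_fit: GLMFit) -> dict[str, float]:
    """delta R^2 of each predictor: R^2(full) minus R^2(model without it)."""
    out = {}
    for var in full_fit.predictors:
        reduced = [p for p in full_fit.predictors if p != var]
        if reduced:
            r2_reduced = float(_ols(design, reduced).rsquared)
        else:
            r2_reduced = 0.0
        out[var] = full_fit.r_squared - r2_reduced
    return out


def cross_validate_mse(
    design: pd.DataFrame,
    predictors=PREDICTORS,
    train_fraction: float = 0.8,
    iterations: int = 100,
    seed: int = 0,
) -> float:
    """Mean held-out MSE over repeated random row splits.

    Each iteration permutes the rows (seeded), fits OLS on the first
    ``train_fraction`` and scores squared error on the remainder.
    """
    X = np.column_stack(
        [np.ones(len(design)), design[list(predictors)].to_numpy()]
    )
    y = design["z"].to_numpy()
    n = len(y)
    n_train = int(round(train_fraction * n))
    if n_train < X.shape[1] or n_train >= n:
        raise ValueError("degenerate train/test split")
    rng = np.random.default_rng(seed)
    mses = np.empty(iterations)
    for i in range(iterations):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        beta, *_ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
        resid = y[te] - X[te] @ beta
        mses[i] = np.mean(resid**2)
    return float(mses.mean())
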