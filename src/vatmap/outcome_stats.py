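"""Univariate activation-outcome regression and leave-one-out validation.

Improvement is regressed on bundle activation by ordinary least squares, with
both hemispheres of each patient pooled as independent observations.  The
reported quantities are the two-sided slope p-value (t statistic, n-2 df) and
adjusted R².  Predictive value is assessed by leave-one-out cross-validation:
the mean squared out-of-sample prediction error normalized by the outcome
variance over the whole group, whose complement r2_loo = 1 - error may be
negative when the fitted relation predicts worse than the group mean.

No multiple-testing correction is applied across structures; raw p-values
are reported and should be read accordingly when many structures are
screened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from vatmap.errors import (
    DegenerateFoldError,
    DegeneratePredictorError,
    InsufficientDataError,
)

__all__ = ["RegressionResult", "LooResult", "fit_univariate", "loo_cv", "structure_screen"]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of improvement ~ activation."""

    slope: float
    intercept: float
    slope_p: float
    r2_adj: float
    n: int


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out prediction error, normalized by group outcome variance."""

    one_minus_r2: float
    r2_loo: float
    n: int


def _extract_xy(obs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obs, pd.DataFrame):
        x = obs["activation"].to_numpy(dtype=np.float64)
        y = obs["improvement"].to_numpy(dtype=np.float64)
    else:
        x, y = obs
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected paired 1D activation/improvement, got {x.shape} vs {y.shape}")
    return x, y


def fit_univariate(obs) -> RegressionResult:
    """Ordinary least squares of improvement on activation.

    ``obs`` is either an observation DataFrame (columns ``activation``,
    ``improvement``) or an ``(x, y)`` pair of arrays.  Requires n >= 3 and a
    non-constant predictor.
    """
    x, y = _extract_xy(obs)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 observations to fit, got {n}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("activation has zero variance; slope is unidentifiable")
    if np.ptp(y) == 0:
        # constant outcome: slope 0 exactly, R^2 = 0 by convention, nothing significant
        return RegressionResult(
            slope=0.0,
            intercept=float(y[0]),
            slope_p=1.0,
            r2_adj=1.0 - (n - 1) / (n - 2),
            n=int(n),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_p=float(model.pvalues[1]),
        r2_adj=float(model.rsquared_adj),
        n=int(n),
    )


def loo_cv(obs, variance_ddof: int = 0) -> LooResult:
    """Leave-one-out validation of the univariate regression.

    Each observation is predicted from an OLS fit on the remaining n-1; the
    normalizer is the outcome variance over the whole group (population
    convention, ddof=0, by default — configurable), identical for every fold.
    """
    x, y = _extract_xy(obs)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 observations for leave-one-out, got {n}")
    var_y = float(np.var(y, ddof=variance_ddof))
    if var_y == 0:
        raise DegeneratePredictorError("outcome has zero variance; normalizer undefined")
    sq_err = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        xt, yt = x[mask], y[mask]
        if np.ptp(xt) == 0:
            raise DegenerateFoldError(f"fold {i}: training activations are constant")
        slope, intercept = np.polyfit(xt, yt, 1)
        sq_err[i] = (y[i] - (slope * x[i] + intercept)) ** 2
        mask[i] = True
    one_minus_r2 = float(sq_err.mean() / var_y)
    return LooResult(one_minus_r2=one_minus_r2, r2_loo=1.0 - one_minus_r2, n=int(n))


def structure_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Per-structure, per-partition regression and leave-one-out summary.

    Partitions are each cohort (when the observation table carries a
    ``cohort`` column) plus the pooled ``"joint"`` partition.  A structure
    whose fit fails in one partition (e.g. a degenerate predictor) is
    reported with NaN statistics and the error message in ``note`` rather
    than aborting the screen.  Output is sorted by ``r2_adj`` descending
    within each partition.
    """
    if "structure" not in table.columns:
        raise ValueError("observation table needs a 'structure' column")
    partitions: list[tuple[str, pd.DataFrame]] = []
    if "cohort" in table.columns:
        for name, sub in table.groupby("cohort", sort=True):
            partitions.append((str(name), sub))
    partitions.append(("joint", table))

    rows = []
    for pname, part in partitions:
        for structure, sub in part.groupby("structure", sort=True):
            rec = {
                "structure": structure,
                "partition": pname,
                "n": len(sub),
                "slope": np.nan,
                "p": np.nan,
                "r2_adj": np.nan,
                "r2_loo": np.nan,
                "note": "",
            }
            try:
                fit = fit_univariate(sub)
                rec.update(slope=fit.slope, p=fit.slope_p, r2_adj=fit.r2_adj)
            except Exception as exc:
                rec["note"] = f"fit: {exc}"
            try:
                loo = loo_cv(sub)
                rec["r2_loo"] = loo.r2_loo
            except Exception as exc:
                rec["note"] = (rec["note"] + "; " if rec["note"] else "") + f"loo: {exc}"
            rows.append(rec)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["partition", "r2_adj", "structure"], ascending=[True, False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)
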