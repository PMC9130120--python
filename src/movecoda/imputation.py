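"""Logratio-space imputation of missing and below-detection-limit parts.

Compositional operations require strictly positive parts, so missing
entries and (near-)zero values must be filled in *before* any logratio
transform. Two procedures are provided, both working in pivot ilr
coordinates (the part under repair moved to the first coordinate so that
the remaining coordinates depend only on the other parts):

* :func:`impute_missing` — EM-style iterative regression: each incomplete
  coordinate is regressed on the others over the complete records, the
  predictions replace the missing entries, and the cycle repeats until the
  coordinates stabilise.
* :func:`impute_below_limit` — replacement of values under a detection
  limit (e.g. MVPA under 0.5 min/day) by the conditional expectation of
  the pivot coordinate given the record's other parts, truncated below an
  effective ceiling of twice the limit. With a 0.5-min screen the
  replacements land just under one minute.

Observed entries of incomplete records are never modified by
:func:`impute_missing`; records entirely at or above the limit are never
modified by :func:`impute_below_limit`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionError

__all__ = ["DetectionLimitSpec", "ImputationResult", "impute_missing", "impute_below_limit"]


@dataclass(frozen=True)
class DetectionLimitSpec:
    """A per-part detection limit, in the units of the dataset (minutes)."""

    part: str
    limit: float = 0.5

    def __post_init__(self):
        if self.limit <= 0:
            raise ValueError(f"detection limit must be positive, got {self.limit}")


@dataclass
class ImputationResult:
    """Imputed dataset plus an audit log of every replaced value."""

    data: pd.DataFrame
    log: pd.DataFrame  # columns: row, part, old, new, method
    converged: bool = True
    n_iter: int = 0


def _pivot_coef(d: int) -> float:
    return np.sqrt((d - 1) / d)


def _pivot_rest(x: np.ndarray, j: int) -> np.ndarray:
    """Pivot ilr coordinates 2..D-1 for part ``j`` first: depend only on the
    other parts, so they are computable when part ``j`` is missing/zero."""
    others = np.delete(x, j, axis=1)
    lx = np.log(others)
    d = others.shape[1]
    out = np.empty((x.shape[0], d - 1))
    for k in range(d - 1):
        # contrast part k against the geometric mean of parts k+1..d-1
        tail = lx[:, k + 1 :].mean(axis=1)
        out[:, k] = np.sqrt((d - 1 - k) / (d - k)) * (lx[:, k] - tail)
    return out


def _pivot_first(x: np.ndarray, j: int) -> np.ndarray:
    """First pivot coordinate: part j against the geometric mean of the rest."""
    d = x.shape[1]
    others = np.delete(x, j, axis=1)
    return _pivot_coef(d) * (np.log(x[:, j]) - np.log(others).mean(axis=1))


def _value_from_pivot(z1: np.ndarray, x: np.ndarray, j: int) -> np.ndarray:
    """Invert the first pivot coordinate holding the other parts fixed."""
    d = x.shape[1]
    g = np.exp(np.log(np.delete(x, j, axis=1)).mean(axis=1))
    return g * np.exp(z1 / _pivot_coef(d))


def _ols_predict(y: np.ndarray, X: np.ndarray, X_new: np.ndarray):
    """Least-squares fit with intercept; returns predictions and residual SD."""
    A = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = max(len(y) - A.shape[1], 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    A_new = np.column_stack([np.ones(len(X_new)), X_new])
    return A_new @ beta, sigma


def impute_missing(
    data: pd.DataFrame,
    part_cols,
    *,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> ImputationResult:
    """Fill missing part values by iterative regression in ilr coordinates.

    Parameters
    ----------
    data : DataFrame with one row per record; ``part_cols`` are the
        behavior columns in minutes; missingness is NaN.
    part_cols : ordered behavior column names.
    max_iter, tol : convergence control on the imputed pivot coordinates.

    Observed entries keep their exact input values; each imputed entry is
    scaled to be consistent with its record's observed total.
    """
    part_cols = list(part_cols)
    out = data.copy()
    vals = out[part_cols].to_numpy(dtype=float)
    miss = ~np.isfinite(vals)

    if miss.all(axis=1).any():
        bad = out.index[miss.all(axis=1)][0]
        raise CompositionError(f"record {bad!r} has every part missing; cannot impute")
    if not miss.any():
        return ImputationResult(out, _empty_log(), True, 0)

    complete = ~miss.any(axis=1)
    if complete.sum() < 10:
        raise CompositionError(
            f"need at least 10 complete records to train the imputer, have {int(complete.sum())}"
        )
    if np.nan_to_num(vals, nan=1.0).min() <= 0:
        raise CompositionError("observed parts must be strictly positive before imputation")

    d = len(part_cols)
    # work on proportions; remember each record's observed minute total so
    # imputed entries can be returned on the original scale
    obs_sum = np.where(miss, 0.0, vals).sum(axis=1)
    # initialise missing entries at the complete-records' compositional mean share
    comp_props = vals[complete] / vals[complete].sum(axis=1, keepdims=True)
    center = np.exp(np.log(comp_props).mean(axis=0))
    center /= center.sum()
    work = vals.copy()
    for j in range(d):
        rows = miss[:, j]
        if rows.any():
            # initial guess keeps observed minutes, sets the missing part at the
            # center's share relative to the observed remainder
            obs_share = 1.0 - center[j]
            work[rows, j] = center[j] / obs_share * obs_sum[rows]
    work = work / work.sum(axis=1, keepdims=True)

    converged = False
    it = 0
    prev = None
    for it in range(1, max_iter + 1):
        cur = []
        for j in range(d):
            rows = np.flatnonzero(miss[:, j])
            if rows.size == 0:
                continue
            obs_rows = np.flatnonzero(~miss[:, j])
            z_rest = _pivot_rest(work, j)
            z1 = _pivot_first(work[obs_rows], j)
            pred, _ = _ols_predict(z1, z_rest[obs_rows], z_rest[rows])
            new_vals = _value_from_pivot(pred, work[rows], j)
            work[rows, j] = new_vals
            work[rows] /= work[rows].sum(axis=1, keepdims=True)
            cur.append(pred)
        cur = np.concatenate(cur)
        if prev is not None and np.max(np.abs(cur - prev)) < tol:
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn(
            f"missing-value imputation did not converge in {max_iter} iterations; "
            "returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    # back to minutes: observed entries untouched, imputed entries scaled so
    # the record's observed parts keep their exact input values
    result = vals.copy()
    log_rows = []
    for i in np.flatnonzero(miss.any(axis=1)):
        obs = ~miss[i]
        scale = vals[i, obs].sum() / work[i, obs].sum()
        for j in np.flatnonzero(miss[i]):
            new = work[i, j] * scale
            result[i, j] = new
            log_rows.append(
                {
                    "row": out.index[i],
                    "part": part_cols[j],
                    "old": np.nan,
                    "new": float(new),
                    "method": "iterative_ilr_regression",
                }
            )
    out[part_cols] = result
    return ImputationResult(out, pd.DataFrame(log_rows, columns=_LOG_COLS), converged, it)


_LOG_COLS = ["row", "part", "old", "new", "method"]


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=_LOG_COLS)


def impute_below_limit(
    data: pd.DataFrame,
    part_cols,
    spec: DetectionLimitSpec,
    *,
    which: str = "below",
    method: str = "regression",
    ceiling_factor: float = 2.0,
    fallback_fraction: float = 0.65,
) -> ImputationResult:
    """Replace values of one part lying under a detection limit.

    Parameters
    ----------
    spec : the part name (one of ``part_cols``) and the limit in minutes.
    which : ``"below"`` treats every value strictly under the limit as
        unobserved (the sensitivity screen); ``"zeros"`` repairs only exact
        zeros, using the limit as the detection-limit parameter (the main
        analysis, where genuine sub-limit values are left as recorded).
    method : ``"regression"`` predicts the part's pivot coordinate from the
        record's other parts over the records at/above the limit and takes
        the expectation truncated below ``ceiling_factor * limit``;
        ``"multiplicative"`` replaces by ``fallback_fraction * limit`` and
        rescales the other parts to preserve the record total.

    Replacements are strictly positive; regression replacements are never
    below the recorded value and are bounded by ``ceiling_factor * limit``.
    Each repaired record is reclosed to its original total.
    """
    part_cols = list(part_cols)
    if spec.part not in part_cols:
        raise CompositionError(f"unknown part {spec.part!r}; have {part_cols}")
    if which not in ("below", "zeros"):
        raise ValueError(f"which must be 'below' or 'zeros', got {which!r}")
    if method not in ("regression", "multiplicative"):
        raise ValueError(f"unknown method {method!r}")

    out = data.copy()
    vals = out[part_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise CompositionError("impute missing values before the detection-limit screen")
    j = part_cols.index(spec.part)
    other = np.delete(vals, j, axis=1)
    if np.any(other <= 0):
        raise CompositionError(
            "a record has nonpositive values outside the screened part; "
            "cannot predict the replacement"
        )

    col = vals[:, j]
    mask = (col == 0.0) if which == "zeros" else (col < spec.limit)
    if not mask.any():
        return ImputationResult(out, _empty_log(), True, 0)

    totals = vals.sum(axis=1)
    props = vals / totals[:, None]
    cap_min = ceiling_factor * spec.limit

    if method == "multiplicative":
        new_min = np.full(mask.sum(), fallback_fraction * spec.limit)
    else:
        train = col >= spec.limit
        if train.sum() < 10:
            raise CompositionError(
                f"need at least 10 records at/above the limit to train, have {int(train.sum())}"
            )
        # rest coordinates never touch column j, so zeros there are safe
        z_rest = _pivot_rest(props, j)
        z1_train = _pivot_first(props[train], j)
        pred, sigma = _ols_predict(z1_train, z_rest[train], z_rest[mask])
        # ceiling in coordinate space, per record (depends on its other parts)
        rows = np.flatnonzero(mask)
        cap_prop = cap_min / totals[rows]
        g = np.exp(np.log(np.delete(props[rows], j, axis=1)).mean(axis=1))
        z_cap = _pivot_coef(props.shape[1]) * (np.log(cap_prop) - np.log(g))
        if sigma <= 0:
            z_new = np.minimum(pred, z_cap)
        else:
            a = (-np.inf - pred) / sigma
            b = (z_cap - pred) / sigma
            z_new = stats.truncnorm.mean(a, b, loc=pred, scale=sigma)
        new_prop = _value_from_pivot(z_new, props[rows], j)
        new_min = new_prop * totals[rows]

    rows = np.flatnonzero(mask)
    if method == "regression":
        # never decrease a recorded value; always stay under the ceiling
        new_min = np.clip(new_min, np.maximum(col[rows], 1e-12), cap_min)
    log_rows = [
        {
            "row": out.index[i],
            "part": spec.part,
            "old": float(col[i]),
            "new": float(v),
            "method": f"below_limit_{method}",
        }
        for i, v in zip(rows, new_min)
    ]
    repaired = vals.copy()
    repaired[rows, j] = new_min
    if method == "multiplicative":
        # spread the added minutes over the other parts
        other_scale = (totals[rows] - new_min) / np.delete(repaired[rows], j, axis=1).sum(axis=1)
        for r, i in enumerate(rows):
            for jj in range(len(part_cols)):
                if jj != j:
                    repaired[i, jj] *= other_scale[r]
    else:
        # reclose the repaired records to their original totals
        repaired[rows] *= (totals[rows] / repaired[rows].sum(axis=1))[:, None]
    out[part_cols] = repaired
    return ImputationResult(out, pd.DataFrame(log_rows, columns=_LOG_COLS), True, 1)
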