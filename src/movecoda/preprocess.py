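"""Day-level validity filtering, participant inclusion, and aggregation.

Input is accelerometer-derived day records: minutes of SED, LPA, MVPA and
sleep per measurement day (in-bed time to next in-bed time, so day lengths
hover around 1410–1430 min rather than exactly 1440), with the day's
waking wear time as quality metadata. The pipeline is

1. keep valid days — at least 10 h (600 min) of waking wear;
2. keep participants with at least ``min_days`` valid days at every
   required timepoint (the trial rule: 4 days at both baseline and the
   6-month point);
3. collapse each subject-timepoint's valid days into one composition,
   by default the compositional (geometric) mean of the day compositions.

Missing behavior values (empty CSV fields) propagate through aggregation
as NaN and are repaired afterwards by :mod:`movecoda.imputation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import CANONICAL_PARTS, CompositionError, closure

__all__ = [
    "PART_COLS",
    "DAY_COLS",
    "SUBJECT_COLS",
    "MIN_WEAR_MIN",
    "MIN_VALID_DAYS",
    "load_days",
    "load_subjects",
    "filter_valid_days",
    "filter_participants",
    "aggregate_subject_timepoint",
]

#: Behavior columns, aligned with the canonical part order (SED, LPA, MVPA, SLEEP).
PART_COLS: tuple[str, ...] = ("sed_min", "lpa_min", "mvpa_min", "sleep_min")
DAY_COLS: tuple[str, ...] = (
    "subject_id",
    "timepoint",
    "day_index",
    *PART_COLS,
    "waking_wear_min",
    "day_length_min",
)
SUBJECT_COLS: tuple[str, ...] = ("subject_id", "group", "gender", "age")

GROUPS = ("control", "intervention")
GENDERS = ("woman", "man")

#: Valid-day rule: at least 10 h of waking wear.
MIN_WEAR_MIN: float = 600.0
#: Inclusion rule: at least this many valid days at every required timepoint.
MIN_VALID_DAYS: int = 4


class SchemaError(ValueError):
    pass


def load_days(path) -> pd.DataFrame:
    """Read a day-level CSV (columns :data:`DAY_COLS`; empty fields = missing)."""
    df = pd.read_csv(path)
    missing = set(DAY_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"day file lacks columns {sorted(missing)}")
    _check_day_invariants(df)
    return df


def _check_day_invariants(df: pd.DataFrame) -> None:
    if (df["day_length_min"] <= 0).any():
        raise SchemaError("day_length_min must be positive")
    if (df["waking_wear_min"] > df["day_length_min"] + 1e-9).any():
        raise SchemaError("waking wear time exceeds day length")
    vals = df[list(PART_COLS)]
    if (vals.lt(0)).any().any():
        raise SchemaError("behavior minutes must be nonnegative")
    if vals.gt(df["day_length_min"], axis=0).any().any():
        raise SchemaError("a behavior exceeds its day length")


def load_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLS) - set(df.columns)
    if missing:
        raise SchemaError(f"subject file lacks columns {sorted(missing)}")
    bad_group = set(df["group"].unique()) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
    bad_gender = set(df["gender"].unique()) - set(GENDERS)
    if bad_gender:
        raise SchemaError(f"unknown gender labels {sorted(bad_gender)}; expected {GENDERS}")
    if (df["age"] <= 0).any():
        raise SchemaError("age must be positive")
    return df


def filter_valid_days(days: pd.DataFrame, min_wear: float = MIN_WEAR_MIN) -> tuple[pd.DataFrame, int]:
    """Retain days with at least ``min_wear`` minutes of waking wear.

    The boundary is inclusive ("at least 10 h"). Returns the retained days
    in their original order and the count removed.
    """
    keep = days["waking_wear_min"] >= min_wear
    return days.loc[keep].copy(), int((~keep).sum())


@dataclass
class ExclusionRecord:
    subject_id: object
    reason: str


def filter_participants(
    days: pd.DataFrame,
    subjects: pd.DataFrame,
    required_timepoints=("baseline", "m6"),
    min_days: int = MIN_VALID_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Keep subjects with >= ``min_days`` valid days at every required timepoint.

    ``days`` must already be valid-day filtered. Returns (days, subjects,
    exclusions) where exclusions lists each dropped subject with a reason.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    counts = (
        days[days["timepoint"].isin(required_timepoints)]
        .groupby(["subject_id", "timepoint"], sort=False)
        .size()
        .unstack(fill_value=0)
    )
    excluded = []
    for sid in subjects["subject_id"]:
        for tp in required_timepoints:
            n = int(counts.loc[sid, tp]) if (sid in counts.index and tp in counts.columns) else 0
            if n < min_days:
                excluded.append(
                    {"subject_id": sid, "reason": f"{n} valid days at {tp} (< {min_days})"}
                )
                break
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    drop = set(exclusions["subject_id"])
    subjects_kept = subjects[~subjects["subject_id"].isin(drop)].copy()
    if subjects_kept.empty:
        raise CompositionError("no participants survive the inclusion rule")
    days_kept = days[~days["subject_id"].isin(drop)].copy()
    return days_kept, subjects_kept, exclusions


def aggregate_subject_timepoint(
    days: pd.DataFrame,
    method: str = "compositional",
    constant: float = 1440.0,
    strict: bool = False,
) -> pd.DataFrame:
    """Collapse valid days into one composition per (subject, timepoint).

    ``method="compositional"`` (default) closes each day and takes the
    component-wise geometric mean, the center of the day compositions in
    Aitchison geometry; ``"arithmetic"`` averages raw minutes. Both are
    closed to ``constant`` (1440 min) when all parts are positive.

    Missing parts (NaN) propagate to the aggregate and are left unclosed
    for downstream imputation, as are zero parts; with ``strict=True`` a
    zero part raises instead, for pipelines that impute at day level.
    """
    if method not in ("compositional", "arithmetic"):
        raise ValueError(f"unknown aggregation method {method!r}")
    rows = []
    for (sid, tp), grp in days.groupby(["subject_id", "timepoint"], sort=False):
        vals = grp[list(PART_COLS)].to_numpy(dtype=float)
        if strict and np.nanmin(vals) <= 0:
            raise CompositionError(
                f"zero part for subject {sid!r} at {tp!r}: impute before aggregation "
                "or aggregate with strict=False and impute the aggregates"
            )
        if method == "compositional":
            with np.errstate(divide="ignore"):
                # close each day, then geometric mean; a zero day gives a zero
                # aggregate part, repaired later by the detection-limit screen
                props = vals / np.nansum(vals, axis=1, keepdims=True)
                agg = np.exp(np.mean(np.log(props), axis=0))
            if np.isnan(vals).any():
                cols_ok = ~np.isnan(vals).any(axis=0)
                # with a missing part the day shares are not defined; average
                # the observed minutes per part and leave the rest NaN
                agg = np.full(len(PART_COLS), np.nan)
                agg[cols_ok] = np.exp(np.log(vals[:, cols_ok]).mean(axis=0))
        else:
            agg = vals.mean(axis=0)
        if np.all(np.isfinite(agg)) and np.all(agg > 0):
            agg = closure(agg, constant)
        else:
            if not np.isnan(agg).any():
                # keep zeros but scale the record to the reporting total
                agg = constant * agg / agg.sum()
            warnings.warn(
                f"subject {sid!r} at {tp!r} has missing or zero parts; "
                "pass the aggregates through imputation before ilr",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append({"subject_id": sid, "timepoint": tp, "n_days": len(grp),
                     **dict(zip(PART_COLS, agg))})
    return pd.DataFrame(rows)
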