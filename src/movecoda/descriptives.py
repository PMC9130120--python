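"""Descriptive layer: compositional mean tables, change compositions,
ternary exports and confidence regions.

The change (perturbation difference) between two timepoints divides the
later composition by the earlier one, component-wise, and recloses: the
uniform composition means "no change", a part above 1/D grew relative to
the others. Changes are visualised as the four 3-of-4 subcompositions on
ternary plots, with elliptical confidence regions computed under a
normality assumption on the Mahalanobis distance of the logratio
(2-D ilr) transform of each 3-part subcomposition.

Two region kinds are supported: ``mean`` regions for the group mean
(Hotelling-T² quantile) and ``data`` regions covering the underlying
distribution (chi-square(2) quantile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .balances import BalancePartition, movement_partition
from .composition import (
    CANONICAL_PARTS,
    CompositionError,
    closure,
    compositional_mean,
    perturb_difference,
    ternary_coords,
)
from .preprocess import PART_COLS

__all__ = [
    "mean_table",
    "change_compositions",
    "ternary_panels",
    "ConfidenceRegion",
    "confidence_region",
    "group_regions",
    "SUBCOMP_PANELS",
]

#: The four 3-of-4 subcompositions (panel label -> kept parts, canonical order).
SUBCOMP_PANELS: dict[str, tuple[str, str, str]] = {
    "A": ("SED", "LPA", "SLEEP"),
    "B": ("SED", "LPA", "MVPA"),
    "C": ("SED", "MVPA", "SLEEP"),
    "D": ("LPA", "MVPA", "SLEEP"),
}

_PART_TO_COL = dict(zip(CANONICAL_PARTS, PART_COLS))


def mean_table(
    data: pd.DataFrame,
    subjects: pd.DataFrame,
    groups=("control", "intervention"),
    timepoints=("baseline", "m6"),
    constant: float = 1440.0,
) -> pd.DataFrame:
    """Compositional mean per (group, timepoint), scaled to ``constant`` minutes.

    ``data`` holds one row per subject-timepoint with the behavior columns;
    group membership comes from ``subjects``. Every output row sums to
    ``constant`` (1440 min = 24 h by default).
    """
    merged = data.merge(subjects[["subject_id", "group"]], on="subject_id", validate="m:1")
    rows = []
    for g in groups:
        for tp in timepoints:
            cell = merged[(merged["group"] == g) & (merged["timepoint"] == tp)]
            if cell.empty:
                raise CompositionError(f"empty mean-table cell: group={g!r}, timepoint={tp!r}")
            m = compositional_mean(cell[list(PART_COLS)].to_numpy(), constant)
            rows.append({"group": g, "timepoint": tp, "n": len(cell), **dict(zip(PART_COLS, m))})
    return pd.DataFrame(rows)


def change_compositions(
    data: pd.DataFrame,
    from_tp: str = "baseline",
    to_tp: str = "m6",
) -> pd.DataFrame:
    """Per-subject change composition between two timepoints (closed to 1).

    Subjects missing either timepoint are skipped. The resulting rows use
    the behavior columns as proportions of the change composition.
    """
    a = data[data["timepoint"] == from_tp].set_index("subject_id")[list(PART_COLS)]
    b = data[data["timepoint"] == to_tp].set_index("subject_id")[list(PART_COLS)]
    common = a.index.intersection(b.index)
    if common.empty:
        raise CompositionError(f"no subjects present at both {from_tp!r} and {to_tp!r}")
    diff = perturb_difference(b.loc[common].to_numpy(), a.loc[common].to_numpy())
    out = pd.DataFrame(diff, columns=list(PART_COLS))
    out.insert(0, "subject_id", common.to_numpy())
    return out


def ternary_panels(changes: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Ternary coordinates of every 3-of-4 subcomposition of the changes.

    One output row per (panel, subject): panel label, kept parts, group,
    abscissa and ordinate on the unit-side reference triangle.
    """
    merged = changes.merge(subjects[["subject_id", "group"]], on="subject_id", validate="1:1")
    rows = []
    for panel, parts in SUBCOMP_PANELS.items():
        cols = [_PART_TO_COL[p] for p in parts]
        sub = closure(merged[cols].to_numpy())
        xy = ternary_coords(sub)
        for (_, rec), (x, y) in zip(merged.iterrows(), xy):
            rows.append(
                {
                    "panel": panel,
                    "parts": "-".join(parts),
                    "group": rec["group"],
                    "subject_id": rec["subject_id"],
                    "abscissa": x,
                    "ordinate": y,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfidenceRegion:
    """Elliptical region for a 3-part compositional sample.

    ``center``/``shape`` live in the 2-D ilr plane of the subcomposition
    (``basis`` maps that plane back to the simplex); ``quantile`` is the
    squared Mahalanobis radius of the boundary.
    """

    center: np.ndarray
    shape: np.ndarray
    quantile: float
    level: float
    kind: str
    n: int
    partition: BalancePartition

    def contains(self, point) -> bool:
        """Is a 3-part composition (or 2-D coordinate pair) inside the region?"""
        from .balances import ilr

        u = np.asarray(point, dtype=float)
        if u.shape[-1] == 3:
            u = ilr(closure(u), self.partition)
        d = u - self.center
        return bool(d @ np.linalg.solve(self.shape, d) <= self.quantile)

    def boundary_coords(self, n_points: int = 360) -> np.ndarray:
        """(n, 2) ilr-plane boundary, counter-clockwise, closed on itself."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.shape)
        pts = self.center + np.sqrt(self.quantile) * circle @ L.T
        return np.vstack([pts, pts[:1]])

    def boundary_ternary(self, n_points: int = 360) -> np.ndarray:
        """Boundary mapped back through the subcomposition to ternary (x, y)."""
        from .balances import ilr_inverse

        comps = ilr_inverse(self.boundary_coords(n_points), self.partition)
        return ternary_coords(comps)


def confidence_region(
    points,
    level: float = 0.95,
    kind: str = "mean",
    partition: BalancePartition | None = None,
    labels: tuple[str, str, str] | None = None,
) -> ConfidenceRegion:
    """Normal-theory elliptical region for 3-part compositions.

    The points are mapped to the 2-D ilr plane (basis from the movement
    partition restricted to the three parts, unless ``partition`` is
    given); the region center is the coordinate mean and its shape the
    sample covariance. ``kind="mean"`` bounds the squared Mahalanobis
    distance of the *mean* by the Hotelling-T²/F quantile
    2(n-1)/(n(n-2)) · F(level; 2, n-2); ``kind="data"`` bounds individual
    observations by the chi-square(2) quantile.
    """
    from .balances import ilr

    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise CompositionError("confidence_region expects an (n, 3) array of compositions")
    n = x.shape[0]
    if n < 4:
        raise CompositionError(f"need at least 4 points for a confidence region, got {n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if kind not in ("mean", "data"):
        raise ValueError(f"kind must be 'mean' or 'data', got {kind!r}")
    if partition is None:
        if labels is None:
            labels = ("SED", "LPA", "SLEEP")
        partition = movement_partition().restrict(labels)
    z = ilr(closure(x), partition)
    center = z.mean(axis=0)
    shape = np.cov(z, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(shape) < 2 or np.linalg.det(shape) <= 0:
        raise CompositionError("singular coordinate covariance; region undefined")
    if kind == "mean":
        q = 2.0 * (n - 1) / (n * (n - 2)) * stats.f.ppf(level, 2, n - 2)
    else:
        q = stats.chi2.ppf(level, 2)
    return ConfidenceRegion(center, shape, float(q), level, kind, n, partition)


def group_regions(
    changes: pd.DataFrame,
    subjects: pd.DataFrame,
    level: float = 0.95,
    kind: str = "mean",
    n_boundary: int = 360,
) -> pd.DataFrame:
    """Confidence-region boundaries for every panel × group of the changes.

    Returns a long table (panel, parts, group, kind, level, vertex,
    abscissa, ordinate) ready for CSV export; 6 significant digits.
    """
    merged = changes.merge(subjects[["subject_id", "group"]], on="subject_id", validate="1:1")
    rows = []
    for panel, parts in SUBCOMP_PANELS.items():
        cols = [_PART_TO_COL[p] for p in parts]
        for g, grp in merged.groupby("group", sort=True):
            region = confidence_region(
                grp[cols].to_numpy(), level=level, kind=kind, labels=parts
            )
            xy = region.boundary_ternary(n_boundary)
            for v, (x, y) in enumerate(xy):
                rows.append(
                    {
                        "panel": panel,
                        "parts": "-".join(parts),
                        "group": g,
                        "kind": kind,
                        "level": level,
                        "vertex": v,
                        "abscissa": float(f"{x:.6g}"),
                        "ordinate": float(f"{y:.6g}"),
                    }
                )
    return pd.DataFrame(rows)
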