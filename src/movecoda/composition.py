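"""Aitchison-geometry primitives for D-part compositions.

A *composition* is a vector of strictly positive parts carrying only
relative information: a day split into sedentary time (SED), light
physical activity (LPA), moderate-to-vigorous physical activity (MVPA)
and sleep is the running example, with the canonical part order
``(SED, LPA, MVPA, SLEEP)`` used throughout the package.

All operations here live on the simplex: *closure* rescales a vector to a
constant sum (1 for internal work, 1440 min for reporting); *perturbation*
is component-wise multiplication followed by closure — the simplex
analogue of addition; the *compositional mean* is the closed
component-wise geometric mean. Everything accepts either a single part
vector or a 2-D array of row vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_PARTS",
    "MINUTES_PER_DAY",
    "Composition",
    "TernaryPoint",
    "closure",
    "perturb",
    "power",
    "perturb_difference",
    "compositional_mean",
    "clr",
    "aitchison_distance",
    "subcomposition",
    "ternary_coords",
]

#: Canonical behavior order used by every dataset in the package.
CANONICAL_PARTS: tuple[str, ...] = ("SED", "LPA", "MVPA", "SLEEP")

#: Reporting closure constant: minutes in 24 h.
MINUTES_PER_DAY: float = 1440.0

_SUM_RTOL = 1e-9


class CompositionError(ValueError):
    """Raised for invalid compositional input (nonpositive parts, bad labels)."""


def _as_array(parts, name: str = "parts") -> np.ndarray:
    x = np.asarray(parts, dtype=float)
    if x.ndim not in (1, 2):
        raise CompositionError(f"{name} must be a vector or matrix of parts, got ndim={x.ndim}")
    return x


def _check_positive(x: np.ndarray, labels=None) -> None:
    if not np.all(np.isfinite(x)):
        raise CompositionError("parts must be finite; impute missing values first")
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)
        if x.ndim == 1:
            j = int(bad[0][0])
            part = labels[j] if labels is not None else f"part {j}"
            raise CompositionError(
                f"nonpositive value {x[j]!r} in {part}; zeros must pass through imputation first"
            )
        i, j = (int(v) for v in bad[0])
        part = labels[j] if labels is not None else f"part {j}"
        raise CompositionError(
            f"nonpositive value in record {i}, {part}; zeros must pass through imputation first"
        )


def closure(parts, constant: float = 1.0, *, labels=None) -> np.ndarray:
    """Rescale ``parts`` (rows) to sum to ``constant``, preserving ratios."""
    if constant <= 0:
        raise CompositionError(f"closure constant must be positive, got {constant}")
    x = _as_array(parts)
    _check_positive(x, labels)
    total = x.sum(axis=-1, keepdims=True)
    return constant * x / total


def perturb(x, y, constant: float = 1.0) -> np.ndarray:
    """Aitchison perturbation x ⊕ y: closed component-wise product."""
    return closure(_as_array(x) * _as_array(y), constant)


def power(x, a: float, constant: float = 1.0) -> np.ndarray:
    """Aitchison powering a ⊙ x: closed component-wise power."""
    xa = _as_array(x)
    _check_positive(xa)
    return closure(xa**a, constant)


def perturb_difference(after, before, constant: float = 1.0) -> np.ndarray:
    """Change composition: closure of the component-wise ratio after/before.

    The "no change" result is the uniform composition (1/D, ..., 1/D);
    parts above 1/D grew relative to the others, parts below shrank.
    """
    a = _as_array(after, "after")
    b = _as_array(before, "before")
    if a.shape[-1] != b.shape[-1]:
        raise CompositionError(
            f"part count mismatch: after has {a.shape[-1]}, before has {b.shape[-1]}"
        )
    _check_positive(a)
    _check_positive(b)
    return closure(a / b, constant)


def compositional_mean(samples, constant: float = 1.0) -> np.ndarray:
    """Closed component-wise geometric mean of a sample of compositions.

    This is the center of a compositional sample; it commutes with the ilr
    transform (ilr of the mean equals the arithmetic mean of the ilr values).
    """
    x = _as_array(samples, "samples")
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        raise CompositionError("compositional_mean of an empty collection")
    _check_positive(x)
    g = np.exp(np.log(x).mean(axis=0))
    return closure(g, constant)


def clr(x) -> np.ndarray:
    """Centered logratio: ln(x_i / geometric mean of the row)."""
    xa = _as_array(x)
    _check_positive(xa)
    lx = np.log(xa)
    return lx - lx.mean(axis=-1, keepdims=True)


def aitchison_distance(x, y) -> float | np.ndarray:
    """Scale-invariant simplex metric: Euclidean distance between clr vectors."""
    d = clr(x) - clr(y)
    return np.sqrt((d**2).sum(axis=-1))


def subcomposition(x, keep, labels=CANONICAL_PARTS, constant: float = 1.0) -> np.ndarray:
    """Reclose the parts named in ``keep`` (order taken from ``keep``)."""
    keep = tuple(keep)
    if len(set(keep)) != len(keep):
        raise CompositionError(f"duplicate labels in keep={keep}")
    try:
        idx = [list(labels).index(k) for k in keep]
    except ValueError as exc:
        raise CompositionError(f"unknown part label in keep={keep}; have {tuple(labels)}") from exc
    xa = _as_array(x)
    return closure(xa[..., idx], constant, labels=keep)


# Reference triangle: vertex of part 1 at the origin, part 2 at (1, 0),
# part 3 at the apex (1/2, sqrt(3)/2). Barycentric -> Cartesian is affine.
_TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_coords(x3) -> np.ndarray:
    """2-D Cartesian embedding of 3-part compositions for ternary plotting.

    Rows are closed to 1 and mapped barycentrically onto an equilateral
    triangle with unit side; pure compositions land on the corners and the
    uniform composition on the centroid.
    """
    p = closure(_as_array(x3))
    if p.shape[-1] != 3:
        raise CompositionError(f"ternary projection needs 3 parts, got {p.shape[-1]}")
    return p @ _TERNARY_VERTICES


@dataclass(frozen=True)
class TernaryPoint:
    abscissa: float
    ordinate: float


@dataclass(frozen=True)
class Composition:
    """One strictly positive D-part composition with named parts.

    Thin convenience wrapper over the array-level functions; datasets are
    handled as arrays/DataFrames, this type is the atom for single records.
    """

    parts: np.ndarray
    labels: tuple[str, ...] = CANONICAL_PARTS
    constant: float = 1.0

    def __post_init__(self):
        x = _as_array(self.parts)
        if x.ndim != 1:
            raise CompositionError("Composition holds a single part vector")
        if len(self.labels) != x.shape[0]:
            raise CompositionError(
                f"{len(self.labels)} labels for {x.shape[0]} parts"
            )
        closed = closure(x, self.constant, labels=self.labels)
        if not np.allclose(closed, x, rtol=_SUM_RTOL, atol=0):
            x = closed
        object.__setattr__(self, "parts", x)

    @classmethod
    def close(cls, parts, constant: float = 1.0, labels: tuple[str, ...] = CANONICAL_PARTS):
        return cls(closure(parts, constant, labels=labels), labels, constant)

    def with_constant(self, constant: float) -> "Composition":
        return Composition(closure(self.parts, constant), self.labels, constant)

    def perturb(self, other: "Composition") -> "Composition":
        self._check_labels(other)
        return Composition(perturb(self.parts, other.parts, self.constant), self.labels, self.constant)

    def difference(self, before: "Composition") -> "Composition":
        """Change composition self ⊖ before (ratios, reclosed)."""
        self._check_labels(before)
        return Composition(
            perturb_difference(self.parts, before.parts, self.constant), self.labels, self.constant
        )

    def inverse(self) -> "Composition":
        return Composition(closure(1.0 / self.parts, self.constant), self.labels, self.constant)

    def sub(self, keep) -> "Composition":
        return Composition(
            subcomposition(self.parts, keep, self.labels, 1.0), tuple(keep), 1.0
        )

    def ternary(self) -> TernaryPoint:
        xy = ternary_coords(self.parts)
        return TernaryPoint(float(xy[0]), float(xy[1]))

    def distance(self, other: "Composition") -> float:
        self._check_labels(other)
        return float(aitchison_distance(self.parts, other.parts))

    def _check_labels(self, other: "Composition") -> None:
        if self.labels != other.labels:
            raise CompositionError(
                f"part labels differ: {self.labels} vs {other.labels}"
            )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.parts, dtype=dtype)
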