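"""Sequential binary partitions and isometric logratio balance coordinates.

A sequential binary partition (SBP) recursively splits the D parts of a
composition into a positive and a negative group; each split defines one
*balance*: a normalised logratio of the geometric means of the two groups,

    z_k = sqrt(p_k m_k / (p_k + m_k)) * ln( g(positive parts) / g(negative parts) )

where p_k and m_k count the parts in the two groups. The D-1 balances form
an orthonormal isometric logratio (ilr) coordinate system: the map is a
bijective isometry between the simplex (Aitchison metric) and R^{D-1}.

The shipped default, :func:`movement_partition`, is the three-balance
contrast used for 24-h movement behaviors:

* z1 — active (LPA, MVPA) vs. passive (SED, sleep); positive when the
  active behaviors dominate,
* z2 — LPA vs. MVPA,
* z3 — SED vs. sleep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import CANONICAL_PARTS, CompositionError, closure, clr

__all__ = [
    "BalancePartition",
    "movement_partition",
    "ilr",
    "ilr_inverse",
    "MOVEMENT_COORD_NAMES",
]

#: Table-style block labels for the three default balances.
MOVEMENT_COORD_NAMES: tuple[str, ...] = (
    "Coordinate 1 (active vs. passive movement behaviors)",
    "Coordinate 2 (LPA vs. MVPA)",
    "Coordinate 3 (SED vs. sleep)",
)


class PartitionError(ValueError):
    """Raised for sign tables that do not form a valid SBP."""


def _basis_from_signs(signs: np.ndarray) -> np.ndarray:
    """Orthonormal balancing elements from a (D-1, D) sign table."""
    k, d = signs.shape
    basis = np.zeros((k, d))
    for r in range(k):
        pos = signs[r] > 0
        neg = signs[r] < 0
        p, m = pos.sum(), neg.sum()
        basis[r, pos] = np.sqrt(m / (p * (p + m)))
        basis[r, neg] = -np.sqrt(p / (m * (p + m)))
    return basis


@dataclass(frozen=True)
class BalancePartition:
    """A validated SBP sign table with its orthonormal ilr basis.

    ``sign_table`` has one row per balance and one column per part, with
    entries +1 (numerator group), -1 (denominator group) and 0 (inactive).
    Rows must split the parts top-down: the first row partitions all D
    parts; every later row partitions a group left intact so far.
    """

    sign_table: np.ndarray
    labels: tuple[str, ...] = CANONICAL_PARTS

    def __post_init__(self):
        s = np.asarray(self.sign_table, dtype=int)
        if s.ndim != 2:
            raise PartitionError("sign table must be 2-D")
        k, d = s.shape
        if d != len(self.labels):
            raise PartitionError(f"{d} columns for {len(self.labels)} part labels")
        if k != d - 1:
            raise PartitionError(f"an SBP over {d} parts needs {d - 1} rows, got {k}")
        if not np.all(np.isin(s, (-1, 0, 1))):
            raise PartitionError("sign table entries must be in {-1, 0, +1}")
        self._validate_sbp(s)
        object.__setattr__(self, "sign_table", s)

    @staticmethod
    def _validate_sbp(s: np.ndarray) -> None:
        d = s.shape[1]
        groups = [frozenset(range(d))]  # unsplit groups, tree frontier
        for r, row in enumerate(s):
            pos = frozenset(np.flatnonzero(row > 0).tolist())
            neg = frozenset(np.flatnonzero(row < 0).tolist())
            if not pos or not neg:
                raise PartitionError(f"row {r} needs at least one +1 and one -1")
            support = pos | neg
            if support not in groups:
                raise PartitionError(
                    f"row {r} does not partition a previously intact group"
                )
            groups.remove(support)
            if len(pos) > 1:
                groups.append(pos)
            if len(neg) > 1:
                groups.append(neg)

    @property
    def n_parts(self) -> int:
        return self.sign_table.shape[1]

    @property
    def n_coords(self) -> int:
        return self.sign_table.shape[0]

    @property
    def positive_counts(self) -> np.ndarray:
        return (self.sign_table > 0).sum(axis=1)

    @property
    def negative_counts(self) -> np.ndarray:
        return (self.sign_table < 0).sum(axis=1)

    @property
    def coefficients(self) -> np.ndarray:
        """Leading factors sqrt(p_k m_k / (p_k + m_k)) per balance."""
        p = self.positive_counts
        m = self.negative_counts
        return np.sqrt(p * m / (p + m))

    @property
    def basis(self) -> np.ndarray:
        """(D-1, D) orthonormal basis; rows sum to zero."""
        return _basis_from_signs(self.sign_table)

    def restrict(self, keep) -> "BalancePartition":
        """Induced partition on a subset of parts.

        Keeps the rows that still contrast two nonempty groups after the
        other parts are dropped; for any 3-of-4 subset of the movement
        partition this yields a valid two-balance SBP.
        """
        keep = tuple(keep)
        try:
            idx = [list(self.labels).index(k) for k in keep]
        except ValueError as exc:
            raise PartitionError(f"unknown label in keep={keep}") from exc
        sub = self.sign_table[:, idx]
        rows = [r for r in sub if (r > 0).any() and (r < 0).any()]
        return BalancePartition(np.array(rows, dtype=int), keep)

    @classmethod
    def from_rows(cls, rows, labels=CANONICAL_PARTS) -> "BalancePartition":
        """Build from config-style rows: mappings of part label -> '+'/'-'/0."""
        table = np.zeros((len(rows), len(labels)), dtype=int)
        code = {"+": 1, "+1": 1, 1: 1, "-": -1, "-1": -1, -1: -1, 0: 0, "0": 0}
        for r, row in enumerate(rows):
            for label, sign in row.items():
                if label not in labels:
                    raise PartitionError(f"unknown part label {label!r}")
                table[r, list(labels).index(label)] = code[sign]
        return cls(table, tuple(labels))


def movement_partition() -> BalancePartition:
    """The default movement-behavior SBP on (SED, LPA, MVPA, SLEEP).

    Row 1: LPA, MVPA positive vs. SED, sleep negative (active vs. passive);
    row 2: LPA vs. MVPA; row 3: SED vs. sleep.
    """
    table = np.array(
        [
            [-1, 1, 1, -1],
            [0, 1, -1, 0],
            [1, 0, 0, -1],
        ]
    )
    return BalancePartition(table, CANONICAL_PARTS)


def ilr(x, partition: BalancePartition | None = None) -> np.ndarray:
    """Forward ilr: balance coordinates of composition row(s) ``x``.

    Invariant to the closure constant (only ratios enter), so minutes and
    proportions give identical coordinates.
    """
    part = partition or movement_partition()
    xa = np.asarray(x, dtype=float)
    if xa.shape[-1] != part.n_parts:
        raise CompositionError(
            f"composition has {xa.shape[-1]} parts, partition expects {part.n_parts}"
        )
    # basis rows sum to zero, so the clr centering cancels; clr() also
    # enforces strict positivity with a helpful error.
    return clr(xa) @ part.basis.T


def ilr_inverse(z, partition: BalancePartition | None = None, constant: float = 1.0) -> np.ndarray:
    """Inverse ilr: composition row(s) closed to ``constant``."""
    part = partition or movement_partition()
    za = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(za)):
        raise CompositionError("balance coordinates must be finite")
    if za.shape[-1] != part.n_coords:
        raise CompositionError(
            f"{za.shape[-1]} coordinates for a partition with {part.n_coords} balances"
        )
    return closure(np.exp(za @ part.basis), constant)
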