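"""Step 1 of the two-step method: counting numbers and their thresholds.

For a pair of elements observed across ``N`` samples, the *counting number*
of a candidate relationship is the number of samples whose joint on/off state
falls in the relationship's allowed cells.  Without measurement error the true
relationship counts exactly ``N``; with per-entry misclassification
probability ``eps`` the count concentrates below ``N``, and Step 1 keeps the
relationships whose count clears a lower threshold.

Threshold construction.  A sample landing in a forbidden cell of the true
relationship requires at least one misread coordinate, so the expected
forbidden mass is ``2*eps*(1-eps)`` for a similarity-type relationship (two
forbidden cells reachable by single flips from the diagonal) and
``eps*(1-eps)`` for a prerequisite-type one (a single forbidden cell).  To
allow for the uncertainty in the error level itself, ``eps`` is inflated to a
one-sided upper confidence limit before the expectation is formed: each
sample exposes two coordinates to independent misreads, so over ``N`` samples
the error level behaves like a proportion estimated from ``2N`` trials,

    eps_u = eps + z_{1-alpha} * sqrt(eps*(1-eps) / (2N)),

and the suggested threshold is the integer part of ``N * (1 - mass(eps_u))``.
At ``N = 100, eps = 0.05, alpha = 0.05`` this yields 86 (similar) and 93
(prerequisite); at ``N = 81, eps = 0.10`` it yields 61 and 71.  A relationship
passes when its counting number is **at least** the integer threshold, which
keeps the noise-free case (count = N, threshold = N) selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import KINDS, BinaryMatrix, RelationshipKind, allowed_cells

__all__ = [
    "PairTable",
    "ThresholdConfig",
    "tabulate_pair",
    "relationship_counts",
    "cells_from_counts",
    "similar_threshold",
    "prerequisite_threshold",
    "integer_threshold",
    "screen_counts",
    "perfect_count_relations",
]


@dataclass(frozen=True)
class PairTable:
    """Observed 2x2 cell counts for one ordered element pair."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self):
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("a pair table needs at least one observation")

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    def cell(self, c: tuple[int, int]) -> int:
        return {(0, 0): self.n00, (0, 1): self.n01,
                (1, 0): self.n10, (1, 1): self.n11}[c]

    def as_array(self) -> np.ndarray:
        """Counts in cell order (0,0), (0,1), (1,0), (1,1)."""
        return np.array([self.n00, self.n01, self.n10, self.n11], dtype=float)

    def swapped(self) -> "PairTable":
        """The table for the pair taken in the opposite order."""
        return PairTable(self.n00, self.n10, self.n01, self.n11)


def tabulate_pair(matrix: BinaryMatrix, a: str, b: str) -> PairTable:
    """Tally the four joint on/off cells of elements ``a`` and ``b``."""
    if a == b:
        raise ValueError(f"need two distinct elements, got {a!r} twice")
    ra, rb = matrix.row(a), matrix.row(b)
    joint = 2 * ra + rb
    counts = np.bincount(joint, minlength=4)
    return PairTable(int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3]))


def relationship_counts(table: PairTable) -> dict[RelationshipKind, int]:
    """The six counting numbers of the pair.

    Satisfies ``counts[SIM] + counts[SIM_DUAL] == N`` and the four
    prerequisite counts sum to ``3N`` (each equals ``N`` minus one cell).
    """
    return {
        kind: sum(table.cell(c) for c in allowed_cells(kind)) for kind in KINDS
    }


def cells_from_counts(counts: dict[RelationshipKind, int], n: int) -> PairTable:
    """Invert the four prerequisite counting numbers back to cell counts."""
    table = PairTable(
        n00=n - counts[RelationshipKind.F00],
        n01=n - counts[RelationshipKind.F01],
        n10=n - counts[RelationshipKind.F10],
        n11=n - counts[RelationshipKind.F11],
    )
    if table.total != n:
        raise ValueError("prerequisite counts are inconsistent with the sample size")
    if relationship_counts(table) != dict(counts):
        raise ValueError("counting numbers are mutually inconsistent")
    return table


def _epsilon_upper(n: int, epsilon: float, alpha: float) -> float:
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5), got {epsilon}")
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    if epsilon == 0.0:
        return 0.0
    z = norm.ppf(1.0 - alpha)
    eps_u = epsilon + z * math.sqrt(epsilon * (1.0 - epsilon) / (2.0 * n))
    return min(eps_u, 0.5)


def similar_threshold(n: int, epsilon: float, alpha: float = 0.05) -> float:
    """Lower bound for the counting number of a true similarity relationship."""
    eps_u = _epsilon_upper(n, epsilon, alpha)
    return n * (1.0 - 2.0 * eps_u * (1.0 - eps_u))


def prerequisite_threshold(n: int, epsilon: float, alpha: float = 0.05) -> float:
    """Lower bound for the counting number of a true prerequisite relationship."""
    eps_u = _epsilon_upper(n, epsilon, alpha)
    return n * (1.0 - eps_u * (1.0 - eps_u))


def integer_threshold(bound: float) -> int:
    """Integer screening threshold: the integer part of the real bound."""
    return math.floor(bound + 1e-9)


@dataclass
class ThresholdConfig:
    """Settings for the two screening steps."""

    epsilon: float
    alpha: float = 0.05
    pvalue_threshold: float = 1.0
    pvalue_decimals: int = 4
    t_sim: int | None = None
    t_pre: int | None = None

    def resolve(self, n: int) -> "ThresholdConfig":
        """Fill in the integer count thresholds for sample size ``n``."""
        t_sim = self.t_sim if self.t_sim is not None else integer_threshold(
            similar_threshold(n, self.epsilon, self.alpha))
        t_pre = self.t_pre if self.t_pre is not None else integer_threshold(
            prerequisite_threshold(n, self.epsilon, self.alpha))
        return ThresholdConfig(self.epsilon, self.alpha, self.pvalue_threshold,
                               self.pvalue_decimals, t_sim, t_pre)


def screen_counts(
    counts: dict[RelationshipKind, int], config: ThresholdConfig, n: int
) -> set[RelationshipKind]:
    """Kinds whose counting number reaches the relevant threshold."""
    cfg = config.resolve(n)
    out = set()
    for kind, c in counts.items():
        t = cfg.t_sim if kind.is_similarity else cfg.t_pre
        if c >= t:
            out.add(kind)
    return out


def perfect_count_relations(matrix: BinaryMatrix, subsume: bool = True):
    """(pair, kind) combinations whose counting number equals the sample size.

    On noise-free data these are exactly the relationships the sample can
    support.  With ``subsume`` (the default) a perfect similarity absorbs the
    two single-cell prerequisite patterns it logically implies (and a perfect
    dual similarity likewise), so each discovered fact is reported once.
    """
    from .model import PairRelation  # local import to avoid cycle at import time

    n = matrix.n_samples
    out: list[PairRelation] = []
    ids = matrix.element_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            counts = relationship_counts(tabulate_pair(matrix, a, b))
            kinds = {k for k, c in counts.items() if c == n}
            if subsume:
                if RelationshipKind.SIM in kinds:
                    kinds -= {RelationshipKind.F01, RelationshipKind.F10}
                if RelationshipKind.SIM_DUAL in kinds:
                    kinds -= {RelationshipKind.F00, RelationshipKind.F11}
            out.extend(PairRelation(a, b, k) for k in sorted(kinds, key=lambda k: k.value))
    return out
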