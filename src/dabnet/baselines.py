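"""The two comparison methods: Boolean-implication statistics and the
constrained misclassification-rate criterion.

Boolean implications.  An implication between two genes predicts one sparse
quadrant of their 2x2 table.  The sparseness statistic is

    (expected - observed) / sqrt(expected),   expected = row * column / N,

and the error-rate statistic is the sparse count averaged over its two
margins.  An implication is called when the sparseness statistic exceeds 3
and the error rate stays below 0.1; a similarity is called when both
off-diagonal quadrants qualify, a dual similarity when both diagonal
quadrants do.

Constrained error rate.  Alternatively, each candidate relationship can be
scored by the smallest misclassification probability that explains the
observed table when the relationship's forbidden cells carry no true mass;
true relationships should admit a small rate.  This criterion has no
canonical cutoff; ``lilu_screen`` exposes it as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .counting import PairTable, tabulate_pair
from .inference import flip_kernel
from .model import KINDS, BinaryMatrix, PairRelation, RelationshipKind, allowed_cells

__all__ = [
    "SahooResult",
    "sahoo_statistics",
    "sahoo_screen",
    "lilu_relation_epsilon",
    "lilu_screen",
]

_CELL_INDEX = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


@dataclass(frozen=True)
class SahooResult:
    """Implication test for one sparse quadrant."""

    direction: tuple[int, int]        # the predicted-sparse cell
    sparseness: float
    error_rate: float
    called: bool
    degenerate: bool = False


def sahoo_statistics(
    table: PairTable, direction: tuple[int, int],
    s_min: float = 3.0, err_max: float = 0.1,
) -> SahooResult:
    """Sparseness and error-rate statistics for one quadrant."""
    a, b = direction
    n = table.total
    obs = table.cell(direction)
    row = table.cell((a, 0)) + table.cell((a, 1))
    col = table.cell((0, b)) + table.cell((1, b))
    if row == 0 or col == 0:
        return SahooResult(direction, math.nan, math.nan, called=False,
                           degenerate=True)
    expected = row * col / n
    sparseness = (expected - obs) / math.sqrt(expected)
    error_rate = 0.5 * (obs / row + obs / col)
    called = sparseness > s_min and error_rate < err_max
    return SahooResult(direction, sparseness, error_rate, called)


def sahoo_screen(
    matrix: BinaryMatrix, s_min: float = 3.0, err_max: float = 0.1
) -> set[PairRelation]:
    """All implication calls over all pairs, merged into relationships.

    A sparse cell (a, b) supports the relationship forbidding that cell;
    both off-diagonal cells sparse merge into a similarity call, both
    diagonal cells into a dual-similarity call.
    """
    kind_of = {(0, 1): RelationshipKind.F01, (1, 0): RelationshipKind.F10,
               (0, 0): RelationshipKind.F00, (1, 1): RelationshipKind.F11}
    out: set[PairRelation] = set()
    ids = matrix.element_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            table = tabulate_pair(matrix, a, b)
            called = {d for d in kind_of
                      if sahoo_statistics(table, d, s_min, err_max).called}
            kinds = {kind_of[d] for d in called}
            if {RelationshipKind.F01, RelationshipKind.F10} <= kinds:
                kinds -= {RelationshipKind.F01, RelationshipKind.F10}
                kinds.add(RelationshipKind.SIM)
            if {RelationshipKind.F00, RelationshipKind.F11} <= kinds:
                kinds -= {RelationshipKind.F00, RelationshipKind.F11}
                kinds.add(RelationshipKind.SIM_DUAL)
            out.update(PairRelation(a, b, k) for k in kinds)
    return out


def _constrained_loglik(counts: np.ndarray, epsilon: float,
                        allowed: list[int]) -> float:
    """Profile log-likelihood at ``epsilon`` with true mass confined to
    the allowed cells (EM over the restricted simplex)."""
    n = counts.sum()
    k = flip_kernel(epsilon)
    p = np.zeros(4)
    p[allowed] = 1.0 / len(allowed)
    for _ in range(2000):
        q = np.maximum(k @ p, 1e-300)
        p_new = p * (k.T @ (counts / q))
        p_new[[i for i in range(4) if i not in allowed]] = 0.0
        s = p_new.sum()
        if s <= 0:
            return -math.inf
        p_new /= s
        if np.max(np.abs(p_new - p)) < 1e-13:
            p = p_new
            break
        p = p_new
    q = np.maximum(k @ p, 1e-300)
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(q[mask])))


def lilu_relation_epsilon(table: PairTable, kind: RelationshipKind) -> float:
    """Smallest-error MLE of the flip rate under the relationship constraint.

    Maximises the multinomial likelihood over the flip rate and a true
    distribution supported on the relationship's allowed cells; returns the
    maximising rate in [0, 0.5).
    """
    counts = table.as_array()
    allowed = sorted(_CELL_INDEX[c] for c in allowed_cells(kind))
    forbidden = [i for i in range(4) if i not in allowed]
    if counts[forbidden].sum() == 0:
        return 0.0  # perfect fit needs no error
    res = minimize_scalar(
        lambda e: -_constrained_loglik(counts, e, allowed),
        bounds=(1e-6, 0.5 - 1e-6), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def lilu_screen(
    matrix: BinaryMatrix, eps_cutoff: float = 0.05
) -> set[PairRelation]:
    """Relationships whose constrained flip-rate estimate stays below the cutoff.

    For each pair every kind with a constrained estimate below ``eps_cutoff``
    is called; a similarity call absorbs its two implied one-cell patterns.
    """
    out: set[PairRelation] = set()
    ids = matrix.element_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            table = tabulate_pair(matrix, a, b)
            eps = {k: lilu_relation_epsilon(table, k) for k in KINDS}
            kinds = {k for k, e in eps.items() if e < eps_cutoff}
            if RelationshipKind.SIM in kinds:
                kinds -= {RelationshipKind.F01, RelationshipKind.F10}
            if RelationshipKind.SIM_DUAL in kinds:
                kinds -= {RelationshipKind.F00, RelationshipKind.F11}
            out.update(PairRelation(a, b, k) for k in kinds)
    return out
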