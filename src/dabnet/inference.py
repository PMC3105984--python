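"""Step 2 machinery: the misclassification model and asymptotic p-values.

Noise model.  Each observed on/off entry is the true entry flipped
independently with probability ``eps < 1/2``.  For a pair of elements the
observed cell distribution is ``q = K(eps) p`` where ``p`` is the true cell
distribution and ``K(eps)`` the Kronecker square of the single-coordinate
flip kernel ``[[1-eps, eps], [eps, 1-eps]]``.  ``K`` is invertible for
``eps != 1/2``, which gives closed-form misclassification-corrected cell
estimates from the observed frequencies; the raw algebraic inverse may leave
the probability simplex, so a clipped-and-renormalised copy is carried
alongside and flagged.

Hypothesis tests.  Each of the six relationships asserts that its forbidden
cells carry no true probability mass.  The package's test statistics are
expressed directly in the observed counts; the misclassification correction
rescales both the plug-in estimate and its reference scale by the same power
of ``1/(1-2*eps)``, so ``eps`` cancels from the standardised statistic (it
still governs Step 1 and the error-rate estimators):

* similarity (forbids the off-diagonal): ``z = sqrt(N) * [ (q01+q10)^2 -
  4*q00*q11 ]`` with ``q`` the observed cell frequencies.  The bracket is
  ``(p01-p10)^2 - 4*cov(a,b)`` — negative whenever diagonal association
  dominates, as a true similarity forces, and positive when it does not.
* dual similarity: the mirror form ``(q00+q11)^2 - 4*q01*q10``.
* single-forbidden-cell kinds: the forbidden cell's standardised residual
  against its margin-product expectation, ``z = (n_c - E_c) /
  sqrt(E_c (1 - E_c/N))`` with ``E_c = row*column/N`` — an excess over what
  chance co-occurrence explains is evidence against that relationship.

All six are referred to the standard normal, folded and clipped:
``p = min(1, 2*(1 - Phi(z)))``.  A deficit (z <= 0) therefore yields p = 1,
the value the selection rule of Step 3 demands of a true relationship.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


from .counting import PairTable
from .model import RelationshipKind

__all__ = [
    "NoiseModel",
    "CellProbEstimate",
    "EpsilonEstimate",
    "flip_kernel",
    "observed_cell_probs",
    "estimate_true_probs",
    "relationship_zstat",
    "asymptotic_pvalue",
    "estimate_epsilon",
    "pooled_epsilon",
]

_CELL_INDEX = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


@dataclass(frozen=True)
class NoiseModel:
    """Independent per-entry misclassification with probability ``epsilon``."""

    epsilon: float

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must lie in [0, 0.5), got {self.epsilon}")


@dataclass
class CellProbEstimate:
    """Corrected cell probabilities: raw algebraic inverse plus a clipped copy."""

    raw: np.ndarray        # order (0,0), (0,1), (1,0), (1,1); sums to 1
    clipped: np.ndarray    # raw with negatives set to 0, renormalised
    was_clipped: bool

    @property
    def p00(self) -> float: return float(self.raw[0])
    @property
    def p01(self) -> float: return float(self.raw[1])
    @property
    def p10(self) -> float: return float(self.raw[2])
    @property
    def p11(self) -> float: return float(self.raw[3])


def flip_kernel(epsilon: float) -> np.ndarray:
    """4x4 map from true to observed cell probabilities."""
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5], got {epsilon}")
    f = np.array([[1 - epsilon, epsilon], [epsilon, 1 - epsilon]])
    return np.kron(f, f)


def observed_cell_probs(true_probs, epsilon: float) -> np.ndarray:
    """Push a true cell distribution through the misclassification kernel."""
    p = np.asarray(true_probs, dtype=float)
    if p.shape != (4,):
        raise ValueError("true_probs must have four entries")
    if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("true_probs must be a probability vector")
    return flip_kernel(epsilon) @ p


def estimate_true_probs(table: PairTable, epsilon: float) -> CellProbEstimate:
    """Misclassification-corrected cell probabilities (exact kernel inverse)."""
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("the flip kernel is singular at epsilon = 0.5")
    q = table.as_array() / table.total
    raw = np.linalg.solve(flip_kernel(epsilon), q)
    clipped = np.clip(raw, 0.0, None)
    was_clipped = bool((raw < 0).any())
    s = clipped.sum()
    clipped = clipped / s if s > 0 else np.full(4, 0.25)
    return CellProbEstimate(raw=raw, clipped=clipped, was_clipped=was_clipped)


# ---------------------------------------------------------------------------
# asymptotic p-values
# ---------------------------------------------------------------------------

def relationship_zstat(kind: RelationshipKind, table: PairTable) -> float:
    """The standardised statistic whose upper tail scores the relationship."""
    n = table.total
    q = table.as_array() / n
    q00, q01, q10, q11 = q
    if kind is RelationshipKind.SIM:
        return math.sqrt(n) * ((q01 + q10) ** 2 - 4.0 * q00 * q11)
    if kind is RelationshipKind.SIM_DUAL:
        return math.sqrt(n) * ((q00 + q11) ** 2 - 4.0 * q01 * q10)
    (ca, cb), = kind.forbidden_cells
    row = q[2 * ca] + q[2 * ca + 1]
    col = q[cb] + q[cb + 2]
    e = row * col
    obs = q[_CELL_INDEX[(ca, cb)]]
    var = e * (1.0 - e) / n
    if var <= 0.0:
        # degenerate margin: the forbidden cell is structurally fixed
        return 0.0 if obs == e else math.inf * math.copysign(1.0, obs - e)
    return (obs - e) / math.sqrt(var)


def asymptotic_pvalue(
    kind: RelationshipKind, table: PairTable, epsilon: float = 0.0
) -> float:
    """Folded, clipped asymptotic p-value for the relationship's hypothesis.

    Large values (p = 1 after rounding) support the relationship; the
    selection rule of Step 3 keeps relationships whose rounded p-value
    reaches the threshold (default exactly 1).  ``epsilon`` is validated for
    interface symmetry with Step 1 but cancels from the standardised
    statistic (see module docstring).
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5), got {epsilon}")
    z = relationship_zstat(kind, table)
    if math.isinf(z):
        return 0.0 if z > 0 else 1.0
    # 2*(1 - Phi(z)) == erfc(z / sqrt(2))
    return float(min(1.0, math.erfc(z / math.sqrt(2.0))))


# ---------------------------------------------------------------------------
# misclassification-rate estimation
# ---------------------------------------------------------------------------

@dataclass
class EpsilonEstimate:
    epsilon_hat: float
    loglik: float
    probs_hat: CellProbEstimate
    converged: bool
    message: str = ""


def _multinomial_loglik(counts: np.ndarray, q: np.ndarray) -> float:
    mask = counts > 0
    if (q[mask] <= 0).any():
        return -math.inf
    return float(np.sum(counts[mask] * np.log(q[mask])))


def estimate_epsilon(table: PairTable, tol: float = 1e-7) -> EpsilonEstimate:
    """Maximum-likelihood misclassification rate for one pair (unconstrained).

    With four observed cells and an unconstrained true distribution the model
    is saturated: every ``eps`` whose deconvolved table remains a valid
    probability vector attains the same (maximal) likelihood, so the
    likelihood is flat on an interval ``[0, eps_max]`` and decreases beyond
    it.  ``eps`` is identified only through the impossibility of negative
    true-cell mass; the estimator returned is the upper endpoint ``eps_max``
    (found by bisection), which recovers the generating rate when the true
    distribution has empty cells — the situation a DAB relationship creates.
    For tables with all deconvolved cells interior up to ``eps -> 0.5`` the
    estimate sits at the boundary and is flagged.
    """
    counts = table.as_array()

    def feasible(eps: float) -> bool:
        raw = np.linalg.solve(flip_kernel(eps), counts / counts.sum())
        return bool((raw >= -1e-12).all())

    hi = 0.5 - 1e-9
    if feasible(hi):
        est = estimate_true_probs(table, hi)
        warnings.warn("epsilon is not identified for this table; boundary estimate 0.5")
        return EpsilonEstimate(0.5, _multinomial_loglik(counts, counts / counts.sum()),
                               est, converged=False,
                               message="flat likelihood up to the boundary")
    lo = 0.0
    if not feasible(lo):  # cannot happen: eps=0 inverse is the table itself
        raise AssertionError("zero-noise deconvolution infeasible")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    eps_hat = lo
    est = estimate_true_probs(table, eps_hat)
    ll = _multinomial_loglik(counts, counts / counts.sum())
    return EpsilonEstimate(eps_hat, ll, est, converged=True)


def profile_loglik(table: PairTable, epsilon: float) -> float:
    """Log-likelihood at ``epsilon`` with the true cells profiled out.

    Inside the feasible region the saturated fit is attainable; outside it
    the best true distribution sits on the simplex boundary and is found
    numerically.
    """
    counts = table.as_array()
    n = counts.sum()
    k = flip_kernel(epsilon)
    raw = np.linalg.solve(k, counts / n)
    if (raw >= -1e-12).all():
        return _multinomial_loglik(counts, counts / n)
    # boundary fit: maximise over the simplex via an EM fixed point
    p = np.full(4, 0.25)
    for _ in range(500):
        p_new = p * (k.T @ (counts / np.maximum(k @ p, 1e-300)))
        p_new /= p_new.sum()
        if np.max(np.abs(p_new - p)) < 1e-12:
            p = p_new
            break
        p = p_new
    return _multinomial_loglik(counts, k @ p)


def pooled_epsilon(tables: list[PairTable], grid: int = 199) -> EpsilonEstimate:
    """Misclassification rate maximising the summed profile likelihood.

    Pooling across pairs breaks the per-pair flatness as soon as any pair
    constrains ``eps`` from above; evaluated on a grid over ``[0, 0.5)`` and
    refined around the best point.
    """
    eps_grid = np.linspace(0.0, 0.49, grid)
    total = np.zeros_like(eps_grid)
    for t in tables:
        total += np.array([profile_loglik(t, e) for e in eps_grid])
    # upper endpoint of the maximal ridge (the likelihood may be flat below)
    i = int(np.where(total >= total.max() - 1e-7)[0][-1])
    lo = eps_grid[max(i - 1, 0)]
    hi = eps_grid[min(i + 1, grid - 1)]
    fine = np.linspace(lo, hi, 41)
    total_f = np.zeros_like(fine)
    for t in tables:
        total_f += np.array([profile_loglik(t, e) for e in fine])
    j = int(np.where(total_f >= total_f.max() - 1e-7)[0][-1])
    eps_hat = float(fine[j])
    ref = tables[0]
    return EpsilonEstimate(eps_hat, float(total_f[j]),
                           estimate_true_probs(ref, min(eps_hat, 0.5 - 1e-9)),
                           converged=True)
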