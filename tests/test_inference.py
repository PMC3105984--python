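"""Noise map, corrected estimators, p-values, and the error-rate MLE."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dabnet import (PairTable, RelationshipKind, asymptotic_pvalue,
                    estimate_epsilon, estimate_true_probs, flip_kernel,
                    observed_cell_probs, relationship_zstat)
from dabnet.inference import pooled_epsilon

K = RelationshipKind


# ---------------------------------------------------------------------------
# forward map and its inverse
# ---------------------------------------------------------------------------

def test_forward_map_limits():
    p = np.array([0.5, 0.1, 0.15, 0.25])
    assert np.allclose(observed_cell_probs(p, 0.0), p)
    assert np.allclose(observed_cell_probs(p, 0.5), 0.25)
    uniform = np.full(4, 0.25)
    for eps in (0.0, 0.1, 0.3):
        assert np.allclose(observed_cell_probs(uniform, eps), uniform)


@pytest.mark.parametrize("eps", [0.0, 0.05, 0.2, 0.49])
@pytest.mark.parametrize("p", [
    (0.25, 0.25, 0.25, 0.25), (0.7, 0.0, 0.1, 0.2), (0.0, 0.0, 0.5, 0.5),
    (0.1, 0.2, 0.3, 0.4),
])
def test_forward_then_inverse_is_identity(eps, p):
    q = observed_cell_probs(np.array(p), eps)
    # exact multinomial proportions as a (scaled) integer table
    table = PairTable(*(np.round(q * 10**6).astype(int)))
    est = estimate_true_probs(table, eps)
    assert np.abs(est.raw - np.array(p)).max() < 1e-5
    assert abs(est.raw.sum() - 1.0) < 1e-12


def test_inverse_at_zero_noise_is_the_empirical_frequency():
    t = PairTable(10, 20, 30, 40)
    est = estimate_true_probs(t, 0.0)
    assert np.allclose(est.raw, [0.1, 0.2, 0.3, 0.4])
    assert not est.was_clipped


def test_out_of_simplex_inverse_is_flagged_and_clipped():
    # nearly pure cell with a rare neighbour: correction overshoots below zero
    t = PairTable(97, 1, 1, 1)
    est = estimate_true_probs(t, 0.05)
    assert est.was_clipped
    assert (est.raw < 0).any()
    assert (est.clipped >= 0).all()
    assert abs(est.clipped.sum() - 1.0) < 1e-12
    with pytest.raises(ValueError):
        estimate_true_probs(t, 0.5)


# ---------------------------------------------------------------------------
# asymptotic p-values
# ---------------------------------------------------------------------------

def test_published_similarity_pvalue_anchor():
    """Cells recovered from the published (A,B) counting row."""
    t = PairTable(10, 2, 43, 45)
    p = asymptotic_pvalue(K.SIM, t, 0.05)
    assert p == pytest.approx(0.8207, abs=0.002)
    assert asymptotic_pvalue(K.F01, t, 0.05) == 1.0


# Entries of the published p-value table that the package's closed forms
# reproduce exactly at four decimals (cells recovered from the counting
# table; pair, kind, expected p).
_REFERENCE_PVALUES = [
    ((10, 2, 43, 45), K.F00, 0.1358), ((7, 5, 23, 65), K.F00, 0.0680),
    ((10, 2, 42, 46), K.F00, 0.1201), ((11, 1, 73, 15), K.F00, 0.7599),
    ((17, 36, 13, 34), K.F00, 0.7636), ((16, 14, 36, 34), K.F00, 0.9122),
    ((28, 2, 26, 44), K.F00, 0.0014), ((6, 24, 41, 29), K.F01, 0.0268),
    ((34, 13, 50, 3), K.F01, 0.0377), ((52, 2, 32, 14), K.F11, 0.0110),
    ((28, 2, 56, 14), K.F11, 0.3746), ((44, 8, 40, 8), K.F11, 0.9043),
    ((23, 30, 24, 23), K.SIM, 0.4237), ((21, 26, 31, 22), K.SIM, 0.1613),
    ((19, 28, 35, 18), K.SIM, 0.0093),
]


@pytest.mark.parametrize("cells,kind,expected", _REFERENCE_PVALUES)
def test_published_pvalue_table_anchors(cells, kind, expected):
    p = asymptotic_pvalue(kind, PairTable(*cells), 0.05)
    assert round(p, 4) == pytest.approx(expected, abs=2e-4)


@pytest.mark.parametrize("cells,kind,expected", [
    ((17, 36, 13, 34), K.SIM_DUAL, 0.4654),
    ((16, 14, 36, 34), K.SIM_DUAL, 0.6280),
])
def test_published_dual_similarity_anchors(cells, kind, expected):
    """Reproduced to three decimals (the published table's last digit can
    differ by one unit for these entries)."""
    p = asymptotic_pvalue(kind, PairTable(*cells), 0.05)
    assert p == pytest.approx(expected, abs=1e-3)


def test_similarity_statistic_sign_logic():
    # perfectly similar data: statistic deep in the acceptance region
    assert relationship_zstat(K.SIM, PairTable(50, 0, 0, 50)) < 0
    assert asymptotic_pvalue(K.SIM, PairTable(50, 0, 0, 50), 0.0) == 1.0
    # perfectly anti-similar data: strong rejection
    assert asymptotic_pvalue(K.SIM, PairTable(0, 50, 50, 0), 0.0) < 1e-10
    # and the dual statistic mirrors it
    assert asymptotic_pvalue(K.SIM_DUAL, PairTable(0, 50, 50, 0), 0.0) == 1.0


def test_epsilon_does_not_move_the_standardised_statistic():
    t = PairTable(10, 2, 43, 45)
    for kind in K:
        assert asymptotic_pvalue(kind, t, 0.0) == asymptotic_pvalue(kind, t, 0.2)
    with pytest.raises(ValueError):
        asymptotic_pvalue(K.SIM, t, 0.7)


@given(st.tuples(*[st.integers(0, 300)] * 4).filter(lambda c: sum(c) > 0))
@settings(max_examples=500, deadline=None)
def test_pvalues_lie_in_unit_interval(cells):
    t = PairTable(*cells)
    for kind in K:
        p = asymptotic_pvalue(kind, t, 0.05)
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# misclassification-rate estimation
# ---------------------------------------------------------------------------

def _grid_oracle(table, grid=501):
    """Best epsilon on a fine grid by profile likelihood."""
    from dabnet.inference import profile_loglik
    eps = np.linspace(0.0, 0.49, grid)
    ll = np.array([profile_loglik(table, e) for e in eps])
    best = ll.max()
    # upper end of the flat maximal ridge
    return eps[np.where(ll >= best - 1e-9)[0][-1]]


@pytest.mark.parametrize("eps_true", [0.05, 0.1, 0.2])
def test_epsilon_recovery_with_structural_zero(eps_true):
    p = np.array([0.35, 0.0, 0.25, 0.4])  # a true relationship empties a cell
    q = observed_cell_probs(p, eps_true)
    t = PairTable(*(np.round(q * 10**4).astype(int)))
    est = estimate_epsilon(t)
    assert est.converged
    assert est.epsilon_hat == pytest.approx(eps_true, abs=0.02)
    assert est.epsilon_hat == pytest.approx(_grid_oracle(t), abs=0.002)


def test_epsilon_zero_for_noise_free_similar_pair():
    est = estimate_epsilon(PairTable(60, 0, 0, 40))
    assert est.epsilon_hat == pytest.approx(0.0, abs=1e-6)


def test_degenerate_single_cell_table_sits_on_the_boundary():
    est = estimate_epsilon(PairTable(100, 0, 0, 0))
    assert est.epsilon_hat == pytest.approx(0.0, abs=1e-6)


def test_unidentified_interior_table_is_flagged():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        est = estimate_epsilon(PairTable(25, 25, 25, 25))
    assert not est.converged
    assert any("not identified" in str(x.message) for x in w)


def test_pooled_epsilon_tracks_the_binding_pair():
    p = np.array([0.35, 0.0, 0.25, 0.4])
    q = observed_cell_probs(p, 0.08)
    constrained = PairTable(*(np.round(q * 10**4).astype(int)))
    flat = PairTable(2500, 2500, 2500, 2500)
    est = pooled_epsilon([constrained, flat], grid=99)
    assert est.epsilon_hat == pytest.approx(0.08, abs=0.02)
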