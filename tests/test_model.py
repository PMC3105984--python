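"""Relationship semantics, state enumeration, closure and covering pairs."""

import itertools

import pytest

from dabnet import (PairRelation, RelationshipKind, allowed_cells, closure,
                    covering_edges, enumerate_compatible_states,
                    holds_in_state, is_compatible, random_dab_network,
                    similarity_classes)

K = RelationshipKind
CELLS = [(0, 0), (0, 1), (1, 0), (1, 1)]


@pytest.mark.parametrize("kind,expected", [
    (K.SIM, {(0, 0), (1, 1)}),
    (K.SIM_DUAL, {(0, 1), (1, 0)}),
    (K.F01, {(0, 0), (1, 0), (1, 1)}),
    (K.F10, {(0, 0), (0, 1), (1, 1)}),
    (K.F00, {(0, 1), (1, 0), (1, 1)}),
    (K.F11, {(0, 0), (0, 1), (1, 0)}),
])
def test_allowed_cells(kind, expected):
    assert allowed_cells(kind) == frozenset(expected)
    assert len(allowed_cells(kind)) + len(kind.forbidden_cells) == 4


def test_holds_in_state_matches_allowed_cells():
    for kind in K:
        for cell in CELLS:
            assert holds_in_state(kind, *cell) == (cell in allowed_cells(kind))
    with pytest.raises(ValueError):
        holds_in_state(K.SIM, 2, 0)


def test_pair_relation_canonicalization():
    assert PairRelation("B", "A", K.F01) == PairRelation("A", "B", K.F10)
    assert PairRelation("B", "A", K.SIM) == PairRelation("A", "B", K.SIM)
    with pytest.raises(ValueError):
        PairRelation("A", "A", K.SIM)


def test_worked_example_states_are_exactly_the_compatible_ones(worked_states):
    relations, states = worked_states
    enumerated = enumerate_compatible_states(list("ABCDEFG"), relations)
    assert set(enumerated) == set(states)
    assert len(enumerated) == 13


def test_compatibility_edge_cases():
    rel = PairRelation("A", "B", K.F00)
    assert not is_compatible((0, 0), [rel], ["A", "B"])
    assert is_compatible((0, 0), [], ["A", "B"])
    with pytest.raises(KeyError):
        is_compatible((0, 0), [PairRelation("A", "X", K.SIM)], ["A", "B"])


def test_contradictory_relations_have_empty_state_space():
    rels = [PairRelation("a", "b", K.SIM), PairRelation("a", "b", K.SIM_DUAL)]
    assert enumerate_compatible_states(["a", "b"], rels) == []


def _oracle_states(elements, relations):
    """Literal per-state, per-relation double loop."""
    out = []
    for state in itertools.product((0, 1), repeat=len(elements)):
        ok = True
        for r in relations:
            va = state[elements.index(r.a)]
            vb = state[elements.index(r.b)]
            if (va, vb) in r.kind.forbidden_cells:
                ok = False
                break
        if ok:
            out.append(state)
    return out


@pytest.mark.parametrize("seed", range(8))
def test_enumeration_matches_oracle_on_random_networks(seed):
    rels = random_dab_network(6, density=0.4, seed=seed)
    elements = sorted({e for r in rels for e in (r.a, r.b)})
    assert enumerate_compatible_states(elements, rels) == \
        _oracle_states(elements, rels)


def test_closure_transitivity_and_substitution():
    c = closure({PairRelation("A", "B", K.F01), PairRelation("B", "C", K.F01)})
    assert PairRelation("A", "C", K.F01) in c
    c = closure({PairRelation("A", "B", K.SIM), PairRelation("B", "C", K.F01)})
    assert PairRelation("A", "C", K.F01) in c


@pytest.mark.parametrize("seed", range(10))
def test_closure_preserves_state_space_and_is_idempotent(seed):
    rels = random_dab_network(6, density=0.5, seed=seed)
    elements = sorted({e for r in rels for e in (r.a, r.b)})
    closed = closure(rels)
    assert closure(closed) == closed
    assert enumerate_compatible_states(elements, rels) == \
        enumerate_compatible_states(elements, closed)


def test_closure_entails_only_relations_valid_in_all_states():
    rels = {PairRelation("A", "B", K.SIM), PairRelation("B", "C", K.F01)}
    elements = ["A", "B", "C"]
    states = enumerate_compatible_states(elements, rels)
    for r in closure(rels):
        assert all(
            (s[elements.index(r.a)], s[elements.index(r.b)])
            not in r.kind.forbidden_cells
            for s in states
        )


@pytest.mark.parametrize("seed", range(30))
def test_covering_edges_regenerate_the_closure(seed):
    rels = random_dab_network(7, density=0.5, seed=seed, sim_prob=0.25)
    closed = closure(rels)
    cover = covering_edges(rels)
    sims = {r for r in closed if r.kind is K.SIM}
    assert cover <= closed
    assert closure(cover | sims) == closed


def test_covering_of_a_chain_drops_the_transitive_edge():
    rels = {PairRelation("A", "B", K.F01), PairRelation("B", "C", K.F01),
            PairRelation("A", "C", K.F01)}
    assert covering_edges(rels) == {PairRelation("A", "B", K.F01),
                                    PairRelation("B", "C", K.F01)}
    assert covering_edges(set()) == set()


def test_similarity_classes_are_transitive(worked_states):
    relations, _ = worked_states
    classes = similarity_classes(list("ABCDEFG"), relations)
    assert frozenset({"B", "E"}) in classes
    assert sum(len(c) for c in classes) == 7
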