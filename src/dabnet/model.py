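"""Semantics of pairwise Boolean relationships and of the networks they define.

A directed acyclic Boolean (DAB) network constrains the joint on/off states of
its elements through two families of pairwise relationships:

* similarity — two elements are on and off together (``SIM``), or one is on
  exactly when the other is off (``SIM_DUAL``);
* prerequisite — the on-state of one element is necessary for the on-state of
  another.  With dual (complemented) elements there are four variants, each
  forbidding exactly one of the four joint states of the pair.

Every relationship is therefore characterised by the subset of the four cells
``(a, b) in {0,1}^2`` it forbids, and a network is uniquely determined by its
compatible state space: the set of global on/off assignments violating no
pairwise relationship.

Internally the module works on a *signed-literal implication graph*: each
relationship between elements ``a`` and ``b`` is an implication between the
literals ``a``, ``not a``, ``b``, ``not b`` (for example "a prerequisite of b"
is ``b => a``, equivalently ``not a => not b``).  Transitive closure and
covering-pair (transitive) reduction are graph operations on that structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "RelationshipKind",
    "PairRelation",
    "BinaryMatrix",
    "NetworkModel",
    "allowed_cells",
    "holds_in_state",
    "is_compatible",
    "enumerate_compatible_states",
    "closure",
    "covering_edges",
    "similarity_classes",
]

_CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))


class RelationshipKind(Enum):
    """The six pairwise relationships, identified by their forbidden cells."""

    SIM = "SIM"            # a and b coincide: forbids (0,1) and (1,0)
    SIM_DUAL = "SIM_DUAL"  # a is the complement of b: forbids (0,0) and (1,1)
    F01 = "F01"            # a prerequisite of b: forbids (0,1)
    F10 = "F10"            # b prerequisite of a: forbids (1,0)
    F00 = "F00"            # a off forces b on: forbids (0,0)
    F11 = "F11"            # a and b never both on: forbids (1,1)

    @property
    def forbidden_cells(self) -> frozenset[tuple[int, int]]:
        return _FORBIDDEN[self]

    @property
    def is_similarity(self) -> bool:
        """True for the two-forbidden-cell (similarity-type) kinds."""
        return self in (RelationshipKind.SIM, RelationshipKind.SIM_DUAL)

    def swapped(self) -> "RelationshipKind":
        """The same relationship with the two elements interchanged."""
        return _SWAP[self]


_FORBIDDEN = {
    RelationshipKind.SIM: frozenset({(0, 1), (1, 0)}),
    RelationshipKind.SIM_DUAL: frozenset({(0, 0), (1, 1)}),
    RelationshipKind.F01: frozenset({(0, 1)}),
    RelationshipKind.F10: frozenset({(1, 0)}),
    RelationshipKind.F00: frozenset({(0, 0)}),
    RelationshipKind.F11: frozenset({(1, 1)}),
}

_SWAP = {
    RelationshipKind.SIM: RelationshipKind.SIM,
    RelationshipKind.SIM_DUAL: RelationshipKind.SIM_DUAL,
    RelationshipKind.F01: RelationshipKind.F10,
    RelationshipKind.F10: RelationshipKind.F01,
    RelationshipKind.F00: RelationshipKind.F00,
    RelationshipKind.F11: RelationshipKind.F11,
}

KINDS = (
    RelationshipKind.SIM,
    RelationshipKind.SIM_DUAL,
    RelationshipKind.F01,
    RelationshipKind.F10,
    RelationshipKind.F00,
    RelationshipKind.F11,
)


def allowed_cells(kind: RelationshipKind) -> frozenset[tuple[int, int]]:
    """Cells of the 2x2 pair table that the relationship permits."""
    if not isinstance(kind, RelationshipKind):
        raise TypeError(f"unknown relationship kind: {kind!r}")
    return frozenset(c for c in _CELLS if c not in kind.forbidden_cells)


def holds_in_state(kind: RelationshipKind, a_val: int, b_val: int) -> bool:
    """Whether the joint observation ``(a_val, b_val)`` is permitted."""
    if a_val not in (0, 1) or b_val not in (0, 1):
        raise ValueError(f"state values must be bits, got ({a_val!r}, {b_val!r})")
    return (a_val, b_val) not in kind.forbidden_cells


@dataclass(frozen=True, order=True)
class PairRelation:
    """A relationship between two named elements, stored canonically.

    ``(a, b, F01)`` states the same fact as ``(b, a, F10)``; the constructor
    normalises to the lexicographically smaller element first so each fact has
    a single representation.
    """

    a: str
    b: str
    kind: RelationshipKind

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"a relation needs two distinct elements, got {self.a!r} twice")
        if self.b < self.a:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)
            object.__setattr__(self, "kind", self.kind.swapped())

    def holds(self, a_val: int, b_val: int) -> bool:
        return holds_in_state(self.kind, a_val, b_val)


@dataclass
class BinaryMatrix:
    """An element-by-sample matrix of on/off (1/0) observations."""

    element_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        m, n = self.values.shape
        if len(self.element_ids) != m or len(self.sample_ids) != n:
            raise ValueError("label lengths do not match the value grid")
        if m < 2:
            raise ValueError("a binary matrix needs at least two elements")
        if len(set(self.element_ids)) != m or len(set(self.sample_ids)) != n:
            raise ValueError("element and sample labels must be unique")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary entry {self.values[i, j]} at element "
                f"{self.element_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_elements(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, element: str) -> np.ndarray:
        try:
            return self.values[self.element_ids.index(element)]
        except ValueError:
            raise KeyError(f"unknown element {element!r}") from None


@dataclass
class NetworkModel:
    """Relations called on a set of elements plus their derived structure."""

    elements: list[str]
    relations: set[PairRelation]
    similarity_classes: list[frozenset[str]] = field(default_factory=list)
    covering: set[PairRelation] = field(default_factory=set)

    def __post_init__(self):
        if not self.similarity_classes:
            self.similarity_classes = similarity_classes(self.elements, self.relations)


# ---------------------------------------------------------------------------
# compatibility and enumeration
# ---------------------------------------------------------------------------

def is_compatible(
    state: Sequence[int],
    relations: Iterable[PairRelation],
    elements: Sequence[str],
) -> bool:
    """Whether a full assignment of on/off values violates no relation."""
    idx = {e: i for i, e in enumerate(elements)}
    if len(state) != len(elements):
        raise ValueError("state length does not match the element list")
    for rel in relations:
        if rel.a not in idx or rel.b not in idx:
            raise KeyError(f"relation {rel} references an unknown element")
        if not rel.holds(state[idx[rel.a]], state[idx[rel.b]]):
            return False
    return True


def enumerate_compatible_states(
    elements: Sequence[str],
    relations: Iterable[PairRelation],
) -> list[tuple[int, ...]]:
    """All states compatible with the relations, in lexicographic order.

    Performs an exhaustive sweep of the ``2^m`` assignments and is therefore
    restricted to ``m <= 25`` elements.
    """
    m = len(elements)
    if m > 25:
        raise ValueError(
            f"exhaustive enumeration over 2^{m} states is impractical; "
            "sample states instead"
        )
    relations = list(relations)
    out = []
    for state in itertools.product((0, 1), repeat=m):
        if is_compatible(state, relations, elements):
            out.append(state)
    return out


# ---------------------------------------------------------------------------
# signed-literal implication graph
# ---------------------------------------------------------------------------

def _implications(rel: PairRelation) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Implication edges over literals ``(name, sign)``; sign 1 = plain, 0 = negated.

    Each forbidden cell (a=va, b=vb) yields the implication
    ``(a == va) => (b != vb)`` together with its contrapositive.
    """
    edges = []
    for va, vb in rel.kind.forbidden_cells:
        lhs = (rel.a, va)
        rhs = (rel.b, 1 - vb)
        edges.append((lhs, rhs))
        edges.append(((rel.b, vb), (rel.a, 1 - va)))
    return edges


def _literal_graph(relations: Iterable[PairRelation]) -> nx.DiGraph:
    g = nx.DiGraph()
    for rel in relations:
        g.add_edges_from(_implications(rel))
    return g


def _relation_from_implication(la, lb) -> PairRelation | None:
    """Translate a literal implication back into a one-forbidden-cell relation."""
    (a, sa), (b, sb) = la, lb
    if a == b:
        return None
    # (a == sa) => (b == sb) forbids the cell (a=sa, b=1-sb)
    return PairRelation(a, b, _kind_for_forbidden(sa, 1 - sb))


def _kind_for_forbidden(va: int, vb: int) -> RelationshipKind:
    return {
        (0, 1): RelationshipKind.F01,
        (1, 0): RelationshipKind.F10,
        (0, 0): RelationshipKind.F00,
        (1, 1): RelationshipKind.F11,
    }[(va, vb)]


def closure(relations: Iterable[PairRelation]) -> set[PairRelation]:
    """Transitive closure under prerequisite chaining and similarity substitution.

    Similarity relations act as two-way implications, so chains through
    similar elements (and through dual elements) are followed as well.  The
    result is reported with similarity recombined: when both one-cell patterns
    of a pair are entailed they are merged back into ``SIM``/``SIM_DUAL``.
    Entailments that hold only because a literal is forced (contradictory
    inputs) are not derived; contradictory inputs are simply passed through.
    """
    relations = set(relations)
    g = _literal_graph(relations)
    reach = dict(nx.all_pairs_shortest_path_length(g))
    derived: set[PairRelation] = set()
    for la, targets in reach.items():
        for lb in targets:
            if lb == la:
                continue
            rel = _relation_from_implication(la, lb)
            if rel is not None:
                derived.add(rel)
    return _recombine_similarity(derived | relations)


def _recombine_similarity(rels: set[PairRelation]) -> set[PairRelation]:
    out = set(rels)
    pairs = {(r.a, r.b) for r in rels}
    for a, b in pairs:
        kinds = {r.kind for r in rels if (r.a, r.b) == (a, b)}
        if {RelationshipKind.F01, RelationshipKind.F10} <= kinds:
            out -= {PairRelation(a, b, RelationshipKind.F01),
                    PairRelation(a, b, RelationshipKind.F10)}
            out.add(PairRelation(a, b, RelationshipKind.SIM))
        if {RelationshipKind.F00, RelationshipKind.F11} <= kinds:
            out -= {PairRelation(a, b, RelationshipKind.F00),
                    PairRelation(a, b, RelationshipKind.F11)}
            out.add(PairRelation(a, b, RelationshipKind.SIM_DUAL))
        if RelationshipKind.SIM in kinds:
            out -= {PairRelation(a, b, RelationshipKind.F01),
                    PairRelation(a, b, RelationshipKind.F10)}
        if RelationshipKind.SIM_DUAL in kinds:
            out -= {PairRelation(a, b, RelationshipKind.F00),
                    PairRelation(a, b, RelationshipKind.F11)}
    return out


def _expand_similarity(rels: Iterable[PairRelation]) -> set[PairRelation]:
    """Replace SIM/SIM_DUAL by their two one-cell components."""
    out: set[PairRelation] = set()
    for r in rels:
        if r.kind is RelationshipKind.SIM:
            out.add(PairRelation(r.a, r.b, RelationshipKind.F01))
            out.add(PairRelation(r.a, r.b, RelationshipKind.F10))
        elif r.kind is RelationshipKind.SIM_DUAL:
            out.add(PairRelation(r.a, r.b, RelationshipKind.F00))
            out.add(PairRelation(r.a, r.b, RelationshipKind.F11))
        else:
            out.add(r)
    return out


def similarity_classes(
    elements: Sequence[str], relations: Iterable[PairRelation]
) -> list[frozenset[str]]:
    """Partition of the elements by (transitive) similarity."""
    g = nx.Graph()
    g.add_nodes_from(elements)
    for r in relations:
        if r.kind is RelationshipKind.SIM:
            g.add_edge(r.a, r.b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: sorted(c)[0])


def covering_edges(relations: Iterable[PairRelation]) -> set[PairRelation]:
    """Transitive reduction of the class-level implication order.

    Returns the minimal set of non-similarity relations whose closure,
    together with the similarity relations of the input closure, equals the
    closure of the input.  Raises on an implication cycle that is not a pure
    similarity/duality equivalence, naming the offending elements.
    """
    closed = closure(relations)
    g = _literal_graph(_expand_similarity(closed))
    # condense literal-level equivalences (similar / dual-similar groups)
    sccs = list(nx.strongly_connected_components(g))
    for comp in sccs:
        names = {name for name, _ in comp}
        signs = {}
        for name, sign in comp:
            if name in signs and signs[name] != sign:
                raise ValueError(
                    f"contradictory cycle: element {name!r} is equivalent to its own dual"
                )
            signs[name] = sign
    cond = nx.condensation(g, sccs)
    red = nx.transitive_reduction(cond)
    rep = {i: sorted(comp)[0] for i, comp in enumerate(sccs)}
    out: set[PairRelation] = set()
    for i, j in red.edges():
        rel = _relation_from_implication(rep[i], rep[j])
        if rel is not None:
            out.add(rel)
    return _recombine_similarity(out)
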