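"""Synthetic data: the seven-element worked example, state sampling, noise,
random networks and end-to-end recovery experiments.

The worked example is a seven-element network (elements A–G) whose thirteen
compatible states are embedded verbatim below; its twelve pairwise
relationships are recovered at run time as the maximal relationships holding
in every state, so fixture and semantics cannot drift apart.

Defaults mirror the published study conditions: 100 states drawn uniformly
from the compatible states, each entry flipped independently with
probability 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .counting import perfect_count_relations
from .model import (BinaryMatrix, PairRelation, RelationshipKind,
                    enumerate_compatible_states)

__all__ = [
    "SimulationConfig",
    "RecoveryMetrics",
    "worked_example_matrix",
    "worked_example_fixture",
    "sample_states",
    "perturb",
    "random_dab_network",
    "recovery_experiment",
]

# The 13 compatible states of the worked example, elements A..G by row,
# one column per state.
_WORKED_EXAMPLE_STATES = """
A 0 1 1 1 1 1 1 1 1 1 1 1 1
B 0 0 1 1 1 1 1 1 0 0 0 0 0
C 0 0 0 1 1 1 1 1 1 1 1 1 1
D 1 1 1 1 0 1 0 0 1 0 1 0 0
E 0 0 1 1 1 1 1 1 0 0 0 0 0
F 0 0 0 0 0 1 1 1 0 0 1 1 1
G 0 0 0 0 0 0 0 1 0 0 0 0 1
"""


@dataclass
class SimulationConfig:
    """Sampling settings for a simulated observation matrix."""

    n_samples: int = 100
    epsilon: float = 0.05
    seed: int = 0
    state_weights: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError(f"epsilon must lie in [0, 0.5], got {self.epsilon}")
        if self.state_weights is not None:
            w = np.asarray(self.state_weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("state weights must be a probability vector")
            self.state_weights = w


@dataclass
class RecoveryMetrics:
    """Set comparison of called relations against a ground truth."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def exact_recovery(self) -> bool:
        return self.false_positives == 0 and self.false_negatives == 0


def worked_example_matrix() -> BinaryMatrix:
    """The worked example's 13 compatible states as a 7 x 13 binary matrix."""
    rows = [ln.split() for ln in _WORKED_EXAMPLE_STATES.strip().splitlines()]
    elements = [r[0] for r in rows]
    values = np.array([[int(v) for v in r[1:]] for r in rows], dtype=np.int8)
    return BinaryMatrix(elements, [f"s{i+1}" for i in range(values.shape[1])], values)


def worked_example_fixture() -> tuple[set[PairRelation], list[tuple[int, ...]]]:
    """The worked example: its 12 relationships and 13 compatible states."""
    m = worked_example_matrix()
    relations = set(perfect_count_relations(m, subsume=True))
    states = [tuple(int(v) for v in col) for col in m.values.T]
    return relations, states


def sample_states(states, config: SimulationConfig,
                  elements: list[str] | None = None) -> BinaryMatrix:
    """Draw ``n_samples`` columns i.i.d. from the given states."""
    states = [tuple(s) for s in states]
    if not states:
        raise ValueError("cannot sample from an empty state list")
    if elements is None:
        elements = [chr(ord("A") + i) for i in range(len(states[0]))]
    if config.n_samples == 0:
        warnings.warn("sampling zero states produces an empty matrix")
        return BinaryMatrix(elements, [],
                            np.zeros((len(elements), 0), dtype=np.int8))
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(states), size=config.n_samples, p=config.state_weights)
    values = np.array([states[i] for i in idx], dtype=np.int8).T
    samples = [f"s{i+1}" for i in range(config.n_samples)]
    return BinaryMatrix(elements, samples, values)


def perturb(matrix: BinaryMatrix, epsilon: float, seed: int) -> BinaryMatrix:
    """Flip every entry independently with probability ``epsilon``."""
    if not 0.0 <= epsilon <= 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5], got {epsilon}")
    rng = np.random.default_rng(seed)
    flips = rng.random(matrix.values.shape) < epsilon
    values = np.where(flips, 1 - matrix.values, matrix.values).astype(np.int8)
    return BinaryMatrix(list(matrix.element_ids), list(matrix.sample_ids), values)


def simulate_matrix(states, config: SimulationConfig,
                    elements: list[str] | None = None) -> BinaryMatrix:
    """Sample states and apply bit-flip noise, with split seed streams."""
    ss = np.random.SeedSequence(config.seed).spawn(2)
    clean = sample_states(states, SimulationConfig(
        config.n_samples, 0.0, int(ss[0].generate_state(1)[0] % 2**31),
        config.state_weights), elements=elements)
    return perturb(clean, config.epsilon, int(ss[1].generate_state(1)[0] % 2**31))


def random_dab_network(m: int, density: float = 0.3, seed: int = 0,
                       sim_prob: float = 0.15) -> set[PairRelation]:
    """A random acyclic network: similarity merges plus prerequisite edges.

    Elements are randomly merged into similarity groups (probability
    ``sim_prob`` per element of joining an existing group), the groups are
    put in a random topological order, and each forward group pair receives
    a prerequisite edge with probability ``density``.
    """
    if m < 2:
        raise ValueError("need at least two elements")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    elements = [chr(ord("A") + i) if m <= 26 else f"g{i}" for i in range(m)]
    groups: list[list[str]] = []
    for e in elements:
        if groups and rng.random() < sim_prob:
            groups[rng.integers(len(groups))].append(e)
        else:
            groups.append([e])
    rng.shuffle(groups)
    rels: set[PairRelation] = set()
    for g in groups:
        for a, b in zip(g, g[1:]):
            rels.add(PairRelation(a, b, RelationshipKind.SIM))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if rng.random() < density:
                # representative of the earlier group is prerequisite of the later
                rels.add(PairRelation(groups[i][0], groups[j][0],
                                      RelationshipKind.F01))
    return rels


def recovery_experiment(relations: set[PairRelation], config: SimulationConfig,
                        methods: dict) -> dict[str, RecoveryMetrics]:
    """Sample → perturb → infer with each method; compare against the truth.

    ``methods`` maps a name to a callable ``matrix -> set[PairRelation]``.
    The ground truth is the closure of the input relations restricted to the
    maximal observable pairwise facts.
    """
    elements = sorted({e for r in relations for e in (r.a, r.b)})
    states = enumerate_compatible_states(elements, relations)
    matrix = simulate_matrix(states, config, elements=elements)
    truth = _observable_truth(states, elements)
    out = {}
    for name, method in methods.items():
        called = set(method(matrix))
        out[name] = RecoveryMetrics(
            true_positives=len(called & truth),
            false_positives=len(called - truth),
            false_negatives=len(truth - called),
        )
    return out


def _observable_truth(states, elements) -> set[PairRelation]:
    m = BinaryMatrix(list(elements), [f"s{i}" for i in range(len(states))],
                     np.array(states, dtype=np.int8).T)
    return set(perfect_count_relations(m, subsume=True))
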