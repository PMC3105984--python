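"""The full Steps 1-3 selection procedure."""

import warnings

import numpy as np
import pytest

from dabnet import (BinaryMatrix, InferenceConfig, PairRelation, PairTable,
                    RelationshipKind, enumerate_compatible_states,
                    infer_network, infer_pair, random_dab_network,
                    tabulate_pair)
from dabnet.counting import perfect_count_relations

K = RelationshipKind


def test_published_row_selects_only_the_true_prerequisite():
    # cells recovered from the published (A,B) counting row at N=100
    calls = infer_pair(PairTable(10, 2, 43, 45),
                       InferenceConfig(epsilon=0.05), pair=("A", "B"))
    selected = [c for c in calls if c.selected]
    assert [c.kind for c in selected] == [K.F01]
    assert all(c.count == 98 for c in selected)


def test_noise_free_similar_pair_selects_similarity(worked_matrix):
    t = tabulate_pair(worked_matrix, "B", "E")
    calls = infer_pair(t, InferenceConfig(epsilon=0.0), pair=("B", "E"))
    by_kind = {c.kind: c for c in calls}
    assert by_kind[K.SIM].selected and by_kind[K.SIM].subsumed_by is None
    # the implied one-cell patterns are selected but subsumed
    assert by_kind[K.F01].subsumed_by is K.SIM
    assert by_kind[K.F10].subsumed_by is K.SIM


def test_balanced_table_selects_nothing():
    calls = infer_pair(PairTable(25, 25, 25, 25), InferenceConfig(epsilon=0.05))
    assert not any(c.selected for c in calls)


def test_call_invariants():
    calls = infer_pair(PairTable(10, 2, 43, 45), InferenceConfig(epsilon=0.05))
    assert len(calls) == 6
    for c in calls:
        assert c.selected == (c.passed_count and c.passed_pvalue)
        assert 0.0 <= c.pvalue <= 1.0


def test_noise_free_network_recovers_the_twelve_relations(worked_matrix, worked_states):
    relations, _ = worked_states
    net, report = infer_network(worked_matrix, InferenceConfig(epsilon=0.0))
    assert net.relations == relations
    assert len(net.relations) == 12
    assert frozenset({"B", "E"}) in net.similarity_classes


def test_report_layout_and_identities(worked_matrix):
    _, report = infer_network(worked_matrix, InferenceConfig(epsilon=0.0))
    assert len(report) == 21  # all pairs of seven elements
    for _, row in report.iterrows():
        n = 13
        assert row["count_SIM"] + row["count_SIM_DUAL"] == n
        f_total = sum(row[f"count_{k}"] for k in ("F01", "F10", "F00", "F11"))
        assert f_total == 3 * n
        for k in ("SIM", "SIM_DUAL", "F01", "F10", "F00", "F11"):
            assert 0.0 <= row[f"pvalue_{k}"] <= 1.0


def test_single_element_matrix_is_rejected():
    with pytest.raises(ValueError):
        BinaryMatrix(["A"], ["s1"], np.array([[1]]))


@pytest.mark.parametrize("seed", range(10))
def test_noise_free_completeness_on_random_networks(seed):
    """At eps = 0 the procedure selects exactly the observable maximal
    relations of the compatible-state matrix."""
    rels = random_dab_network(6, density=0.4, seed=seed, sim_prob=0.2)
    elements = sorted({e for r in rels for e in (r.a, r.b)})
    states = enumerate_compatible_states(elements, rels)
    matrix = BinaryMatrix(elements, [f"s{i}" for i in range(len(states))],
                          np.array(states, dtype=np.int8).T)
    truth = set(perfect_count_relations(matrix, subsume=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net, _ = infer_network(matrix, InferenceConfig(epsilon=0.0))
    assert net.relations == truth


def test_both_screens_are_needed_on_noisy_data(worked_states):
    """Some relationships pass only the counting screen, others only the
    p-value screen (mirrors the published simulation's discussion)."""
    from dabnet import simulate_matrix, SimulationConfig
    _, states = worked_states
    m = simulate_matrix(states, SimulationConfig(100, 0.05, seed=5))
    _, report = infer_network(m, InferenceConfig(epsilon=0.05))
    count_only = pvalue_only = 0
    for _, row in report.iterrows():
        for k, tmin in (("SIM", 86), ("F01", 93), ("F10", 93),
                        ("F00", 93), ("F11", 93)):
            passes_count = row[f"count_{k}"] >= tmin
            passes_p = row[f"pvalue_{k}"] >= 1.0
            count_only += passes_count and not passes_p
            pvalue_only += passes_p and not passes_count
    assert count_only > 0
    assert pvalue_only > 0
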