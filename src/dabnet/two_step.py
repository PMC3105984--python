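"""The full two-step selection procedure.

Step 1 screens each pair's six counting numbers against the confidence-bound
thresholds; Step 2 screens the six asymptotic p-values (rounded to a fixed
number of decimals) against the p-value threshold, by default exactly 1; Step
3 keeps the relationships passing both screens.  A selected similarity
logically implies the two single-cell prerequisite patterns of its pair, so
those are reported as subsumed rather than as separate discoveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .counting import (PairTable, ThresholdConfig, relationship_counts,
                       screen_counts, tabulate_pair)
from .inference import asymptotic_pvalue, estimate_epsilon, pooled_epsilon
from .model import (KINDS, BinaryMatrix, NetworkModel, PairRelation,
                    RelationshipKind, covering_edges, similarity_classes)

__all__ = ["InferenceConfig", "RelationshipCall", "infer_pair", "infer_network"]


@dataclass
class InferenceConfig:
    """Settings for a full two-step run.

    ``epsilon`` may be a number or ``"estimate"`` (pooled maximum likelihood
    over all pairs).  The p-value screen compares ``round(p, pvalue_decimals)``
    with ``pvalue_threshold``; the count thresholds are derived from
    ``epsilon`` and ``alpha`` unless fixed explicitly.
    """

    epsilon: float | str = 0.0
    alpha: float = 0.05
    pvalue_threshold: float = 1.0
    pvalue_decimals: int = 4
    t_sim: int | None = None
    t_pre: int | None = None
    report_all: bool = True

    def thresholds(self, epsilon: float) -> ThresholdConfig:
        return ThresholdConfig(
            epsilon=epsilon, alpha=self.alpha,
            pvalue_threshold=self.pvalue_threshold,
            pvalue_decimals=self.pvalue_decimals,
            t_sim=self.t_sim, t_pre=self.t_pre,
        )


@dataclass(frozen=True)
class RelationshipCall:
    """One (pair, kind) candidate with both screening outcomes."""

    pair: tuple[str, str]
    kind: RelationshipKind
    count: int
    pvalue: float
    passed_count: bool
    passed_pvalue: bool
    subsumed_by: RelationshipKind | None = None

    @property
    def selected(self) -> bool:
        return self.passed_count and self.passed_pvalue


def _resolve_epsilon(matrix: BinaryMatrix | None, config: InferenceConfig,
                     table: PairTable | None = None) -> float:
    if config.epsilon == "estimate":
        if matrix is not None:
            ids = matrix.element_ids
            tables = [tabulate_pair(matrix, a, b)
                      for i, a in enumerate(ids) for b in ids[i + 1:]]
            est = pooled_epsilon(tables)
        elif table is not None:
            est = estimate_epsilon(table)
            if not est.converged:
                warnings.warn("per-pair epsilon estimate did not identify a rate")
        else:
            raise ValueError("cannot estimate epsilon without data")
        return min(est.epsilon_hat, 0.5 - 1e-9)
    eps = float(config.epsilon)
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"epsilon must lie in [0, 0.5), got {eps}")
    return eps


def infer_pair(
    table: PairTable,
    config: InferenceConfig,
    pair: tuple[str, str] = ("a", "b"),
    epsilon: float | None = None,
) -> list[RelationshipCall]:
    """Annotate all six relationships of one pair with both screens."""
    eps = epsilon if epsilon is not None else _resolve_epsilon(None, config, table)
    n = table.total
    counts = relationship_counts(table)
    passing = screen_counts(counts, config.thresholds(eps), n)
    calls = []
    for kind in KINDS:
        p = asymptotic_pvalue(kind, table, eps)
        calls.append(RelationshipCall(
            pair=pair, kind=kind, count=counts[kind], pvalue=p,
            passed_count=kind in passing,
            passed_pvalue=round(p, config.pvalue_decimals) >= config.pvalue_threshold,
        ))
    return _mark_subsumed(calls)


def _mark_subsumed(calls: list[RelationshipCall]) -> list[RelationshipCall]:
    by_kind = {c.kind: c for c in calls}
    absorbed: dict[RelationshipKind, RelationshipKind] = {}
    if by_kind[RelationshipKind.SIM].selected:
        for k in (RelationshipKind.F01, RelationshipKind.F10):
            absorbed[k] = RelationshipKind.SIM
    if by_kind[RelationshipKind.SIM_DUAL].selected:
        for k in (RelationshipKind.F00, RelationshipKind.F11):
            absorbed[k] = RelationshipKind.SIM_DUAL
    out = []
    for c in calls:
        if c.selected and c.kind in absorbed:
            out.append(RelationshipCall(c.pair, c.kind, c.count, c.pvalue,
                                        c.passed_count, c.passed_pvalue,
                                        subsumed_by=absorbed[c.kind]))
        else:
            out.append(c)
    return out


def infer_network(
    matrix: BinaryMatrix, config: InferenceConfig
) -> tuple[NetworkModel, pd.DataFrame]:
    """Run the two-step procedure over all element pairs.

    Returns the called network (selected, non-subsumed relations with their
    similarity classes and covering edges) and a per-pair report holding all
    six counting numbers and p-values — the layout of the published
    simulation tables.  Constant elements are flagged in the report since
    none of their pair relationships is empirically distinguishable.
    """
    if matrix.n_elements < 2:
        raise ValueError("network inference needs at least two elements")
    eps = _resolve_epsilon(matrix, config)
    ids = matrix.element_ids
    constant = {e for e in ids if len(set(matrix.row(e))) == 1}
    if constant:
        warnings.warn(f"constant elements: {sorted(constant)}")

    rows = []
    relations: set[PairRelation] = set()
    conflicts = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            table = tabulate_pair(matrix, a, b)
            calls = infer_pair(table, config, pair=(a, b), epsilon=eps)
            selected = [c for c in calls if c.selected and c.subsumed_by is None]
            for c in selected:
                relations.add(PairRelation(a, b, c.kind))
            if len(selected) > 1:
                conflicts.append((a, b, [c.kind.value for c in selected]))
            row = {"pair": f"({a}, {b})", "a": a, "b": b,
                   "constant": a in constant or b in constant}
            for c in calls:
                row[f"count_{c.kind.value}"] = c.count
                row[f"pvalue_{c.kind.value}"] = round(c.pvalue, config.pvalue_decimals)
                row[f"selected_{c.kind.value}"] = c.selected
            rows.append(row)
    if conflicts:
        warnings.warn(f"multiple relationships selected for pairs: {conflicts}")

    try:
        cover = covering_edges(relations)
    except ValueError as exc:  # cyclic or contradictory call set
        warnings.warn(f"covering reduction unavailable: {exc}")
        cover = set()
    net = NetworkModel(
        elements=list(ids),
        relations=relations,
        similarity_classes=similarity_classes(ids, relations),
        covering=cover,
    )
    return net, pd.DataFrame(rows)
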