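"""Screening thresholds and the similarity p-value anchor.

Prints the counting-number thresholds at the two study conditions and
evaluates the six p-values for a pair whose cells were recovered from the
published simulation's counting row for (A, B).
"""

from dabnet import (PairTable, RelationshipKind, asymptotic_pvalue,
                    integer_threshold, prerequisite_threshold,
                    relationship_counts, similar_threshold)

for n, eps in ((100, 0.05), (81, 0.10)):
    ts = integer_threshold(similar_threshold(n, eps))
    tp = integer_threshold(prerequisite_threshold(n, eps))
    print(f"N={n:4d}  eps={eps:.2f}  ->  similar >= {ts}, prerequisite >= {tp}")

table = PairTable(10, 2, 43, 45)  # A off/on x B off/on cells
counts = relationship_counts(table)
print("\npair (A,B): cells (10, 2, 43, 45), N = 100")
for kind in RelationshipKind:
    p = asymptotic_pvalue(kind, table, epsilon=0.05)
    print(f"  {kind.value:9s} count={counts[kind]:3d}  p={p:0.4f}")

# Only the first prerequisite kind combines a counting number above 93 with
# a p-value of 1: the procedure calls "A prerequisite of B" and nothing else
# for this pair.  The similarity p-value of 0.8220 is large but below the
# selection threshold of exactly 1.
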