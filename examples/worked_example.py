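"""The seven-element worked example: counting on noise-free states.

Builds the 7 x 13 matrix of compatible states, finds every (pair,
relationship) combination whose counting number equals the sample size, and
verifies that brute-force enumeration of all 2^7 assignments against those
relationships returns exactly the 13 states we started from.
"""

from dabnet import enumerate_compatible_states, worked_example_matrix
from dabnet.counting import perfect_count_relations

matrix = worked_example_matrix()
print(f"states: {matrix.n_elements} elements x {matrix.n_samples} samples")

relations = perfect_count_relations(matrix, subsume=True)
print(f"\n{len(relations)} relationships with a perfect counting number:")
for r in relations:
    print(f"  {r.a} {r.kind.value} {r.b}")

states = enumerate_compatible_states(matrix.element_ids, set(relations))
print(f"\ncompatible states under those relationships: {len(states)}")
print("identical to the input states:",
      set(states) == {tuple(col) for col in matrix.values.T})

# Each line above is a pairwise fact the 13 states support without a single
# violation; together they pin down the directed acyclic Boolean network,
# and re-enumerating its state space closes the loop.
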