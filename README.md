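# dabnet

Reconstruction of directed acyclic Boolean (DAB) gene networks from noisy
on/off data by a two-step counting method, with misclassification-corrected
cell estimation, asymptotic screening p-values, confidence-bound count
thresholds, a simulator, and two baseline screens (Boolean-implication
statistics and a constrained error-rate criterion).

## The problem

Boolean models of gene regulation reduce each gene to an on/off state and
describe a pathway by pairwise facts of two families: *similarity* (two
genes switch together, or one mirrors the other's complement) and
*prerequisite* (one gene's on-state is necessary for another's; with
complemented genes there are four variants, each forbidding exactly one of
the four joint states of a pair).  A DAB network is identified with its
compatible state space — the set of global on/off assignments violating no
pairwise fact.  Given microarray-style observations in which every entry is
misread independently with probability ε, the task is to decide, for each
of the m(m−1)/2 pairs and each of the 6 relationship kinds, whether the
relationship holds.

## The method

For a pair observed over N samples, the **counting number** of a candidate
kind is the number of samples in its allowed cells; a true kind counts
N(1 − O(ε)).  The procedure is:

1. keep kinds whose counting number reaches a lower confidence-bound
   threshold, `⌊N(1 − mass(ε_u))⌋` with `ε_u = ε + z₁₋α √(ε(1−ε)/2N)` and
   forbidden mass `2ε(1−ε)` (similarity) or `ε(1−ε)` (prerequisite);
2. keep kinds whose asymptotic screening p-value rounds to 1 — closed
   forms in the observed cells: for similarity
   `p = min(1, erfc(z/√2))` with `z = √N[(q01+q10)² − 4 q00 q11]`, and for
   the one-cell kinds the folded standardised residual of the forbidden
   cell against its margin-product expectation;
3. call the kinds passing both screens (a called similarity subsumes the
   two one-cell patterns it implies).

Details, derivations and caveats are in [docs/methods.md](docs/methods.md).

## Worked example

`examples/thresholds_and_pvalues.py` screens one pair whose 2×2 cells are
(10, 2, 43, 45) over N = 100 samples at ε = 0.05:

```
N= 100  eps=0.05  ->  similar >= 86, prerequisite >= 93
N=  81  eps=0.10  ->  similar >= 61, prerequisite >= 71

pair (A,B): cells (10, 2, 43, 45), N = 100
  SIM       count= 55  p=0.8220
  SIM_DUAL  count= 45  p=0.0073
  F01       count= 98  p=1.0000
  F10       count= 57  p=1.0000
  F00       count= 90  p=0.1358
  F11       count= 55  p=0.4598
```

Only `F01` ("A prerequisite of B") combines a counting number above the
prerequisite threshold (98 ≥ 93) with a p-value of exactly 1, so it is the
single call for this pair.  `F10`'s p-value is also 1 — its forbidden cell
is below chance expectation — but its counting number 57 fails Step 1,
which is why both screens are needed.

`examples/noisy_recovery.py` runs the full pipeline on 100 simulated states
of the seven-element reference network (entries flipped with probability
0.05) and prints the 12 called relations, e.g. `A F01 B`, `B SIM E`,
`D F11 G`, matching the generating network exactly on that seed.  The other
examples cover the noise-free counting census, the baseline comparison, and
binarization of log-ratio expression values.

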