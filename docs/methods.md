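# Methods

## Model

A tensor Markov field is a Markov random field over tensor-indexed variables
X_ih (variable i ∈ {0..N−1}, layer h ∈ {0..L−1}), represented as an
undirected multilayer graph Ĝ on the N·L vertex grid. Labels come from a
finite ordered set S (|S| ≥ 2) with a designated default element; a
configuration assigns a label to every vertex. A Gibbs field places strictly
positive potentials on cliques — where *clique* always means every complete
subset, including ∅ and singletons, because the unrestricted clique product
is what makes the Gibbs ⇔ Markov equivalence hold — and defines
P(ω) ∝ ∏_C φ_C(ω_C). Strict positivity is a standing hypothesis: it is what
licenses the Möbius potential construction and the pairwise ⇒ global Markov
implication, so zero probabilities raise `PositivityError` rather than being
smoothed away.

Inter-layer self-coupling edges {(i,h),(i,k)} with h ≠ k are legal; only
literal self-loops are not. This mirrors the bi-delta convention in the MI
pipeline: only exact self-pairs (same variable *and* same layer) are masked.

## Exactness and numerics

All probabilistic primitives are exact enumerations over S^(N·L), guarded at
2^20 configurations; operations refuse larger spaces (`CapacityError`)
rather than approximate silently. Products of potentials and the Möbius
inclusion–exclusion products are accumulated in log space with integer sign
bookkeeping, so candidate potentials are exact up to floating-point
rounding (observed reconstruction errors ~1e-12 on 9-vertex fields).
Conditional-independence deviations on joint tables use the
cross-multiplied form |P(uvS)P(S) − P(uS)P(vS)|/P(S)², which avoids
dividing by small marginals; deviations below tol = 1e-6 classify as CI
(exact CI sits at ~1e-16, genuine dependence in these fields at ≥ 1e-3, so
the classification gap is about ten orders of magnitude). Identity-style
checks (factorization, clique support) default to tol = 1e-8.

The single-site heat-bath sampler provided for fields above the enumeration
guard is approximate (correlated draws, default burn-in 100 sweeps per
vertex) and is used for fixture generation only — never as an oracle.

## I-map checking

`is_independence_map` certifies the global Markov property. Rather than
enumerating all 4^n disjoint triples (A,B,C), it enumerates separator sets C
and, for each, every bipartition of the connected components of Ĝ − C into
two nonempty sides. Every separated triple is contained in one of these
maximal triples, and conditional independence passes to subsets of A and B
(the decomposition property, which holds for every distribution), so the
check is exhaustive while staying polynomial in practice for the 8–10-vertex
fields it targets. Above the 10-vertex guard a reduced, explicitly labeled
check runs instead (all pairwise CI for non-edges plus all single-vertex
separators).

The minimal I-map of a positive joint is built pairwise: an edge is drawn
exactly when the two vertices are *dependent* given all others.

## Mutual-information inference

The MI estimator is the plug-in (maximum-likelihood) functional on the
empirical contingency table, reported in bits. Terms are summed in sorted
order so I(x,y) equals I(y,x) bit-for-bit. No bias correction is applied by
default — the raw functional is the estimand of interest; at the default
10 bins and n = 1000+ samples the plug-in bias for independent continuous
pairs stays below 0.1 bits, which the tests assert empirically.

Continuous columns are discretized by equal-frequency (quantile) binning,
default 10 bins: codes depend only on ranks (ties broken by stable sample
order), hence are invariant under strictly increasing transforms — a useful
property for expression-like data with arbitrary monotone normalizations.
Columns with at most `n_bins` distinct values pass through as order-
preserving relabelings; constant columns collapse to one bin with a warning.
A consequence of median-splitting is that the zero-noise limit of the
continuous emulation recovers a binary label partition exactly only when the
labels are balanced; otherwise mismatches are bounded by the imbalance.

Thresholding uses the strict convention Θ(x) = 1 iff x > 0, so an entry
exactly at I₀ is excluded (deterministic, no Θ(0) ambiguity). The
permutation threshold is the (1−α) quantile of the pooled null: every
column independently permuted, all pairwise MI values collected, repeated
`n_perm` times. Note what this calibrates: the null of *independence* per
pair. It does not control for multiplicity (≈ α·binom(NL,2) chance
exceedances per run) and it cannot screen out *indirect* dependence —
marginal MI between two-step-connected vertices is genuine statistical
dependence and routinely exceeds any independence-null threshold. Threshold
inference is therefore a relevance network, not a faithful-graph estimator;
exact conditional-independence recovery is available through
`ci_graph_from_joint` when the joint is enumerable, and empirically through
`empirical_ci_test` (conditional MI with permutations stratified on the
conditioning configuration, conditioning sets capped at 3 so strata stay
populated).

## Synthetic study conditions

The generator's defaults define the reference conditions used throughout
the tests: N = 4 variables, L = 2 layers, binary labels (256-entry joint,
enumerable in microseconds), 2000 exact samples, interaction strength 1.0.
Edge densities default to p_intra = 0.25 and p_inter = 0.10, chosen once to
give an average degree near 1 — the sparsity regime of small illustrative
multilayer dependency graphs and of curated omics subnetworks. Edge
potentials draw each log-entry uniformly from ±[0.2·strength, strength];
the magnitude floor keeps individual entries away from flatness, though the
*interaction* part of a table (what survives marginalization) can still
nearly cancel between entries, so a small fraction of planted edges carry
very little marginal dependence. The continuous emulation maps label
indices to unit-spaced levels plus Gaussian noise (default sd 0.5, roughly
half the cluster separation).

All randomness flows from one scenario seed through named substreams
(graph / potentials / sampling / noise), so components regenerate
independently and scenarios are bit-reproducible.

What passing tests show — and what they do not: exactness results
(locality, factorization, clique support, I-maps, kernel identities) are
checked by full enumeration and transfer to any discrete field of similar
size. Sample-based results are specific to these conditions; real omics
data add library-size effects, count noise, batch structure and thousands
of variables, none of which the generator emulates.

## Problem sizes

Defaults keep everything interactive: exactness sweeps use 50 random fields
of up to 9 binary vertices; I-map recovery uses 100 default scenarios on the
exact joint; degree identities use 1000 random tensors; sample-based
recovery uses 20 scenarios × 2000 samples × 100 permutations. The full test
suite runs in well under a minute on one core.

## Known limitations

- Exact machinery is limited to enumerable configuration spaces (≈ ≤ 20
  binary vertices; verification sweeps are guarded at 10 because they
  enumerate the subset lattice).
- Only discrete (or discretized) variables; no continuous-state fields, no
  CDF-based CI, no kNN/kernel MI estimators.
- Undirected models only — no chain graphs, no causal orientation.
- Threshold-based MI inference inherits the relevance-network failure mode
  described above: indirect dependencies can enter, and interaction-
  cancelled edges can be missed, regardless of sample size.
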