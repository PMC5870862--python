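# Methods

## Model and assumptions

A design problem is (Θ₁…Θ_M, Υ₁…Υ_n): M equal-length secondary
structures (sets of base pairs (i, j), partners at least three bases
apart, crossing pairs allowed) and per-position allowed-nucleotide sets.
A sequence is a solution iff every pair of every structure is in
B = {AU, UA, GC, CG, GU, UG} and every position respects its allowed
set. The machinery treats structures purely combinatorially — no energy
model enters counting or sampling; thermodynamics appears only in the
optimizer's objective.

The union dependency graph (vertex per position, edge per pair in any
structure) is bipartite exactly when the structural constraints are
simultaneously satisfiable: B is the edge set of the path A–U–G–C, whose
adjacency matrix P is the transfer ("pairing") matrix, and pairing
parity makes odd dependency cycles unsatisfiable. Bipartiteness is
checked by BFS two-coloring with an odd-cycle certificate (reported
1-based). Sequence constraints are propagated to arc consistency (AC-3
fixpoint over edges): sound — a letter is only removed when no
neighbouring assignment could ever support it — but intentionally not
claimed complete; the final feasibility authority is the exact count
(|C| = 0 ⇔ infeasible). An emptied domain yields a position-numbered
error early.

## Decomposition

Components are split into biconnected blocks (networkx block
decomposition); blocks with a vertex of degree ≥ 3 are ear-decomposed
relative to a spanning tree: the first ear is the fundamental cycle of
the first non-tree edge, each further non-tree edge contributes its
uncovered fundamental-cycle segments as path ears whose endpoints (never
interiors) lie in earlier ears. Every edge lands in exactly one ear, so
the leaf edge sets partition the graph. k sibling pieces are binarized
as a left-deep chain in deterministic order (components by smallest
vertex, blocks by block-cut traversal, ears by ear index); counting is
associative, so binarization affects only cost, never results.

Ear decompositions are spanning-tree dependent, and the articulation-set
sizes α = |S_H| (table dimensions, memory 4^α) and β = |S_left ∪
S_right| (work 4^β) can vary widely. Per block, 10 random spanning trees
are tried by default (shuffled-edge Kruskal; the count is a tunable, the
search is seeded) and the candidate minimizing (max α, max β, Σ4^α) is
kept — ties broken in that lexicographic order, a choice made here since
"lowest α and β" can conflict between trees. Solution counts are
invariant to all of these choices, which the tests assert over 10 seeds
per fixture.

## Counting and sampling

Path/cycle leaves are counted by masked transfer-matrix products (domain
masks folded in per vertex; cycles close the trace, rotated to start at
a fixed vertex when one exists). Leaf tables enumerate the ≤ 4^α
articulation colorings and store non-zero counts sparsely. Internal
nodes multiply child tables component-wise over shared dimensions; a
dimension is summed out exactly when its assembled degree reaches its
union-graph degree. All counts are Python integers end to end — floating
point is banned from this path because sampling correctness depends on
exactness (solution spaces beyond 2^63 are routine and unit-tested).

Sampling inverts the forward pass as a *rank descent*: an integer r
drawn uniformly from [0, |C|) is split at every node over the
articulation-letter options in proportion to their exact counts
(canonical option order: vertices ascending, letters alphabetical), the
two child sub-ranks via mixed-radix `divmod`, and along leaves by suffix
counts. This makes rank → sequence a bijection (unit-tested by full
enumeration on small fixtures), hence every solution has probability
exactly 1/|C| — no floating-point probability tables, no rounding bias.

Moves: C-local redraws one component, selected proportionally to its
solution count by default (an unweighted flag exists — the two
descriptions of the selector in the source method differ, and weighted
is the documented default here); P-local redraws only the
non-articulation interior of one leaf, conditioned on the current
articulation letters, so the result is uniform over completions
consistent with the untouched rest; position moves delegate to P-local
or (for articulation positions) C-local; a history of accepted
sequences supports `revert`. The biased comparator keeps the same
traversal but chooses articulation colorings uniformly over non-zero
options — it exists to demonstrate, not to use.

## Objectives and optimizer

The corrected objective (default) is
(1/M)Σ(Eᵢ − G) + ξ·(2/(M(M−1)))Σ_{i<j}|Eᵢ − Eⱼ| with ξ = 0.5, making
both terms per-item averages so their balance does not drift with M;
the classic form Σ(Eᵢ − G) + ξ·Σ(Eᵢ − Eⱼ)² (ξ = 1, absolute-difference
variant by flag) is kept for comparison. The adaptive walk starts from
one global sample, applies one move per trial (uniform mix of P-local /
C-local / global by default), and accepts only strictly lower cost than
the best so far — equal-cost moves are rejected by design. It halts
after `stop` (default 1000) consecutive non-improving *candidates*
(candidates, not accepted moves, are counted — the stopping rule is
phrased ambiguously in the literature and this is the stricter reading).
An optional Metropolis/simulated-annealing acceptance
(exp(−Δ/T), geometric cooling, off by default; parameters are this
package's own) explores plateaus.

Energy backends implement `structure_energy`, `mfe_energy`,
`ensemble_energy`. The mock model (pair weights GC/CG 3, AU/UA 2, GU/UG
1; structure energy = −Σ weights; MFE = best target; ensemble = MFE − 1)
is deterministic and satisfies the backend invariants by construction —
it exists so the optimizer is testable without thermodynamics software,
and it is *not* a physical model: with it δe1 is identically 0 and
costs bottom out at the fixed ensemble gap of 1. The ViennaRNA adapter
is used only when its bindings are importable and is never required by
tests. n_mfe uses a 0.01 kcal/mol tolerance because backends report
rounded decimals.

## Synthetic fixtures and what passing tests show

`random_design` grows M structures pair by pair (separation ≥ 4,
union kept bipartite by rejection), with n//4 + 1 pairs per structure —
a density chosen once so that random unions exercise paths, cycles and
blocks while keeping solution spaces enumerable (|C| up to ~10⁵ at
n = 14) for oracle cross-checks. Constraints are sprinkled as IUPAC
codes that each contain the letter of a pre-computed witness sequence,
so generated fixtures are always solvable. The generator emulates the
*combinatorial* shape of multi-target design problems; it does not
emulate realistic structure statistics (helix stacking, loop-size
distributions) or biological sequence composition, so passing tests
certify the counting/sampling machinery, not design quality on natural
RNAs.

The brute-force oracle is independent of the engine: union-find
components plus per-position backtracking that checks every pair
directly. Uniformity is tested by chi-square goodness of fit with one
cell per solution (no binning), sample sizes ≥ 200·|C| at α = 0.001, on
five fixed fixtures with |C| between 14 and 2304 — sizes chosen so the
full suite runs in well under a minute of sampling. The coverage check
draws d = 2.3·|C| samples and compares the unique fraction to
1 − (1 − 1/|C|)^d (≈ 90 %).

## Numerical and degenerate-input choices

* All user-facing positions 1-based; internal 0-based.
* Pair separation (j − i ≥ 4) enforced at parse time, suppressible;
  the graph machinery itself does not need it.
* `T` is silently read as `U`; duplicate pairs across structures
  collapse to one edge.
* A letters-only uppercase line in a design file is the (single)
  IUPAC constraint; anything with dots or brackets is a structure.
* Zero-dimension memo tables hold exactly `{(): count}`; an all-zero
  table reduces to `{(): 0}`.
* Singleton positions are their own decomposition leaves; a P-local
  move on one redraws it uniformly from its domain.

## Known limitations

* No Boltzmann/energy-weighted sampling — counts are purely
  combinatorial.
* The spanning-tree search is heuristic; no claim of minimal α.
* The optimizer is a single-trajectory adaptive walk, not a population
  or multi-objective method.
* CT/BPSEQ input formats and alignment-level constraints are out of
  scope.
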