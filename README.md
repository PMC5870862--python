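# rnadraft

Multi-target nucleic acid sequence design: exact counting and provably
uniform sampling of sequences compatible with several secondary
structures at once, plus an adaptive-walk optimizer on top.

## The problem

Synthetic riboswitches, thermometers and other multi-stable RNAs must
fold into two or more prescribed secondary structures Θ₁…Θ_M while also
respecting per-position sequence constraints Υᵢ ⊆ {A, U, G, C} (given as
IUPAC codes). The set of sequences *x* with (xᵢ, xⱼ) ∈ B =
{AU, UA, GC, CG, GU, UG} for every pair (i, j) of every target
structure, and xᵢ ∈ Υᵢ everywhere, is the *solution space* C. Design
pipelines need to (a) know |C| exactly, (b) draw from C uniformly — so
that optimization explores the space instead of rediscovering the same
biased candidates — and (c) mutate a candidate locally without ever
leaving C.

## The method

* **Dependency graph.** One vertex per position, one edge per base pair
  occurring in any target structure. A solution exists iff this union
  graph is bipartite (pairing alternates letters along every dependency
  path); an odd cycle is reported as a certificate. Domains are
  pre-reduced to arc consistency.
* **Decomposition.** The graph is split hierarchically — connected
  components → biconnected components → ear decomposition of complex
  blocks — into a binary tree whose leaves are paths and cycles. The
  vertices where pieces attach (articulation points S_H) drive the cost:
  memory is O(4^α), α = |S_H|, work O(4^β); random spanning trees are
  sampled per block and the lowest-(α, β) ear decomposition kept.
* **Counting.** Paths and cycles are counted by masked transfer-matrix
  products over the pairing matrix P (the adjacency matrix of the path
  A–U–G–C); a free path of v vertices has 2·F(v+2) colorings (Fibonacci
  F). Sparse memorization tables indexed by articulation colorings are
  multiplied component-wise up the tree, with dimensions summed out as
  soon as a vertex reaches its full union-graph degree. The root table
  stores |C| as an exact (arbitrary-precision) integer.
* **Uniform sampling.** A rank drawn uniformly from [0, |C|) is pushed
  back down the tree, split at every articulation decision in proportion
  to exact counts. The rank → sequence map is a bijection, so every
  compatible sequence has probability exactly 1/|C|. Move set: *global*
  (new sequence), *C-local* (one connected component, count-weighted
  selection), *P-local* (interior of one decomposition leaf, articulation
  letters held fixed), position-targeted moves, history with revert, and
  a deliberately *biased* comparator for experiments.
* **Optimization.** An adaptive walk minimizes either
  f(x) = Σᵢ(Eᵢ − G) + ξ·Σ_{i<j}(Eᵢ − Eⱼ)²  (classic), or the
  M-normalized variant
  f(x) = (1/M)Σᵢ(Eᵢ − G) + ξ·(2/(M(M−1)))·Σ_{i<j}|Eᵢ − Eⱼ|
  (default, ξ = 0.5), where Eᵢ = E(x, Θᵢ) and G(x) is the ensemble free
  energy. Energy backends are pluggable: a deterministic mock model for
  testing, and a ViennaRNA adapter when its Python bindings are present.
  Reported metrics: δe1/δe2 (gap of best/worst target to the MFE) and
  n_mfe (targets at the MFE).

## Worked example

A design file holds one dot-bracket structure per line (extra bracket
families `[] {} <> Aa…Zz` encode pseudoknots), an optional IUPAC
constraint line, and `#` comments:

```
# two-state toy switch
((((...)))).....
.....((((...))))
NNNNNNNGNNNNNNNN
```

```
$ rnadraft info demo.design
length n           : 16
structures M       : 2
components         : 8
articulation points: none
max alpha / beta   : 0 / 0
solutions |C|      : 829440
...
```

829 440 sequences satisfy both hairpins and the fixed G — counted
exactly, not estimated. α = β = 0 because every component is a plain
path: tables never exceed a single entry.

```
$ rnadraft sample demo.design --num 3 --seed 7
>design.1 seed=7 mode=global
CAUUGGUGGUGACCAC
>design.2 seed=7 mode=global
GUUUUAAGGGCGUCUU
>design.3 seed=7 mode=global
UUGCUUUGUGAGGCAG
```

Each draw is uniform over all 829 440 solutions and reproducible from
the seed.

```
$ rnadraft optimize demo.design --stop 200 --seed 1 --runs 2
run  seed  cost    trials  delta_e1  delta_e2  n_mfe  sequence
1    1     1.0000  200     0.0000    0.0000    2      CAACGGGGUUGUGCCC
2    2     1.0000  205     0.0000    0.0000    2      UCACAUAGUGGGACUA
```

Under the mock energy model both targets reach the ground state
(δe1 = δe2 = 0, n_mfe = 2); the cost of 1.0 is the residual ensemble
gap, which this backend fixes at 1 by construction.

The same functionality is available as a library
(`rnadraft.build_model`, `sample_global`, `DesignSampler`,
`adaptive_walk`, …); see `docs/methods.md` for the model details.

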