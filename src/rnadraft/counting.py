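"""Exact solution counting by dynamic programming over the decomposition.

Every quantity here is an arbitrary-precision integer: uniform sampling
downstream divides by these counts, and any rounding would bias it, so
floating point is deliberately absent from this module.

Path and cycle leaves are counted with a transfer-matrix product over the
pairing matrix P (the adjacency matrix of the path A-U-G-C), with
per-vertex domain masks folded into the product.  A leaf with attachment
vertices (its articulation set) yields a sparse memorization table: one
exact count per assignment of letters to those vertices.  Internal tree
nodes combine their children's tables by component-wise multiplication
over shared dimensions; as soon as an articulation vertex has reached its
full union-graph degree inside the assembled subgraph, nothing further
attaches there and its dimension is summed out ("internalized").  The
root table has zero dimensions and stores |C|, the exact number of
sequences compatible with all structures and sequence constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .constraints import ALPHABET, PAIR_RULE
from .decompose import DecompositionTree, SubgraphNode
from .graph import DependencyGraph

#: 4x4 pairing matrix over the alphabet order (A, U, G, C); entry 1 iff
#: the ordered pair is allowed.  Equals the path graph A-U-G-C.
PAIRING_MATRIX: Tuple[Tuple[int, ...], ...] = tuple(
    tuple(1 if (a, b) in PAIR_RULE else 0 for b in ALPHABET) for a in ALPHABET
)

_CANONICAL = tuple(sorted(ALPHABET))  # letter iteration order for tables


def _pairs_with(a: str) -> Tuple[str, ...]:
    ia = ALPHABET.index(a)
    return tuple(b for jb, b in enumerate(ALPHABET) if PAIRING_MATRIX[ia][jb])


_PARTNER_LETTERS = {a: frozenset(_pairs_with(a)) for a in ALPHABET}


@dataclass
class MemoTable:
    """Sparse map from articulation-vertex letter tuples to exact counts.

    ``dims`` is the ordered (ascending vertex id) list of articulation
    vertices; a zero-dimension table holds the single entry ``()`` with
    the subgraph's total count.  Absent keys mean zero.
    """

    dims: Tuple[int, ...]
    entries: Dict[Tuple[str, ...], int] = field(default_factory=dict)

    def get(self, key: Tuple[str, ...]) -> int:
        return self.entries.get(key, 0)

    def total(self) -> int:
        return sum(self.entries.values())


def concatenate(left: MemoTable, right: MemoTable) -> MemoTable:
    """Join two tables: union of dimensions, component-wise products.

    Entries must agree on shared dimensions; disjoint dimensions give the
    full outer product (independent subproblems multiply).
    """
    dims = tuple(sorted(set(left.dims) | set(right.dims)))
    shared = sorted(set(left.dims) & set(right.dims))
    l_shared = [left.dims.index(v) for v in shared]
    r_shared = [right.dims.index(v) for v in shared]
    # index the right table by its projection onto the shared dimensions
    r_index: Dict[Tuple[str, ...], List[Tuple[Tuple[str, ...], int]]] = {}
    for rkey, rval in right.entries.items():
        proj = tuple(rkey[k] for k in r_shared)
        r_index.setdefault(proj, []).append((rkey, rval))
    out: Dict[Tuple[str, ...], int] = {}
    pos_of = {v: k for k, v in enumerate(dims)}
    for lkey, lval in left.entries.items():
        proj = tuple(lkey[k] for k in l_shared)
        for rkey, rval in r_index.get(proj, ()):
            key = [""] * len(dims)
            for v, letter in zip(left.dims, lkey):
                key[pos_of[v]] = letter
            for v, letter in zip(right.dims, rkey):
                key[pos_of[v]] = letter
            out[tuple(key)] = lval * rval
    return MemoTable(dims=dims, entries=out)


def reduce(table: MemoTable, vertex: int) -> MemoTable:
    """Sum out one dimension (internalize an articulation vertex).

    Conserves the total count.
    """
    if vertex not in table.dims:
        raise ValueError(f"vertex {vertex} is not a dimension of this table")
    k = table.dims.index(vertex)
    dims = table.dims[:k] + table.dims[k + 1 :]
    out: Dict[Tuple[str, ...], int] = {}
    for key, val in table.entries.items():
        short = key[:k] + key[k + 1 :]
        out[short] = out.get(short, 0) + val
    if not out and not dims:
        out = {(): 0}
    return MemoTable(dims=dims, entries=out)


# ---------------------------------------------------------------------------
# leaf counts via masked transfer matrices


def path_count(
    walk: Sequence[int],
    domains: Sequence[FrozenSet[str]],
    fixed: Optional[Dict[int, str]] = None,
) -> int:
    """Count letter assignments along a simple path.

    ``domains`` maps each walk vertex (by graph id via ``domains[v]``) to
    its allowed letters; ``fixed`` optionally pins vertices to single
    letters.  Implemented as a masked transfer-matrix product: linear in
    the walk length, exact integers throughout.
    """
    fixed = fixed or {}
    masks = [
        frozenset((fixed[v],)) if v in fixed else domains[v] for v in walk
    ]
    if any(v in fixed and fixed[v] not in domains[v] for v in walk):
        return 0
    # state: counts per letter at the current vertex
    state = {a: 1 for a in masks[0]}
    for mask in masks[1:]:
        nxt = {b: 0 for b in mask}
        for a, cnt in state.items():
            for b in _PARTNER_LETTERS[a]:
                if b in mask:
                    nxt[b] += cnt
        state = nxt
    return sum(state.values())


def cycle_count(
    walk: Sequence[int],
    domains: Sequence[FrozenSet[str]],
    fixed: Optional[Dict[int, str]] = None,
) -> int:
    """Count letter assignments around a closed walk (even cycle).

    The masked transfer-matrix trace: fix the first vertex's letter,
    propagate along the cycle, and require the last letter to pair back.
    """
    fixed = fixed or {}
    if any(v in fixed and fixed[v] not in domains[v] for v in walk):
        return 0
    masks = [
        frozenset((fixed[v],)) if v in fixed else domains[v] for v in walk
    ]
    total = 0
    for a in masks[0]:
        state = {a: 1}
        for mask in masks[1:]:
            nxt = {b: 0 for b in mask}
            for x, cnt in state.items():
                for b in _PARTNER_LETTERS[x]:
                    if b in mask:
                        nxt[b] += cnt
            state = nxt
        total += sum(cnt for x, cnt in state.items() if a in _PARTNER_LETTERS[x])
    return total


def leaf_table(node: SubgraphNode, graph: DependencyGraph) -> MemoTable:
    """Memorization table of a path/cycle/singleton leaf.

    Dimensions are the leaf's articulation vertices; each entry counts
    the leaf assignments consistent with that articulation coloring.
    """
    dims = node.articulation_set(graph)
    walk = node.walk
    counter = cycle_count if node.closed else path_count
    entries: Dict[Tuple[str, ...], int] = {}
    choice_sets = [sorted(graph.domains[v], key=_CANONICAL.index) for v in dims]
    for combo in product(*choice_sets):
        fixed = dict(zip(dims, combo))
        cnt = counter(walk, graph.domains, fixed)
        if cnt:
            entries[tuple(combo)] = cnt
    if not dims and () not in entries:
        entries[()] = 0
    return MemoTable(dims=dims, entries=entries)


# ---------------------------------------------------------------------------
# forward recursion


def build_tables(tree: DecompositionTree) -> MemoTable:
    """Bottom-up forward pass: fill ``node.table`` for every tree node.

    Internal nodes concatenate their children's tables, then internalize
    every dimension whose assembled degree equals its union-graph degree
    (recorded in ``node.reduced``).  Returns the root table.
    """
    graph = tree.graph

    def visit(node: SubgraphNode) -> MemoTable:
        if node.is_leaf:
            node.table = leaf_table(node, graph)
            node.reduced = ()
            return node.table
        left, right = node.children
        table = concatenate(visit(left), visit(right))
        deg: Dict[int, int] = {}
        for i, j in node.edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        reduced = []
        for v in list(table.dims):
            if deg.get(v, 0) == graph.degree(v):
                table = reduce(table, v)
                reduced.append(v)
        node.table = table
        node.reduced = tuple(reduced)
        return table

    return visit(tree.root)


def count_solutions(tree: DecompositionTree) -> int:
    """Exact |C|: total sequences compatible with all constraints."""
    root_table = build_tables(tree)
    if root_table.dims:  # pragma: no cover - root is always fully internalized
        raise RuntimeError("root table still has open dimensions")
    return root_table.get(())
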