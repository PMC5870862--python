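"""Hierarchical decomposition of the dependency graph.

The graph is broken down until every piece is a path or a cycle:

    graph -> connected components -> biconnected components (blocks)
          -> ear decomposition of complex blocks -> path / cycle leaves

The result is a binary tree: leaves hold paths and cycles (maximum vertex
degree two), every internal node re-assembles its two children, and the
root holds the complete graph.  The vertices through which a subgraph is
still attached to the rest of the graph (its articulation set ``S_H``)
index the memorization tables of the counting stage; table sizes grow as
``4**|S_H|``, so the decomposition tries to keep articulation sets small.

Ear decompositions are not unique: they derive from a spanning tree of the
block, and the choice can change the table sizes dramatically.  A number
of random spanning trees is therefore tried per block and the one with the
lowest complexity (lexicographic on max alpha, max beta, total table
weight) is kept.  The decomposition only affects cost — every choice
yields the same solution count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .graph import DependencyGraph

Edge = Tuple[int, int]


class NodeKind(Enum):
    ROOT = "root"
    CONNECTED_COMPONENT = "connected_component"
    BICONNECTED_COMPONENT = "biconnected_component"
    EAR = "ear"
    PATH_LEAF = "path_leaf"
    CYCLE_LEAF = "cycle_leaf"


def _norm(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass(eq=False)
class SubgraphNode:
    """One node of the decomposition tree.

    Leaves carry an ordered vertex ``walk`` (closed for cycles).  The
    counting stage later attaches ``table``/``dims``/``reduced``.
    """

    kind: NodeKind
    vertices: FrozenSet[int]
    edges: FrozenSet[Edge]
    children: Tuple["SubgraphNode", ...] = ()
    walk: Optional[Tuple[int, ...]] = None
    closed: bool = False
    # filled in by the counting stage
    table: Optional[object] = None
    reduced: Tuple[int, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def articulation_set(self, graph: DependencyGraph) -> Tuple[int, ...]:
        """Vertices of this subgraph still attached to the outside: their
        degree here is lower than in the union graph."""
        deg: Dict[int, int] = {v: 0 for v in self.vertices}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return tuple(sorted(v for v in self.vertices if deg[v] < graph.degree(v)))

    def iter_nodes(self):
        yield self
        for child in self.children:
            yield from child.iter_nodes()


@dataclass
class ComplexityReport:
    """Memory/CPU exponents of the dynamic program on a decomposition.

    alpha = |S_H| per node (table dimension count, memory ``O(4**alpha)``);
    beta = |S_left ∪ S_right| per internal node (work ``O(4**beta)``).
    """

    alphas: Dict[int, int]
    betas: Dict[int, int]
    max_alpha: int
    max_beta: int
    sum_alpha: int
    sum_beta: int
    table_weight: int  # sum of 4**alpha over nodes, a proxy for stored entries


@dataclass
class DecompositionTree:
    root: SubgraphNode
    #: subtree root per connected component, ordered by smallest vertex
    components: List[SubgraphNode]
    graph: DependencyGraph

    @property
    def leaves(self) -> List[SubgraphNode]:
        return [n for n in self.root.iter_nodes() if n.is_leaf]

    def render(self) -> str:
        """Indented text rendering of the tree (1-based positions)."""
        lines: List[str] = []

        def walk(node: SubgraphNode, depth: int):
            if node.walk is not None:
                detail = "-".join(str(v + 1) for v in node.walk)
                if node.closed:
                    detail += f"-{node.walk[0] + 1}"
            else:
                detail = ",".join(str(v + 1) for v in sorted(node.vertices))
            lines.append("  " * depth + f"{node.kind.value} [{detail}]")
            for child in node.children:
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph decomposition {"]
        ids = {id(n): k for k, n in enumerate(self.root.iter_nodes())}
        for node in self.root.iter_nodes():
            label = node.kind.value
            if node.walk is not None:
                label += ":" + "-".join(str(v + 1) for v in node.walk)
            lines.append(f'  n{ids[id(node)]} [label="{label}"];')
            for child in node.children:
                lines.append(f"  n{ids[id(node)]} -> n{ids[id(child)]};")
        lines.append("}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# leaf construction helpers


def _walk_of_path_or_cycle(
    vertices: Set[int], edges: Set[Edge]
) -> Tuple[Tuple[int, ...], bool]:
    """Order a max-degree-2 subgraph into a walk; returns (walk, closed)."""
    if not edges:
        (v,) = vertices
        return (v,), False
    adj: Dict[int, List[int]] = {v: [] for v in vertices}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    ends = sorted(v for v in vertices if len(adj[v]) == 1)
    closed = not ends
    start = min(vertices) if closed else ends[0]
    walk = [start]
    prev = None
    while True:
        nxts = [w for w in adj[walk[-1]] if w != prev]
        if not nxts:
            break
        # at the start of a cycle both neighbours are open; pick the smaller
        nxt = min(nxts)
        if closed and nxt == start:
            break
        prev = walk[-1]
        walk.append(nxt)
        if closed and len(walk) == len(vertices):
            break
    return tuple(walk), closed


def _leaf(vertices: Set[int], edges: Set[Edge]) -> SubgraphNode:
    walk, closed = _walk_of_path_or_cycle(vertices, edges)
    kind = NodeKind.CYCLE_LEAF if closed else NodeKind.PATH_LEAF
    return SubgraphNode(
        kind=kind,
        vertices=frozenset(vertices),
        edges=frozenset(edges),
        walk=walk,
        closed=closed,
    )


def _join(left: SubgraphNode, right: SubgraphNode, kind: NodeKind) -> SubgraphNode:
    return SubgraphNode(
        kind=kind,
        vertices=left.vertices | right.vertices,
        edges=left.edges | right.edges,
        children=(left, right),
    )


def _chain(nodes: Sequence[SubgraphNode], kind: NodeKind) -> SubgraphNode:
    node = nodes[0]
    for nxt in nodes[1:]:
        node = _join(node, nxt, kind)
    return node


# ---------------------------------------------------------------------------
# ear decomposition


def _tree_path(adj: Dict[int, Set[int]], u: int, v: int) -> List[int]:
    """Unique path u..v in a tree given its adjacency."""
    from collections import deque

    parent = {u: None}
    queue = deque([u])
    while queue:
        x = queue.popleft()
        if x == v:
            break
        for y in adj[x]:
            if y not in parent:
                parent[y] = x
                queue.append(y)
    path = [v]
    while path[-1] != u:
        path.append(parent[path[-1]])
    return path[::-1]


def ear_decompose(
    edges: Set[Edge], tree_edges: Set[Edge]
) -> List[Tuple[Tuple[int, ...], bool]]:
    """Ear-decompose a biconnected edge set relative to a spanning tree.

    Returns ordered ears as ``(walk, closed)``: the first ear is the
    fundamental cycle of the first non-tree edge; every later ear is a
    path whose endpoints (but not interior) lie in earlier ears.  Each
    edge belongs to exactly one ear.
    """
    tree_adj: Dict[int, Set[int]] = {}
    for i, j in tree_edges:
        tree_adj.setdefault(i, set()).add(j)
        tree_adj.setdefault(j, set()).add(i)
    nontree = sorted(edges - set(tree_edges))
    if not nontree:
        raise ValueError("input is a tree; ear decomposition needs a cycle")

    covered_v: Set[int] = set()
    covered_e: Set[Edge] = set()
    ears: List[Tuple[Tuple[int, ...], bool]] = []

    def cover(walk: Sequence[int], closed: bool):
        covered_v.update(walk)
        for a, b in zip(walk, walk[1:]):
            covered_e.add(_norm(a, b))
        if closed:
            covered_e.add(_norm(walk[-1], walk[0]))
        ears.append((tuple(walk), closed))

    # P0: fundamental cycle of the first non-tree edge
    u0, v0 = nontree[0]
    cover(_tree_path(tree_adj, u0, v0), closed=True)

    remaining = list(nontree[1:])
    while remaining:
        for idx, (u, v) in enumerate(remaining):
            cycle = _tree_path(tree_adj, u, v)  # closed by edge (v, u)
            if covered_v.intersection(cycle):
                break
        else:  # pragma: no cover - biconnectedness guarantees progress
            raise RuntimeError("ear decomposition stalled; input not biconnected?")
        remaining.pop(idx)
        m = len(cycle)
        cyc_edges = [(cycle[k], cycle[(k + 1) % m]) for k in range(m)]
        uncov = [k for k in range(m) if _norm(*cyc_edges[k]) not in covered_e]
        if not uncov:
            continue
        if len(uncov) == m:
            # whole fundamental cycle new: attach as a closed ear at a
            # covered vertex (degenerate in truly biconnected blocks)
            pivot = next(k for k in range(m) if cycle[k] in covered_v)
            walk = cycle[pivot:] + cycle[:pivot]
            cover(walk, closed=True)
            continue
        # maximal cyclic runs of uncovered edges -> one path ear per run
        runs: List[List[int]] = []
        for k in sorted(uncov):
            if runs and runs[-1][-1] == k - 1:
                runs[-1].append(k)
            else:
                runs.append([k])
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == m - 1:
            runs[0] = runs.pop() + runs[0]
        for run in runs:
            walk = [cyc_edges[run[0]][0]] + [cyc_edges[k][1] for k in run]
            cover(walk, closed=False)
    return ears


# ---------------------------------------------------------------------------
# complexity scoring


def complexity(tree: DecompositionTree) -> ComplexityReport:
    """Alpha/beta exponents for every node of a decomposition tree."""
    graph = tree.graph
    alphas: Dict[int, int] = {}
    betas: Dict[int, int] = {}
    for node in tree.root.iter_nodes():
        s = node.articulation_set(graph)
        alphas[id(node)] = len(s)
        if node.is_leaf:
            betas[id(node)] = len(s)
        else:
            union: Set[int] = set()
            for child in node.children:
                union.update(child.articulation_set(graph))
            betas[id(node)] = len(union)
    return ComplexityReport(
        alphas=alphas,
        betas=betas,
        max_alpha=max(alphas.values()),
        max_beta=max(betas.values()),
        sum_alpha=sum(alphas.values()),
        sum_beta=sum(betas.values()),
        table_weight=sum(4**a for a in alphas.values()),
    )


def _score_subtree(node: SubgraphNode, graph: DependencyGraph) -> Tuple[int, int, int]:
    max_a = max_b = weight = 0
    for nd in node.iter_nodes():
        a = len(nd.articulation_set(graph))
        if nd.is_leaf:
            b = a
        else:
            union: Set[int] = set()
            for child in nd.children:
                union.update(child.articulation_set(graph))
            b = len(union)
        max_a = max(max_a, a)
        max_b = max(max_b, b)
        weight += 4**a
    return max_a, max_b, weight


# ---------------------------------------------------------------------------
# full decomposition


def _random_spanning_tree(
    vertices: Set[int], edges: List[Edge], rng: random.Random
) -> Set[Edge]:
    shuffled = list(edges)
    rng.shuffle(shuffled)
    parent = {v: v for v in vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: Set[Edge] = set()
    for u, v in shuffled:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add(_norm(u, v))
    return tree


def _decompose_block(
    vertices: Set[int],
    edges: Set[Edge],
    graph: DependencyGraph,
    rng: random.Random,
    trials: int,
) -> SubgraphNode:
    """Decompose one biconnected block into ear leaves (or keep it whole)."""
    deg: Dict[int, int] = {v: 0 for v in vertices}
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    if max(deg.values()) <= 2:
        return _leaf(vertices, edges)

    best: Optional[SubgraphNode] = None
    best_score: Optional[Tuple[int, int, int]] = None
    edge_list = sorted(edges)
    for _ in range(max(1, trials)):
        tree_edges = _random_spanning_tree(vertices, edge_list, rng)
        ears = ear_decompose(set(edges), tree_edges)
        leaves = []
        for walk, closed in ears:
            ear_edges = {_norm(a, b) for a, b in zip(walk, walk[1:])}
            if closed:
                ear_edges.add(_norm(walk[-1], walk[0]))
            node = SubgraphNode(
                kind=NodeKind.CYCLE_LEAF if closed else NodeKind.PATH_LEAF,
                vertices=frozenset(walk),
                edges=frozenset(ear_edges),
                walk=walk,
                closed=closed,
            )
            leaves.append(node)
        candidate = _chain(leaves, NodeKind.EAR) if len(leaves) > 1 else leaves[0]
        if not candidate.is_leaf:
            candidate.kind = NodeKind.BICONNECTED_COMPONENT
        score = _score_subtree(candidate, graph)
        if best_score is None or score < best_score:
            best, best_score = candidate, score
    assert best is not None
    return best


def _order_blocks(
    blocks: List[Tuple[Set[int], Set[Edge]]]
) -> List[Tuple[Set[int], Set[Edge]]]:
    """Block-cut traversal order: BFS over blocks sharing cut vertices,
    starting from the block containing the smallest vertex."""
    n_blocks = len(blocks)
    by_vertex: Dict[int, List[int]] = {}
    for k, (vs, _) in enumerate(blocks):
        for v in vs:
            by_vertex.setdefault(v, []).append(k)
    order: List[int] = []
    seen: Set[int] = set()
    start = min(range(n_blocks), key=lambda k: min(blocks[k][0]))
    queue = [start]
    seen.add(start)
    while queue:
        k = queue.pop(0)
        order.append(k)
        neighbours = sorted(
            {j for v in blocks[k][0] for j in by_vertex[v] if j not in seen}
        )
        for j in neighbours:
            seen.add(j)
            queue.append(j)
    for k in range(n_blocks):  # safety: disconnected should not happen
        if k not in seen:
            order.append(k)
    return [blocks[k] for k in order]


def _decompose_component(
    vertices: Set[int],
    graph: DependencyGraph,
    rng: random.Random,
    trials: int,
) -> SubgraphNode:
    edges = {
        _norm(u, v) for u in vertices for v in graph.adj[u] if u < v
    }
    deg = {v: len(graph.adj[v]) for v in vertices}
    if not edges or max(deg.values()) <= 2:
        node = _leaf(vertices, edges)
        return node
    g = nx.Graph(list(edges))
    blocks = [
        (set(v for e in comp for v in e), {_norm(*e) for e in comp})
        for comp in nx.biconnected_component_edges(g)
    ]
    blocks = _order_blocks(blocks)
    block_nodes = [
        _decompose_block(vs, es, graph, rng, trials) for vs, es in blocks
    ]
    if len(block_nodes) == 1:
        node = block_nodes[0]
    else:
        node = _chain(block_nodes, NodeKind.CONNECTED_COMPONENT)
    node.kind = NodeKind.CONNECTED_COMPONENT
    return node


def decompose(
    graph: DependencyGraph, trials: int = 10, seed: int = 0
) -> DecompositionTree:
    """Build the full decomposition tree of a dependency graph.

    ``trials`` random spanning trees are attempted per complex block and
    the lowest-complexity ear decomposition kept; ``seed`` makes the
    search reproducible.  Isolated positions become singleton leaves.
    """
    rng = random.Random(seed)
    comp_nodes = [
        _decompose_component(set(comp), graph, rng, trials)
        for comp in graph.connected_components()
    ]
    root = _chain(comp_nodes, NodeKind.ROOT) if len(comp_nodes) > 1 else comp_nodes[0]
    root.kind = NodeKind.ROOT
    return DecompositionTree(root=root, components=comp_nodes, graph=graph)
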