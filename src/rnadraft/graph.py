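"""The union dependency graph.

Every position of the design is a vertex; every base pair occurring in at
least one target structure is an edge.  A sequence satisfying all
structures exists iff this union graph is bipartite (the generalized
intersection theorem), because pairing alternates letters along every
dependency path.  On top of the bipartiteness test the per-position
domains (allowed-nucleotide sets) are pre-reduced to arc consistency:
a letter survives at ``u`` only if every neighbour ``v`` still offers a
pairing partner for it.  The final feasibility authority remains the
exact solution count (0 means infeasible), but arc consistency catches
contradictions early and gives a 1-based position certificate.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

import networkx as nx

from .constraints import ALPHABET, PARTNERS, DesignSpec
from .errors import ConstraintInfeasibleError, StructureInfeasibleError


@dataclass
class DependencyGraph:
    """Union graph over sequence positions with per-vertex domains."""

    n: int
    edges: FrozenSet[Tuple[int, int]]
    domains: List[FrozenSet[str]]
    #: diagnostics: for each edge, the (0-based) indices of structures it came from
    edge_origins: Dict[Tuple[int, int], FrozenSet[int]] = field(default_factory=dict)
    #: bipartition colors (0/1 per vertex), filled by check_bipartite
    coloring: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.adj: Dict[int, Set[int]] = {v: set() for v in range(self.n)}
        for i, j in self.edges:
            self.adj[i].add(j)
            self.adj[j].add(i)

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def connected_components(self) -> List[FrozenSet[int]]:
        """Components sorted by smallest vertex (singletons included)."""
        comps = [frozenset(c) for c in nx.connected_components(self.to_networkx())]
        return sorted(comps, key=min)

    def to_dot(self) -> str:
        """DOT export: vertices labeled by 1-based position and domain."""
        lines = ["graph dependency {"]
        for v in range(self.n):
            dom = "".join(sorted(self.domains[v]))
            lines.append(f'  v{v} [label="{v + 1}:{dom}"];')
        for i, j in sorted(self.edges):
            lines.append(f"  v{i} -- v{j};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def check_bipartite(graph: DependencyGraph) -> Dict[int, int]:
    """Two-color the graph or raise with an odd-cycle certificate.

    BFS coloring; on a conflict edge (u, v) with equal colors, the cycle
    through the BFS-tree paths of u and v up to their lowest common
    ancestor has odd length and is returned (1-based) in the error.
    """
    color: Dict[int, int] = {}
    parent: Dict[int, int] = {}
    for start in range(graph.n):
        if start in color:
            continue
        color[start] = 0
        parent[start] = -1
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in graph.adj[u]:
                if v not in color:
                    color[v] = 1 - color[u]
                    parent[v] = u
                    queue.append(v)
                elif color[v] == color[u]:
                    cycle = _odd_cycle(parent, u, v)
                    raise StructureInfeasibleError(
                        "unsatisfiable structural constraints: positions "
                        f"{[p + 1 for p in cycle]} form an odd dependency cycle",
                        odd_cycle=[p + 1 for p in cycle],
                    )
    graph.coloring = color
    return color


def _odd_cycle(parent: Dict[int, int], u: int, v: int) -> List[int]:
    path_u = [u]
    while parent[path_u[-1]] != -1:
        path_u.append(parent[path_u[-1]])
    anc = set(path_u)
    path_v = [v]
    while path_v[-1] not in anc:
        path_v.append(parent[path_v[-1]])
    lca = path_v[-1]
    cycle = path_u[: path_u.index(lca) + 1] + path_v[-2::-1]
    return cycle


def reduce_domains(graph: DependencyGraph) -> DependencyGraph:
    """AC-3 style fixpoint: prune letters without a pairing partner.

    Sound: a letter is removed only when no neighbour assignment can ever
    support it, so no complete compatible assignment is lost.  Raises
    :class:`ConstraintInfeasibleError` when a domain empties.
    """
    queue = deque()
    for i, j in graph.edges:
        queue.append((i, j))
        queue.append((j, i))
    while queue:
        u, v = queue.popleft()
        dom_v = graph.domains[v]
        kept = frozenset(a for a in graph.domains[u] if PARTNERS[a] & dom_v)
        if kept != graph.domains[u]:
            if not kept:
                raise ConstraintInfeasibleError(
                    f"unsatisfiable sequence constraint: no nucleotide remains "
                    f"possible at position {u + 1}",
                    position=u + 1,
                )
            graph.domains[u] = kept
            for w in graph.adj[u]:
                if w != v:
                    queue.append((w, u))
    return graph


def build_graph(spec: DesignSpec) -> DependencyGraph:
    """Build the union dependency graph, check solvability, reduce domains.

    Duplicate pairs across structures collapse to a single edge (only the
    constraint matters, not its multiplicity); the originating structure
    indices are kept for diagnostics.
    """
    origins: Dict[Tuple[int, int], Set[int]] = {}
    for k, struct in enumerate(spec.structures):
        for pair in struct.pairs:
            origins.setdefault(pair, set()).add(k)
    graph = DependencyGraph(
        n=spec.n,
        edges=frozenset(origins),
        domains=list(spec.allowed.sets),
        edge_origins={e: frozenset(ks) for e, ks in origins.items()},
    )
    check_bipartite(graph)
    reduce_domains(graph)
    return graph
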