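"""Uniform sampling of compatible sequences by stochastic backtracking.

The forward counting pass leaves every decomposition-tree node with an
exact memorization table.  Sampling runs the tree in the opposite
direction: an integer rank drawn uniformly from ``[0, |C|)`` is pushed
top-down through the tree, at each node split over the articulation-letter
choices in proportion to their exact counts, and finally unfolded along
path/cycle leaves by a transfer-matrix descent.  Because every split uses
exact integer arithmetic, the rank -> sequence map is a bijection between
``[0, |C|)`` and the solution space, so every compatible sequence has
probability exactly ``1/|C|``.

Move set on top of global sampling:

* C-local — redraw one whole connected component (selection weighted by
  component solution counts by default);
* P-local — redraw the non-articulation interior of one decomposition
  leaf, conditioned on the current articulation letters;
* position — P-local or C-local move covering a requested position;
* biased — the experimental comparator: identical traversal, but every
  articulation-letter decision is made uniformly over the non-zero
  choices instead of count-proportionally (leaf fill-in stays
  count-proportional).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

from .constraints import DesignSpec
from .counting import _CANONICAL, _PARTNER_LETTERS, count_solutions
from .decompose import DecompositionTree, SubgraphNode, decompose
from .errors import ConstraintInfeasibleError, DesignError
from .graph import DependencyGraph, build_graph


@dataclass
class SamplerModel:
    """Everything the backward pass needs: graph, tree, tables, |C|."""

    spec: DesignSpec
    graph: DependencyGraph
    tree: DecompositionTree
    total: int

    @property
    def components(self) -> List[SubgraphNode]:
        return self.tree.components

    def component_count(self, node: SubgraphNode) -> int:
        return node.table.get(())

    def component_of(self, vertex: int) -> SubgraphNode:
        for node in self.tree.components:
            if vertex in node.vertices:
                return node
        raise ValueError(f"vertex {vertex} not in any component")

    def leaf_of(self, vertex: int) -> Optional[SubgraphNode]:
        """The leaf holding ``vertex`` as a non-articulation (interior)
        vertex, or None if the vertex is an articulation point."""
        for leaf in self.tree.leaves:
            if vertex in leaf.vertices and vertex not in leaf.table.dims:
                return leaf
        return None


def build_model(spec: DesignSpec, trials: int = 10, seed: int = 0) -> SamplerModel:
    """Build graph, decomposition and tables; error if |C| = 0."""
    graph = build_graph(spec)
    tree = decompose(graph, trials=trials, seed=seed)
    total = count_solutions(tree)
    if total == 0:
        raise ConstraintInfeasibleError(
            "infeasible design: the solution space is empty"
        )
    return SamplerModel(spec=spec, graph=graph, tree=tree, total=total)


@dataclass
class SequenceState:
    """Current assignment plus the history of accepted sequences/moves."""

    assignment: List[str]
    history: List[Tuple[str, str]] = field(default_factory=list)
    max_history: Optional[int] = None

    @property
    def sequence(self) -> str:
        return "".join(self.assignment)

    def record(self, move: str):
        self.history.append((self.sequence, move))
        if self.max_history is not None and len(self.history) > self.max_history:
            del self.history[0]  # oldest-first eviction

    def revert(self, steps: int) -> str:
        """Restore the sequence accepted ``steps`` moves ago.

        The history includes the current sequence as its last entry, so
        ``revert(1)`` after one move restores the previous sequence.
        """
        if steps < 0 or steps > len(self.history) - 1:
            raise DesignError(
                f"cannot revert {steps} steps: history depth is "
                f"{max(0, len(self.history) - 1)}"
            )
        if steps == 0:
            return self.sequence
        seq, _ = self.history[-steps - 1]
        self.assignment = list(seq)
        self.record(f"revert:{steps}")
        return self.sequence


# ---------------------------------------------------------------------------
# rank descent


def _canon(domain: FrozenSet[str]) -> List[str]:
    return sorted(domain, key=_CANONICAL.index)


def _path_total(masks: List[Sequence[str]]) -> int:
    """Exact count of pairing-compatible letter choices along masked slots."""
    state = {a: 1 for a in masks[0]}
    for mask in masks[1:]:
        nxt = {b: 0 for b in mask}
        for a, cnt in state.items():
            for b in _PARTNER_LETTERS[a]:
                if b in nxt:
                    nxt[b] += cnt
        state = nxt
    return sum(state.values())


def _descend_path(
    walk: Sequence[int],
    masks: List[Sequence[str]],
    rank: int,
    out: Dict[int, str],
) -> None:
    """Deterministically unfold ``rank`` into letters along a path.

    ``masks[i]`` is the canonical-ordered list of letters allowed at
    ``walk[i]``; adjacent letters must pair.
    """
    n = len(walk)
    # suffix counts: completions of walk[i:] starting with a given letter
    suffix: List[Dict[str, int]] = [dict() for _ in range(n)]
    for a in masks[-1]:
        suffix[-1][a] = 1
    for i in range(n - 2, -1, -1):
        for a in masks[i]:
            suffix[i][a] = sum(
                suffix[i + 1].get(b, 0) for b in _PARTNER_LETTERS[a]
            )
    prev: Optional[str] = None
    for i, v in enumerate(walk):
        options = [
            a
            for a in masks[i]
            if suffix[i].get(a, 0) > 0 and (prev is None or a in _PARTNER_LETTERS[prev])
        ]
        for a in options:
            w = suffix[i][a]
            if rank < w:
                out[v] = a
                prev = a
                break
            rank -= w
        else:  # pragma: no cover - rank always within total by construction
            raise RuntimeError("rank descent overran path counts")


def _descend_leaf(
    leaf: SubgraphNode,
    graph: DependencyGraph,
    fixed: Dict[int, str],
    rank: int,
    out: Dict[int, str],
) -> None:
    walk = list(leaf.walk)
    masks = [
        [fixed[v]] if v in fixed else _canon(graph.domains[v]) for v in walk
    ]
    if not leaf.closed:
        _descend_path(walk, masks, rank, out)
        return
    # cycle: rotate so a fixed vertex (if any) leads, choose its letter,
    # then descend the remainder as a path with both-end pairing masks
    pivot = next((k for k, v in enumerate(walk) if v in fixed), 0)
    walk = walk[pivot:] + walk[:pivot]
    masks = masks[pivot:] + masks[:pivot]
    for a in masks[0]:
        rest = (
            [[b for b in masks[1] if b in _PARTNER_LETTERS[a]]]
            + [list(m) for m in masks[2:-1]]
            + [[b for b in masks[-1] if b in _PARTNER_LETTERS[a]]]
        )
        if any(not m for m in rest):
            continue
        w = _path_total(rest)
        if rank < w:
            out[walk[0]] = a
            _descend_path(walk[1:], rest, rank, out)
            return
        rank -= w
    raise RuntimeError("rank descent overran cycle counts")  # pragma: no cover


def _descend_node(
    model: SamplerModel,
    node: SubgraphNode,
    fixed: Dict[int, str],
    rank: int,
    out: Dict[int, str],
    rng: Optional[random.Random] = None,
    biased: bool = False,
) -> None:
    """Unfold a rank into letters for every vertex of ``node``.

    ``fixed`` must assign all dimensions of ``node.table``.  In biased
    mode, articulation-letter choices are uniform over non-zero options
    and fresh sub-ranks are drawn from ``rng``.
    """
    graph = model.graph
    if node.is_leaf:
        _descend_leaf(node, graph, fixed, rank, out)
        for v in node.table.dims:
            out.setdefault(v, fixed[v])
        return
    left, right = node.children
    reduced = node.reduced
    choice_sets = [_canon(graph.domains[v]) for v in reduced]
    options: List[Tuple[Dict[int, str], int, int]] = []
    for combo in product(*choice_sets):
        assign = dict(fixed)
        assign.update(zip(reduced, combo))
        wl = left.table.get(tuple(assign[v] for v in left.table.dims))
        wr = right.table.get(tuple(assign[v] for v in right.table.dims))
        if wl and wr:
            options.append((assign, wl, wr))
    if biased:
        assign, wl, wr = options[rng.randrange(len(options))]
        rl, rr = rng.randrange(wl), rng.randrange(wr)
    else:
        for assign, wl, wr in options:
            w = wl * wr
            if rank < w:
                rl, rr = divmod(rank, wr)
                break
            rank -= w
        else:  # pragma: no cover
            raise RuntimeError("rank descent overran node counts")
    out.update(assign)
    _descend_node(model, left, {v: assign[v] for v in left.table.dims}, rl, out, rng, biased)
    _descend_node(model, right, {v: assign[v] for v in right.table.dims}, rr, out, rng, biased)


def rank_to_sequence(model: SamplerModel, rank: int) -> str:
    """The deterministic bijection ``[0, |C|) -> solution space``."""
    if not 0 <= rank < model.total:
        raise ValueError(f"rank {rank} outside [0, {model.total})")
    out: Dict[int, str] = {}
    _descend_node(model, model.tree.root, {}, rank, out)
    return "".join(out[i] for i in range(model.spec.n))


# ---------------------------------------------------------------------------
# public sampling operations


def _weighted_choice(weights: Sequence[int], rng: random.Random) -> int:
    total = sum(weights)
    r = rng.randrange(total)
    for k, w in enumerate(weights):
        if r < w:
            return k
        r -= w
    raise RuntimeError("unreachable")  # pragma: no cover


def sample_global(
    model: SamplerModel, rng: random.Random, state: Optional[SequenceState] = None
) -> str:
    """Draw a completely new sequence, uniformly over the solution space."""
    seq = rank_to_sequence(model, rng.randrange(model.total))
    if state is not None:
        state.assignment = list(seq)
        state.record("global")
    return seq


def sample_biased(
    model: SamplerModel, rng: random.Random, state: Optional[SequenceState] = None
) -> str:
    """The biased comparator: uniform articulation decisions.

    Articulation-letter combinations are drawn with equal probability
    regardless of how many solutions hang off them; only the path
    fill-in stays count-proportional.  For experiments only.
    """
    out: Dict[int, str] = {}
    _descend_node(model, model.tree.root, {}, 0, out, rng=rng, biased=True)
    seq = "".join(out[i] for i in range(model.spec.n))
    if state is not None:
        state.assignment = list(seq)
        state.record("biased")
    return seq


def _eligible(
    nodes: Sequence[SubgraphNode],
    min_size: Optional[int],
    max_size: Optional[int],
) -> List[SubgraphNode]:
    out = []
    for node in nodes:
        size = len(node.vertices)
        if min_size is not None and size < min_size:
            continue
        if max_size is not None and size > max_size:
            continue
        out.append(node)
    return out


def sample_clocal(
    model: SamplerModel,
    state: SequenceState,
    rng: random.Random,
    component: Optional[int] = None,
    min_size: Optional[int] = None,
    max_size: Optional[int] = None,
    weighted: bool = True,
) -> str:
    """Redraw one connected component, all other positions untouched.

    By default the component is picked with probability proportional to
    its solution count; ``weighted=False`` picks uniformly, ``component``
    (index into ``model.components``) selects explicitly.
    """
    if component is not None:
        node = model.components[component]
    else:
        eligible = _eligible(model.components, min_size, max_size)
        if not eligible:
            raise DesignError("no connected component within the size bounds")
        if weighted:
            counts = [model.component_count(n) for n in eligible]
            node = eligible[_weighted_choice(counts, rng)]
        else:
            node = eligible[rng.randrange(len(eligible))]
    out: Dict[int, str] = {}
    _descend_node(model, node, {}, rng.randrange(model.component_count(node)), out)
    for v, letter in out.items():
        state.assignment[v] = letter
    state.record(f"clocal:{min(node.vertices) + 1}")
    return state.sequence


def sample_plocal(
    model: SamplerModel,
    state: SequenceState,
    rng: random.Random,
    leaf: Optional[int] = None,
    min_size: Optional[int] = None,
    max_size: Optional[int] = None,
) -> str:
    """Redraw the non-articulation interior of one decomposition leaf.

    Articulation letters of the current sequence are kept fixed and the
    interior is redrawn uniformly over completions consistent with them.
    """
    leaves = model.tree.leaves
    if leaf is not None:
        node = leaves[leaf]
    else:
        eligible = _eligible(leaves, min_size, max_size)
        if not eligible:
            raise DesignError("no decomposition leaf within the size bounds")
        node = eligible[rng.randrange(len(eligible))]
    fixed = {v: state.assignment[v] for v in node.table.dims}
    entry = node.table.get(tuple(fixed[v] for v in node.table.dims))
    out: Dict[int, str] = {}
    _descend_leaf(node, model.graph, fixed, rng.randrange(entry), out)
    for v, letter in out.items():
        state.assignment[v] = letter
    state.record(f"plocal:{min(node.vertices) + 1}")
    return state.sequence


def sample_position(
    model: SamplerModel,
    state: SequenceState,
    rng: random.Random,
    position: Union[int, Tuple[int, int]],
) -> str:
    """Resample the move(s) covering a 1-based position or inclusive range.

    A non-articulation position triggers a P-local move on its leaf; an
    articulation position a C-local move on its component.  For a range,
    a minimal set of such moves covering every position is applied.
    """
    if isinstance(position, int):
        positions = [position]
    else:
        lo, hi = position
        positions = list(range(lo, hi + 1))
    for p in positions:
        if not 1 <= p <= model.spec.n:
            raise DesignError(f"position {p} outside [1, {model.spec.n}]")
    covered: set = set()
    for p in positions:
        v = p - 1
        if v in covered:
            continue
        leaf = model.leaf_of(v)
        if leaf is not None:
            idx = model.tree.leaves.index(leaf)
            sample_plocal(model, state, rng, leaf=idx)
            covered.update(set(leaf.vertices) - set(leaf.table.dims))
        else:
            node = model.component_of(v)
            idx = model.components.index(node)
            sample_clocal(model, state, rng, component=idx)
            covered.update(node.vertices)
    return state.sequence


def revert(state: SequenceState, steps: int) -> str:
    """Restore the sequence from ``steps`` history entries back."""
    return state.revert(steps)


class DesignSampler:
    """Stateful convenience wrapper: model + state + one RNG stream."""

    def __init__(
        self,
        spec: DesignSpec,
        seed: Optional[int] = None,
        trials: int = 10,
        tree_seed: int = 0,
    ):
        self.model = build_model(spec, trials=trials, seed=tree_seed)
        self.rng = random.Random(seed)
        self.seed = seed
        first = sample_global(self.model, self.rng)
        self.state = SequenceState(assignment=list(first))
        self.state.record("global")

    @property
    def count(self) -> int:
        return self.model.total

    @property
    def sequence(self) -> str:
        return self.state.sequence

    def set_sequence(self, sequence: str):
        if not self.model.spec.is_compatible(sequence):
            raise DesignError("sequence is not compatible with the design")
        self.state.assignment = list(sequence)

    def sample(self) -> str:
        return sample_global(self.model, self.rng, self.state)

    def sample_biased(self) -> str:
        return sample_biased(self.model, self.rng, self.state)

    def sample_clocal(self, **kwargs) -> str:
        return sample_clocal(self.model, self.state, self.rng, **kwargs)

    def sample_plocal(self, **kwargs) -> str:
        return sample_plocal(self.model, self.state, self.rng, **kwargs)

    def sample_position(self, position) -> str:
        return sample_position(self.model, self.state, self.rng, position)

    def revert(self, steps: int) -> str:
        return self.state.revert(steps)
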