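"""Independent brute-force oracle and random fixture generation.

The oracle checks every constraint directly — positions are assigned one
by one and every base pair is tested against the allowed-pair rule as
soon as both partners are set.  It shares no code with the decomposition
or dynamic-programming machinery, so agreement between the two is a
meaningful cross-check.  The only structural shortcut is elementary:
positions in different connected components (union-find over the pairs)
are independent, so their counts multiply.

``random_design`` produces valid random design problems for tests: the
structures are grown pair by pair under a union-graph bipartiteness
check, and sequence constraints are sprinkled so that at least one known
compatible sequence survives — generated fixtures are always solvable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .constraints import (
    ALPHABET,
    IUPAC_TABLE,
    MIN_SEPARATION,
    AllowedSets,
    DesignSpec,
    PairSet,
    write_design,
)

_PAIR_OK = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
}

ENUMERATION_CAP = 10**7


def _union_edges(spec: DesignSpec) -> Set[Tuple[int, int]]:
    return {pair for s in spec.structures for pair in s.pairs}


def _components(n: int, edges: Set[Tuple[int, int]]) -> List[List[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for v in range(n):
        groups.setdefault(find(v), []).append(v)
    return sorted(groups.values(), key=lambda g: g[0])


def _component_solutions(
    vertices: Sequence[int],
    edges: Set[Tuple[int, int]],
    domains: Sequence[FrozenSet[str]],
    collect: bool,
) -> Tuple[int, List[Dict[int, str]]]:
    """Backtrack over one component; returns (count, assignments?)."""
    order = list(vertices)
    index = {v: k for k, v in enumerate(order)}
    # for each position in order, edges to already-assigned positions
    back_edges: List[List[int]] = [[] for _ in order]
    for i, j in edges:
        a, b = index[i], index[j]
        if a > b:
            a, b = b, a
        back_edges[b].append(a)
    count = 0
    found: List[Dict[int, str]] = []
    assign: List[Optional[str]] = [None] * len(order)

    def rec(k: int):
        nonlocal count
        if k == len(order):
            count += 1
            if collect:
                found.append({v: assign[index[v]] for v in order})
            return
        for letter in sorted(domains[order[k]]):
            ok = True
            for a in back_edges[k]:
                if (assign[a], letter) not in _PAIR_OK:
                    ok = False
                    break
            if ok:
                assign[k] = letter
                rec(k + 1)
        assign[k] = None

    rec(0)
    return count, found


def count_solutions_oracle(spec: DesignSpec) -> int:
    """Exact |C| by direct constraint checking (product over components)."""
    edges = _union_edges(spec)
    total = 1
    for comp in _components(spec.n, edges):
        comp_set = set(comp)
        comp_edges = {e for e in edges if e[0] in comp_set}
        cnt, _ = _component_solutions(comp, comp_edges, spec.allowed.sets, False)
        total *= cnt
    return total


def enumerate_solutions(spec: DesignSpec, cap: int = ENUMERATION_CAP) -> List[str]:
    """All compatible sequences, lexicographically sorted.

    Refuses when the search space (product of per-position domain sizes)
    exceeds ``cap``.
    """
    space = 1
    for s in spec.allowed.sets:
        space *= len(s)
        if space > cap:
            raise ValueError(
                f"enumeration refused: domain product exceeds cap {cap:g}"
            )
    edges = _union_edges(spec)
    per_comp: List[List[Dict[int, str]]] = []
    for comp in _components(spec.n, edges):
        comp_set = set(comp)
        comp_edges = {e for e in edges if e[0] in comp_set}
        _, found = _component_solutions(comp, comp_edges, spec.allowed.sets, True)
        per_comp.append(found)
    sequences = []
    for combo in product(*per_comp):
        letters = {}
        for part in combo:
            letters.update(part)
        sequences.append("".join(letters[i] for i in range(spec.n)))
    return sorted(sequences)


@dataclass
class Fixture:
    """A generated design problem with provenance."""

    spec: DesignSpec
    params: Dict[str, object]
    seed: int
    _enumeration: Optional[List[str]] = field(default=None, repr=False)

    def enumeration(self, cap: int = ENUMERATION_CAP) -> List[str]:
        if self._enumeration is None:
            self._enumeration = enumerate_solutions(self.spec, cap=cap)
        return self._enumeration

    def to_files(self, design_path, sidecar_path=None):
        """Write the design file plus a JSON sidecar with provenance."""
        with open(design_path, "w", encoding="utf-8") as fh:
            fh.write(write_design(self.spec))
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump({"seed": self.seed, "params": self.params}, fh, indent=1)


def _is_bipartite(n: int, edges: Set[Tuple[int, int]]) -> bool:
    color: Dict[int, int] = {}
    adj: Dict[int, List[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for start in adj:
        if start in color:
            continue
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in color:
                    color[v] = 1 - color[u]
                    stack.append(v)
                elif color[v] == color[u]:
                    return False
    return True


# IUPAC codes that genuinely constrain (fewer than four letters)
_CONSTRAINING_CODES = [
    c for c, letters in IUPAC_TABLE.items() if c != "T" and len(letters) < 4
]


def random_design(
    n: int,
    m: int,
    constraint_density: float = 0.0,
    seed: int = 0,
    pairs_per_structure: Optional[int] = None,
) -> Fixture:
    """Generate a random, always-solvable design problem.

    Each of the ``m`` structures receives about ``n // 4 + 1`` random
    pairs (minimum separation respected, union kept bipartite by
    rejection).  Sequence constraints are IUPAC codes sprinkled at
    ``constraint_density``, each chosen to contain the letter of a known
    compatible sequence so the fixture stays solvable by construction.
    """
    if n < 5 or m < 1:
        raise ValueError("need n >= 5 and m >= 1")
    rng = random.Random(seed)
    target_pairs = pairs_per_structure or (n // 4 + 1)
    union: Set[Tuple[int, int]] = set()
    structures: List[PairSet] = []
    for _ in range(m):
        pairs: Set[Tuple[int, int]] = set()
        used: Set[int] = set()
        attempts = 0
        while len(pairs) < target_pairs and attempts < 200:
            attempts += 1
            i = rng.randrange(n - MIN_SEPARATION)
            j = rng.randrange(i + MIN_SEPARATION, n)
            if i in used or j in used:
                continue
            if _is_bipartite(n, union | pairs | {(i, j)}):
                pairs.add((i, j))
                used.update((i, j))
        union |= pairs
        structures.append(PairSet(n=n, pairs=frozenset(pairs)))

    # one concrete compatible sequence (2-color the union graph)
    witness = _witness_sequence(n, union, rng)
    sets: List[FrozenSet[str]] = []
    for v in range(n):
        if rng.random() < constraint_density:
            letter = witness[v]
            code = rng.choice(
                [c for c in _CONSTRAINING_CODES if letter in IUPAC_TABLE[c]]
            )
            sets.append(frozenset(IUPAC_TABLE[code]))
        else:
            sets.append(frozenset(ALPHABET))
    spec = DesignSpec(
        structures=tuple(structures), allowed=AllowedSets(tuple(sets))
    )
    return Fixture(
        spec=spec,
        params={
            "n": n,
            "m": m,
            "constraint_density": constraint_density,
            "pairs_per_structure": target_pairs,
        },
        seed=seed,
    )


def _witness_sequence(
    n: int, edges: Set[Tuple[int, int]], rng: random.Random
) -> str:
    """A sequence compatible with the union pairs: two-color each
    component and map the sides to a random allowed base pair (every
    edge joins opposite sides, so any of the six pairs works)."""
    letters: Dict[int, str] = {}
    adj: Dict[int, List[int]] = {v: [] for v in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    pair_choices = list(sorted(_PAIR_OK))
    for start in range(n):
        if start in letters:
            continue
        if not adj[start]:
            letters[start] = rng.choice(ALPHABET)
            continue
        a, b = rng.choice(pair_choices)
        letters[start] = a
        stack = [start]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in letters:
                    letters[w] = b if letters[u] == a else a
                    stack.append(w)
    return "".join(letters[v] for v in range(n))


def uniformity_test(samples: Sequence[str], enumeration: Sequence[str]) -> float:
    """Chi-square goodness of fit of samples against the uniform law.

    Every sampled sequence must be a member of the enumeration; a
    foreign sequence is a correctness failure and raises immediately.
    Returns the p-value (cells = solutions, no binning).
    """
    universe = {seq: k for k, seq in enumerate(enumeration)}
    observed = np.zeros(len(enumeration))
    for seq in samples:
        if seq not in universe:
            raise AssertionError(
                f"sampled sequence {seq!r} is not a solution of the design"
            )
        observed[universe[seq]] += 1
    result = stats.chisquare(observed)
    return float(result.pvalue)
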