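"""Parsing and validation of structural and sequence constraints.

A design problem consists of M equal-length secondary structures in
dot-bracket notation (pseudoknots expressed through additional bracket
families) and an optional IUPAC string restricting the nucleotides allowed
at each position.  This module turns those text inputs into validated
in-memory objects (:class:`PairSet`, :class:`AllowedSets`,
:class:`DesignSpec`) and writes them back out.

Positions are 0-based internally; every user-facing message is 1-based.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .errors import ParseError

#: The RNA alphabet, in the order used by the pairing matrix (A–U–G–C is the
#: path along which canonical and wobble pairs form).
ALPHABET: Tuple[str, ...] = ("A", "U", "G", "C")

#: Allowed (ordered) base pairs: Watson-Crick plus the GU wobble pair.
PAIR_RULE: FrozenSet[Tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: For each nucleotide, the set of pairing partners under ``PAIR_RULE``.
PARTNERS = {
    "A": frozenset("U"),
    "U": frozenset("AG"),
    "G": frozenset("CU"),
    "C": frozenset("G"),
}

#: Minimal pair separation: partners must be separated by >= 3 bases,
#: i.e. j - i >= 4 (hairpin loops need at least three unpaired bases).
MIN_SEPARATION = 4

IUPAC_TABLE = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

# Bracket families: classic four plus letter pairs (uppercase opens,
# matching lowercase closes) for deeply pseudoknotted input.
_BRACKET_FAMILIES = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (u, u.lower()) for u in string.ascii_uppercase
]
_OPEN_TO_FAMILY = {o: (o, c) for o, c in _BRACKET_FAMILIES}
_CLOSE_TO_FAMILY = {c: (o, c) for o, c in _BRACKET_FAMILIES}


@dataclass(frozen=True)
class PairSet:
    """A secondary structure: a set of base pairs on ``n`` positions.

    Each position occurs in at most one pair; pairs may cross (pseudoknots).
    """

    n: int
    pairs: FrozenSet[Tuple[int, int]]

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i + 1},{j + 1}) out of range for n={self.n}")
            if i in seen or j in seen:
                raise ValueError(f"position {i + 1 if i in seen else j + 1} paired twice")
            seen.add(i)
            seen.add(j)

    @property
    def paired_positions(self) -> FrozenSet[int]:
        return frozenset(p for pair in self.pairs for p in pair)


@dataclass(frozen=True)
class AllowedSets:
    """Per-position allowed-nucleotide sets (one non-empty subset of AUGC
    per position)."""

    sets: Tuple[FrozenSet[str], ...]

    def __post_init__(self):
        for i, s in enumerate(self.sets):
            if not s or not s <= set(ALPHABET):
                raise ValueError(f"invalid allowed set at position {i + 1}: {set(s)}")

    @property
    def n(self) -> int:
        return len(self.sets)

    @classmethod
    def unconstrained(cls, n: int) -> "AllowedSets":
        return cls(tuple(frozenset(ALPHABET) for _ in range(n)))


@dataclass(frozen=True)
class DesignSpec:
    """A complete design problem: M structures + sequence constraints."""

    structures: Tuple[PairSet, ...]
    allowed: AllowedSets
    pair_rule: FrozenSet[Tuple[str, str]] = PAIR_RULE

    def __post_init__(self):
        if len(self.structures) < 1:
            raise ValueError("a design needs at least one structure")
        n = self.structures[0].n
        for k, s in enumerate(self.structures):
            if s.n != n:
                raise ValueError(f"structure {k + 1} has length {s.n}, expected {n}")
        if self.allowed.n != n:
            raise ValueError(
                f"sequence constraint has length {self.allowed.n}, expected {n}"
            )

    @property
    def n(self) -> int:
        return self.structures[0].n

    @property
    def m(self) -> int:
        return len(self.structures)

    def is_compatible(self, sequence: str) -> bool:
        """Check a sequence against every structure and the IUPAC constraint."""
        if len(sequence) != self.n:
            return False
        for i, letter in enumerate(sequence):
            if letter not in self.allowed.sets[i]:
                return False
        for struct in self.structures:
            for i, j in struct.pairs:
                if (sequence[i], sequence[j]) not in self.pair_rule:
                    return False
        return True


def parse_structure(line: str, check_separation: bool = True) -> PairSet:
    """Parse a dot-bracket line into a :class:`PairSet`.

    Supports the families ``()``, ``[]``, ``{}``, ``<>`` and letter pairs
    (``A`` opens, ``a`` closes) so arbitrarily crossing pseudoknots can be
    written.  With ``check_separation`` (default) pairs closer than
    ``MIN_SEPARATION`` positions are rejected.
    """
    stacks: dict = {}
    pairs = set()
    for pos, ch in enumerate(line):
        if ch == ".":
            continue
        if ch in _OPEN_TO_FAMILY:
            stacks.setdefault(_OPEN_TO_FAMILY[ch], []).append(pos)
        elif ch in _CLOSE_TO_FAMILY:
            fam = _CLOSE_TO_FAMILY[ch]
            stack = stacks.get(fam, [])
            if not stack:
                raise ParseError(
                    f"unbalanced '{ch}' of family '{fam[0]}{fam[1]}' at position {pos + 1}",
                    position=pos + 1,
                )
            i = stack.pop()
            if check_separation and pos - i < MIN_SEPARATION:
                raise ParseError(
                    f"pair ({i + 1},{pos + 1}) violates minimal separation: "
                    f"partners must be separated by at least three bases",
                    position=pos + 1,
                )
            pairs.add((i, pos))
        else:
            raise ParseError(
                f"unsupported character {ch!r} at position {pos + 1}", position=pos + 1
            )
    for (o, c), stack in stacks.items():
        if stack:
            raise ParseError(
                f"unbalanced '{o}' of family '{o}{c}' at position {stack[-1] + 1}",
                position=stack[-1] + 1,
            )
    return PairSet(n=len(line), pairs=frozenset(pairs))


def write_structure(pair_set: PairSet) -> str:
    """Render a :class:`PairSet` as dot-bracket text.

    Crossing pairs are distributed greedily over bracket families so that
    each family holds a nested (non-crossing) subset.
    """
    chars = ["."] * pair_set.n
    family_pairs: List[List[Tuple[int, int]]] = []
    for i, j in sorted(pair_set.pairs):
        for k, assigned in enumerate(family_pairs):
            if not any(a < i < b < j or i < a < j < b for a, b in assigned):
                assigned.append((i, j))
                break
        else:
            family_pairs.append([(i, j)])
            k = len(family_pairs) - 1
        if k >= len(_BRACKET_FAMILIES):
            raise ValueError("pair set needs more bracket families than supported")
        o, c = _BRACKET_FAMILIES[k]
        chars[i], chars[j] = o, c
    return "".join(chars)


def parse_iupac(line: str) -> AllowedSets:
    """Parse an IUPAC nucleotide-code string into per-position allowed sets.

    ``T`` is silently treated as ``U`` so DNA-flavoured input works.
    """
    sets = []
    for pos, ch in enumerate(line):
        code = IUPAC_TABLE.get(ch.upper())
        if code is None:
            raise ParseError(
                f"unknown IUPAC code {ch!r} at position {pos + 1}", position=pos + 1
            )
        sets.append(frozenset(code))
    return AllowedSets(tuple(sets))


def write_iupac(allowed: AllowedSets) -> str:
    """Render allowed sets back to the shortest IUPAC code per position."""
    by_set = {frozenset(v): k for k, v in IUPAC_TABLE.items() if k != "T"}
    return "".join(by_set[s] for s in allowed.sets)


def _looks_like_iupac(line: str) -> bool:
    # A letters-only uppercase line is read as the sequence constraint;
    # anything containing dots or brackets is a structure.
    return bool(line) and all(c in IUPAC_TABLE for c in line)


def load_design(source, check_separation: bool = True) -> DesignSpec:
    """Load a design file: one dot-bracket structure per line, at most one
    IUPAC constraint line, ``#`` comment lines ignored.

    ``source`` may be a path, an open file, a multi-line string, or an
    iterable of lines.  A missing constraint line means all positions are
    unconstrained (all-N).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    elif isinstance(source, (list, tuple)):
        lines = list(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    structures: List[PairSet] = []
    constraint: Optional[AllowedSets] = None
    lengths: List[Tuple[int, int]] = []  # (line number, length)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if _looks_like_iupac(line):
            if constraint is not None:
                raise ParseError(
                    f"second sequence-constraint line at line {lineno}; only one allowed"
                )
            constraint = parse_iupac(line)
            lengths.append((lineno, len(line)))
        else:
            structures.append(parse_structure(line, check_separation=check_separation))
            lengths.append((lineno, len(line)))

    if not structures:
        raise ParseError("design file contains no structures")
    ref_lineno, ref_len = lengths[0]
    for lineno, length in lengths[1:]:
        if length != ref_len:
            raise ParseError(
                f"length mismatch: line {ref_lineno} has length {ref_len} "
                f"but line {lineno} has length {length}"
            )
    if constraint is None:
        constraint = AllowedSets.unconstrained(ref_len)
    return DesignSpec(structures=tuple(structures), allowed=constraint)


def write_design(spec: DesignSpec) -> str:
    """Serialize a :class:`DesignSpec` to design-file text."""
    lines = [write_structure(s) for s in spec.structures]
    iupac = write_iupac(spec.allowed)
    if set(iupac) != {"N"}:
        lines.append(iupac)
    return "\n".join(lines) + "\n"


def write_fasta(records: Iterable[Tuple[str, str]]) -> str:
    """Format ``(header, sequence)`` records as FASTA text."""
    out = []
    for header, seq in records:
        out.append(f">{header}")
        out.append(seq)
    return "\n".join(out) + "\n"
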