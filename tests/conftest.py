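"""Shared fixtures: small design problems with known solution spaces.

All fixtures are generated programmatically; "pinned" variants fix the
positions outside the interesting component to 'A' so the solution space
is exactly the component's and stays small enough to enumerate.
"""

import pytest

from rnadraft import DesignSpec, PairSet, load_design
from rnadraft.constraints import parse_iupac


def spec_from_pairs(n, *pairsets, iupac=None):
    if not pairsets:
        pairsets = (set(),)  # a single all-unpaired structure
    structures = tuple(PairSet(n=n, pairs=frozenset(p)) for p in pairsets)
    allowed = parse_iupac(iupac) if iupac else parse_iupac("N" * n)
    return DesignSpec(structures=structures, allowed=allowed)


def pinned_spec(n, keep, *pairsets):
    """Pairs as given; every position outside ``keep`` pinned to A."""
    iupac = "".join("N" if i in keep else "A" for i in range(n))
    return spec_from_pairs(n, *pairsets, iupac=iupac)


@pytest.fixture
def two_structure_spec():
    """The hairpin-pair design '((...))' + '(.....)': |C| = 2304."""
    return load_design(["((...))", "(.....)"])


@pytest.fixture
def constrained_spec():
    """Same, with the last position fixed to A: |C| = 384."""
    return load_design(["((...))", "(.....)", "NNNNNNA"])


@pytest.fixture
def star_spec():
    """Hub position paired three different ways (star graph); isolated
    positions pinned so |C| = 18."""
    return pinned_spec(13, {0, 4, 8, 12}, {(0, 4)}, {(0, 8)}, {(0, 12)})


@pytest.fixture
def cycle4_spec():
    """A 4-cycle of dependencies; isolated positions pinned: |C| = 14."""
    return pinned_spec(13, {0, 4, 8, 12}, {(0, 4), (8, 12)}, {(4, 8), (0, 12)})


@pytest.fixture
def theta_spec():
    """Theta graph (two hubs joined by three 2-edge paths, a K2,3);
    isolated positions pinned: |C| = 22."""
    return pinned_spec(
        17,
        {0, 4, 8, 12, 16},
        {(0, 4), (8, 12)},
        {(4, 8), (0, 12)},
        {(0, 16)},
        {(8, 16)},
    )


@pytest.fixture
def triangle_pairsets():
    """Three structures whose union is an odd (3-)cycle: unsolvable."""
    return (9, ({(0, 4)}, {(4, 8)}, {(0, 8)}))
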