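"""Exception taxonomy shared across the package.

All user-facing positions in error messages are 1-based.
"""


class DesignError(Exception):
    """Base class for all errors raised by rnadraft."""


class ParseError(DesignError):
    """Malformed structure, constraint or design-file input.

    Attributes
    ----------
    position : int or None
        1-based position of the offending character, when known.
    """

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position


class StructureInfeasibleError(DesignError):
    """The union dependency graph is not bipartite: no sequence can satisfy
    all structural constraints simultaneously.

    Attributes
    ----------
    odd_cycle : list[int]
        1-based positions forming an odd cycle certificate.
    """

    def __init__(self, message, odd_cycle=None):
        super().__init__(message)
        self.odd_cycle = list(odd_cycle) if odd_cycle is not None else []


class ConstraintInfeasibleError(DesignError):
    """Sequence constraints contradict the base-pairing pattern: some
    position's allowed-nucleotide set became empty.

    Attributes
    ----------
    position : int
        1-based position whose domain was emptied.
    """

    def __init__(self, message, position=None):
        super().__init__(message)
        self.position = position
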