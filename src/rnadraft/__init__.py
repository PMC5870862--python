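"""rnadraft — multi-target nucleic acid sequence design.

Exact counting and provably uniform sampling of sequences compatible
with multiple secondary-structure constraints (pseudoknots included) and
IUPAC sequence constraints, via dependency-graph decomposition and
dynamic programming, plus local/global resampling moves and an
adaptive-walk optimizer.
"""

from .constraints import (
    ALPHABET,
    PAIR_RULE,
    AllowedSets,
    DesignSpec,
    PairSet,
    load_design,
    parse_iupac,
    parse_structure,
    write_design,
    write_fasta,
    write_structure,
)
from .counting import (
    MemoTable,
    PAIRING_MATRIX,
    concatenate,
    count_solutions,
    cycle_count,
    path_count,
    reduce,
)
from .decompose import (
    ComplexityReport,
    DecompositionTree,
    NodeKind,
    SubgraphNode,
    complexity,
    decompose,
    ear_decompose,
)
from .errors import (
    ConstraintInfeasibleError,
    DesignError,
    ParseError,
    StructureInfeasibleError,
)
from .graph import DependencyGraph, build_graph, check_bipartite, reduce_domains
from .objective import (
    DesignMetrics,
    MockEnergyModel,
    ViennaRNABackend,
    WalkConfig,
    WalkResult,
    adaptive_walk,
    design_metrics,
    objective_corrected,
    objective_original,
)
from .oracle import (
    Fixture,
    count_solutions_oracle,
    enumerate_solutions,
    random_design,
    uniformity_test,
)
from .sampling import (
    DesignSampler,
    SamplerModel,
    SequenceState,
    build_model,
    rank_to_sequence,
    revert,
    sample_biased,
    sample_clocal,
    sample_global,
    sample_plocal,
    sample_position,
)

__version__ = "1.0.0"


def solution_count(spec: DesignSpec, trials: int = 10, seed: int = 0) -> int:
    """Exact number of sequences compatible with a design."""
    graph = build_graph(spec)
    tree = decompose(graph, trials=trials, seed=seed)
    return count_solutions(tree)
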