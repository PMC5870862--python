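"""Objective functions, design-quality metrics and the adaptive walk.

Multi-stable design asks a sequence to fold well into every target
structure at once.  Two single-objective costs are provided, both built
from the target energies E(x, Θ_i) and the ensemble free energy G(x):

* ``original`` — sum of ensemble gaps plus a squared pairwise
  energy-difference penalty,
      f(x) = Σ_i (E_i − G) + ξ · Σ_{i<j} (E_i − E_j)²,
  with ξ defaulting to 1 (an absolute-difference variant of the second
  term is available);
* ``corrected`` — the same two ideas normalized by the number of terms,
      f(x) = (1/M) Σ_i (E_i − G) + ξ · (2/(M(M−1))) Σ_{i<j} |E_i − E_j|,
  so the ratio of the two terms no longer depends on the number of
  target structures M; ξ defaults to 0.5, which restores the 1:1 term
  weighting of the two-target case.

Energy backends are a narrow interface so any thermodynamics engine can
drive the optimizer; a deterministic mock model (simple per-pair weights)
makes everything testable without one, and an adapter to the ViennaRNA
bindings is provided when those are importable.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

from .constraints import DesignSpec, PairSet, write_structure
from .sampling import (
    SamplerModel,
    SequenceState,
    sample_clocal,
    sample_global,
    sample_plocal,
)


class MockEnergyModel:
    """Deterministic toy thermodynamics for testing the optimizer.

    Pair weights GC/CG: 3, AU/UA: 2, GU/UG: 1 (mirroring relative pair
    stabilities); a structure's energy is minus the sum of realized pair
    weights, the MFE is the best of the design's own targets and the
    ensemble energy sits 1 kcal/mol below it.
    """

    name = "mock"
    _WEIGHTS = {
        ("G", "C"): 3.0, ("C", "G"): 3.0,
        ("A", "U"): 2.0, ("U", "A"): 2.0,
        ("G", "U"): 1.0, ("U", "G"): 1.0,
    }

    def __init__(self, spec: DesignSpec):
        self.spec = spec

    def structure_energy(self, sequence: str, structure: PairSet) -> float:
        total = 0.0
        for i, j in structure.pairs:
            total += self._WEIGHTS.get((sequence[i], sequence[j]), 0.0)
        return -total

    def mfe_energy(self, sequence: str) -> float:
        return min(
            self.structure_energy(sequence, s) for s in self.spec.structures
        )

    def ensemble_energy(self, sequence: str) -> float:
        return self.mfe_energy(sequence) - 1.0


class ViennaRNABackend:
    """Energy backend over the ViennaRNA scripting bindings (optional)."""

    name = "viennarna"

    def __init__(self, spec: DesignSpec):
        import RNA  # deferred: bindings are an optional extra

        self._RNA = RNA
        self.spec = spec

    def structure_energy(self, sequence: str, structure: PairSet) -> float:
        db = write_structure(structure)
        return self._RNA.fold_compound(sequence).eval_structure(db)

    def mfe_energy(self, sequence: str) -> float:
        _, mfe = self._RNA.fold_compound(sequence).mfe()
        return mfe

    def ensemble_energy(self, sequence: str) -> float:
        fc = self._RNA.fold_compound(sequence)
        _, energy = fc.pf()
        return energy


def objective_original(
    energies: Sequence[float],
    ensemble: float,
    xi: float = 1.0,
    absolute: bool = False,
) -> float:
    """Ensemble-dominance plus (squared) pairwise energy differences.

    ``absolute=True`` switches the second term to absolute differences.
    """
    m = len(energies)
    cost = sum(e - ensemble for e in energies)
    pair_term = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            d = energies[i] - energies[j]
            pair_term += abs(d) if absolute else d * d
    return cost + xi * pair_term


def objective_corrected(
    energies: Sequence[float], ensemble: float, xi: float = 0.5
) -> float:
    """Per-term normalized objective; ratio of terms independent of M."""
    m = len(energies)
    mean_gap = sum(e - ensemble for e in energies) / m
    if m < 2:
        return mean_gap
    pair_term = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            pair_term += abs(energies[i] - energies[j])
    return mean_gap + xi * (2.0 / (m * (m - 1))) * pair_term


@dataclass(frozen=True)
class DesignMetrics:
    """Quality of one designed sequence against its targets.

    ``delta_e1``/``delta_e2``: energy gap of the most/least stable target
    to the ground state (0 means that target is the MFE structure);
    ``n_mfe``: number of targets whose energy equals the MFE within
    tolerance.
    """

    delta_e1: float
    delta_e2: float
    n_mfe: int


def design_metrics(
    sequence: str,
    spec: DesignSpec,
    backend,
    tolerance: float = 0.01,
) -> DesignMetrics:
    """Compute δe1, δe2 and n_i for a sequence under an energy backend."""
    energies = [backend.structure_energy(sequence, s) for s in spec.structures]
    mfe = backend.mfe_energy(sequence)
    return DesignMetrics(
        delta_e1=min(energies) - mfe,
        delta_e2=max(energies) - mfe,
        n_mfe=sum(1 for e in energies if abs(e - mfe) <= tolerance),
    )


@dataclass
class WalkConfig:
    """Adaptive-walk settings.

    ``stop``: consecutive non-improving candidates before halting;
    ``moves``: "random" mixes P-local/C-local/global uniformly, or force
    one move type; ``objective``: "original" or "corrected" with weight
    ``xi`` (None picks the objective's default); annealing (Metropolis
    acceptance with geometric cooling) is off unless ``temperature`` is
    set.
    """

    stop: int = 1000
    moves: str = "random"
    objective: str = "corrected"
    xi: Optional[float] = None
    seed: Optional[int] = None
    temperature: Optional[float] = None
    cooling: float = 0.995

    def __post_init__(self):
        if self.stop < 1:
            raise ValueError("stop must be >= 1")
        if self.moves not in ("random", "global", "clocal", "plocal"):
            raise ValueError(f"unknown move policy {self.moves!r}")
        if self.objective not in ("original", "corrected"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.xi is not None and self.xi < 0:
            raise ValueError("xi must be >= 0")

    def cost_of(self, energies: Sequence[float], ensemble: float) -> float:
        if self.objective == "original":
            return objective_original(
                energies, ensemble, xi=1.0 if self.xi is None else self.xi
            )
        return objective_corrected(
            energies, ensemble, xi=0.5 if self.xi is None else self.xi
        )


@dataclass(frozen=True)
class Trial:
    index: int
    move: str
    cost: float
    accepted: bool
    best_cost: float


@dataclass
class WalkResult:
    best_sequence: str
    best_cost: float
    initial_cost: float
    trials: int
    trace: List[Trial] = field(default_factory=list)


def adaptive_walk(
    model: SamplerModel, config: WalkConfig, backend
) -> WalkResult:
    """Minimize the objective by repeated resampling moves.

    Starts from one global sample; each trial applies a move (per the
    move policy), scores the candidate, and keeps it only if its cost is
    strictly lower than the best so far (or by Metropolis acceptance when
    annealing is enabled).  Halts after ``stop`` consecutive candidates
    without an improvement of the best cost.
    """
    rng = random.Random(config.seed)
    state = SequenceState(assignment=list(sample_global(model, rng)))
    state.record("global")

    def score(seq: str) -> float:
        energies = [
            backend.structure_energy(seq, s) for s in model.spec.structures
        ]
        return config.cost_of(energies, backend.ensemble_energy(seq))

    current = state.sequence
    current_cost = best_cost = initial_cost = score(current)
    best = current
    temperature = config.temperature
    trace: List[Trial] = []
    no_improve = 0
    trial = 0
    while no_improve < config.stop:
        trial += 1
        move = (
            rng.choice(("plocal", "clocal", "global"))
            if config.moves == "random"
            else config.moves
        )
        if move == "global":
            candidate = sample_global(model, rng, state)
        elif move == "clocal":
            candidate = sample_clocal(model, state, rng)
        else:
            candidate = sample_plocal(model, state, rng)
        cost = score(candidate)

        if temperature is not None:
            delta = cost - current_cost
            accept = delta < 0 or rng.random() < math.exp(-delta / temperature)
            temperature *= config.cooling
        else:
            accept = cost < best_cost
        improved = cost < best_cost
        if improved:
            best, best_cost = candidate, cost
            no_improve = 0
        else:
            no_improve += 1
        if accept:
            current, current_cost = candidate, cost
        else:
            # walk continues from the retained sequence
            state.assignment = list(current)
        trace.append(Trial(trial, move, cost, accept, best_cost))
    return WalkResult(
        best_sequence=best,
        best_cost=best_cost,
        initial_cost=initial_cost,
        trials=trial,
        trace=trace,
    )
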