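"""Objectives, design metrics and the adaptive walk (mock backend)."""

import pytest

from rnadraft import (
    DesignSampler,
    MockEnergyModel,
    WalkConfig,
    adaptive_walk,
    build_model,
    design_metrics,
    load_design,
    objective_corrected,
    objective_original,
)


class TestObjectiveOriginal:
    def test_all_terms_vanish(self):
        assert objective_original((-12, -12), -12, 1) == 0

    def test_substitution(self):
        # (2 + 4) + (-2)^2 = 10
        assert objective_original((-10, -8), -12, 1) == 10

    def test_single_structure_no_pair_term(self):
        assert objective_original((-10,), -12, 1) == 2

    def test_absolute_variant(self):
        # (2 + 4) + |-2| = 8
        assert objective_original((-10, -8), -12, 1, absolute=True) == 8


class TestObjectiveCorrected:
    def test_all_terms_vanish(self):
        assert objective_corrected((-12, -12), -12) == 0

    def test_substitution_two_targets(self):
        # (1/2)(2+4) + 0.5*(2/2)*2 = 4
        assert objective_corrected((-10, -8), -12) == 4

    def test_substitution_three_targets(self):
        # (1/3)(2+4+3) + 0.5*(1/3)(2+1+1) = 3 + 2/3
        assert objective_corrected((-10, -8, -9), -12) == pytest.approx(3 + 2 / 3)

    def test_term_ratio_independent_of_m(self):
        """Both normalized terms (mean ensemble gap, mean pairwise
        difference) are invariant in M for energy vectors replicating the
        same gap pattern: arithmetic progressions with mean gap 3 and
        mean pairwise difference 2 exist for every M, and the corrected
        objective evaluates identically on all of them."""
        ensemble = -12.0

        def progression(m):
            # step 6/(m+1) makes the mean pairwise difference exactly 2
            step = 6.0 / (m + 1)
            centre = ensemble + 3.0
            return tuple(
                centre + step * (k - (m - 1) / 2) for k in range(m)
            )

        values = [
            objective_corrected(progression(m), ensemble, xi=0.5)
            for m in (2, 3, 4)
        ]
        assert values[0] == pytest.approx(3 + 0.5 * 2)
        for v in values[1:]:
            assert v == pytest.approx(values[0])


class TestDesignMetrics:
    def test_gaps_and_counts(self, two_structure_spec):
        class FixedBackend:
            def structure_energy(self, seq, structure):
                return -10.0 if len(structure.pairs) == 2 else -8.0

            def mfe_energy(self, seq):
                return -10.0

        m = design_metrics("A" * 7, two_structure_spec, FixedBackend())
        assert m.delta_e1 == 0
        assert m.delta_e2 == 2
        assert m.n_mfe == 1

    def test_all_targets_at_mfe(self, two_structure_spec):
        class Flat:
            def structure_energy(self, seq, structure):
                return -5.0

            def mfe_energy(self, seq):
                return -5.0

        m = design_metrics("A" * 7, two_structure_spec, Flat())
        assert m.delta_e1 == m.delta_e2 == 0
        assert m.n_mfe == 2

    def test_mock_backend_delta_e1_always_zero(self, two_structure_spec):
        backend = MockEnergyModel(two_structure_spec)
        sampler = DesignSampler(two_structure_spec, seed=0)
        for _ in range(20):
            m = design_metrics(sampler.sample(), two_structure_spec, backend)
            assert m.delta_e1 == 0


class TestAdaptiveWalk:
    def test_unique_solution_stop_one(self):
        spec = load_design(["((...))", "AUAAAAU"])
        model = build_model(spec)
        assert model.total == 1
        result = adaptive_walk(model, WalkConfig(stop=1, seed=0), MockEnergyModel(spec))
        assert result.best_sequence == "AUAAAAU"
        assert result.trials == 1

    def test_best_cost_monotone_and_final_leq_initial(self, two_structure_spec):
        model = build_model(two_structure_spec)
        backend = MockEnergyModel(two_structure_spec)
        for seed in range(5):
            result = adaptive_walk(
                model, WalkConfig(stop=40, seed=seed), backend
            )
            best = [t.best_cost for t in result.trace]
            assert all(a >= b for a, b in zip(best, best[1:]))
            assert result.best_cost <= result.initial_cost

    def test_terminates_after_stop_non_improving(self, two_structure_spec):
        model = build_model(two_structure_spec)
        backend = MockEnergyModel(two_structure_spec)
        result = adaptive_walk(model, WalkConfig(stop=25, seed=1), backend)
        tail = result.trace[-25:]
        assert all(t.cost >= result.best_cost for t in tail)
        assert result.trials >= 25

    def test_aggregate_improvement_over_seeds(self, two_structure_spec):
        model = build_model(two_structure_spec)
        backend = MockEnergyModel(two_structure_spec)
        finals, initials = [], []
        for seed in range(30):
            result = adaptive_walk(model, WalkConfig(stop=30, seed=seed), backend)
            finals.append(result.best_cost)
            initials.append(result.initial_cost)
        assert sum(finals) / 30 < sum(initials) / 30

    def test_move_policy_validated(self):
        with pytest.raises(ValueError):
            WalkConfig(moves="teleport")
        with pytest.raises(ValueError):
            WalkConfig(stop=0)

    def test_annealing_still_tracks_best(self, two_structure_spec):
        model = build_model(two_structure_spec)
        backend = MockEnergyModel(two_structure_spec)
        result = adaptive_walk(
            model,
            WalkConfig(stop=30, seed=2, temperature=1.0, cooling=0.9),
            backend,
        )
        assert result.best_cost <= min(t.cost for t in result.trace)
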