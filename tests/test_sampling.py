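"""Uniform sampling, local moves, the biased comparator, history."""

import collections
import random

import pytest

from rnadraft import (
    ConstraintInfeasibleError,
    DesignError,
    DesignSampler,
    SequenceState,
    build_model,
    rank_to_sequence,
    sample_biased,
    sample_clocal,
    sample_global,
    sample_plocal,
    sample_position,
)
from rnadraft.oracle import enumerate_solutions, uniformity_test

from conftest import spec_from_pairs


@pytest.fixture(scope="module")
def constrained_model():
    from rnadraft import load_design

    return build_model(load_design(["((...))", "(.....)", "NNNNNNA"]))


class TestRankBijection:
    def test_bijection_on_constrained_fixture(self, constrained_model):
        """rank -> sequence must be a bijection onto the solution set."""
        model = constrained_model
        seqs = [rank_to_sequence(model, r) for r in range(model.total)]
        assert len(set(seqs)) == model.total
        assert sorted(seqs) == enumerate_solutions(model.spec)

    def test_bijection_on_theta(self, theta_spec):
        model = build_model(theta_spec)
        seqs = {rank_to_sequence(model, r) for r in range(model.total)}
        assert sorted(seqs) == enumerate_solutions(theta_spec)

    def test_rank_out_of_range(self, constrained_model):
        with pytest.raises(ValueError):
            rank_to_sequence(constrained_model, constrained_model.total)


class TestGlobalSampling:
    def test_single_letter_domain(self):
        spec = spec_from_pairs(5, iupac="AAAAA")
        model = build_model(spec)
        assert model.total == 1
        assert sample_global(model, random.Random(0)) == "AAAAA"

    def test_uniformity_chi_square(self, constrained_model):
        model = constrained_model
        rng = random.Random(2024)
        samples = [sample_global(model, rng) for _ in range(200 * model.total)]
        p = uniformity_test(samples, enumerate_solutions(model.spec))
        assert p > 0.001

    def test_all_draws_compatible(self, constrained_model):
        rng = random.Random(5)
        for _ in range(2000):
            seq = sample_global(constrained_model, rng)
            assert constrained_model.spec.is_compatible(seq)

    def test_infeasible_model_errors(self):
        spec = spec_from_pairs(7, {(0, 6)}, iupac="ANNNNNA")  # A cannot pair A
        with pytest.raises(ConstraintInfeasibleError):
            build_model(spec)


class TestBiasedComparator:
    def test_star_hub_uniform_instead_of_count_weighted(self, star_spec):
        model = build_model(star_spec)
        rng = random.Random(7)
        draws = [sample_biased(model, rng) for _ in range(10000)]
        hub = collections.Counter(seq[0] for seq in draws)
        # count-proportional would be 1/18, 8/18, 8/18, 1/18
        for letter in "AUGC":
            assert abs(hub[letter] / len(draws) - 0.25) < 0.03

    def test_star_fails_uniformity(self, star_spec):
        model = build_model(star_spec)
        rng = random.Random(8)
        draws = [sample_biased(model, rng) for _ in range(10000)]
        assert uniformity_test(draws, enumerate_solutions(star_spec)) < 0.001

    def test_no_articulation_points_means_uniform(self, cycle4_spec):
        """With no articulation decisions the biased sampler collapses to
        the uniform one."""
        model = build_model(cycle4_spec)
        rng = random.Random(9)
        draws = [sample_biased(model, rng) for _ in range(200 * model.total)]
        assert uniformity_test(draws, enumerate_solutions(cycle4_spec)) > 0.001


class TestLocalMoves:
    def test_clocal_changes_only_one_component(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(1)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        state.record("global")
        for _ in range(50):
            before = state.sequence
            sample_clocal(model, state, rng)
            after = state.sequence
            move = state.history[-1][1]
            comp_start = int(move.split(":")[1]) - 1
            comp = model.component_of(comp_start)
            for v in range(model.spec.n):
                if v not in comp.vertices:
                    assert before[v] == after[v]
            assert model.spec.is_compatible(after)

    def test_clocal_selection_weighted_by_counts(self, two_structure_spec):
        # component counts 6, 6, 4, 4, 4 -> selection probabilities /24
        model = build_model(two_structure_spec)
        rng = random.Random(11)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        picks = collections.Counter()
        n_draws = 6000
        for _ in range(n_draws):
            sample_clocal(model, state, rng)
            picks[state.history[-1][1]] += 1
        expect = {"clocal:1": 6, "clocal:2": 6, "clocal:3": 4, "clocal:4": 4, "clocal:5": 4}
        for move, weight in expect.items():
            assert abs(picks[move] / n_draws - weight / 24) < 0.03

    def test_clocal_conditional_uniformity(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(12)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        comp_idx = next(
            k for k, c in enumerate(model.components) if 0 in c.vertices
        )
        pair_counts = collections.Counter()
        for _ in range(6000):
            sample_clocal(model, state, rng, component=comp_idx)
            pair_counts[(state.assignment[0], state.assignment[6])] += 1
        assert len(pair_counts) == 6
        for cnt in pair_counts.values():
            assert abs(cnt / 6000 - 1 / 6) < 0.03

    def test_clocal_size_bounds(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(13)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        with pytest.raises(DesignError):
            sample_clocal(model, state, rng, min_size=3)

    def test_plocal_keeps_articulation_letters(self, star_spec):
        model = build_model(star_spec)
        rng = random.Random(14)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        for _ in range(200):
            hub_before = state.assignment[0]
            sample_plocal(model, state, rng)
            assert state.assignment[0] == hub_before
            assert model.spec.is_compatible(state.sequence)

    def test_plocal_interior_conditionally_uniform(self, star_spec):
        model = build_model(star_spec)
        rng = random.Random(15)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        # force hub to G: each spoke then uniform over partners {C, U}
        while state.assignment[0] != "G":
            sample_global(model, rng, state)
        leaf_idx = next(
            k for k, l in enumerate(model.tree.leaves) if 4 in l.vertices
        )
        spoke = collections.Counter()
        for _ in range(4000):
            sample_plocal(model, state, rng, leaf=leaf_idx)
            spoke[state.assignment[4]] += 1
        assert set(spoke) == {"C", "U"}
        assert abs(spoke["C"] / 4000 - 0.5) < 0.05

    def test_plocal_full_cycle_component(self, cycle4_spec):
        model = build_model(cycle4_spec)
        rng = random.Random(16)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        seen = set()
        for _ in range(400):
            sample_plocal(model, state, rng, min_size=2)
            seen.add("".join(state.assignment[v] for v in (0, 4, 8, 12)))
            assert model.spec.is_compatible(state.sequence)
        assert len(seen) == 14  # whole cycle resampled: all solutions reachable

    def test_singleton_leaf_redraw(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(17)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        seen = set()
        for _ in range(100):
            sample_position(model, state, rng, 3)
            seen.add(state.assignment[2])
        assert seen == set("ACGU")


class TestPositionMoves:
    def test_isolated_position_only_that_changes(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(18)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        before = state.sequence
        sample_position(model, state, rng, 4)
        after = state.sequence
        assert all(before[v] == after[v] for v in range(7) if v != 3)

    def test_articulation_position_resamples_component(self, star_spec):
        model = build_model(star_spec)
        rng = random.Random(19)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        hub_letters = set()
        for _ in range(200):
            sample_position(model, state, rng, 1)  # hub, 1-based
            hub_letters.add(state.assignment[0])
            assert model.spec.is_compatible(state.sequence)
        assert len(hub_letters) > 1  # whole component redrawn, hub moves

    def test_range_covers_two_components(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(20)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        moves_before = len(state.history)
        sample_position(model, state, rng, (1, 2))
        # positions 1 and 2 live in different pair components: two moves
        assert len(state.history) - moves_before == 2

    def test_out_of_range(self, two_structure_spec):
        model = build_model(two_structure_spec)
        rng = random.Random(21)
        state = SequenceState(assignment=list(sample_global(model, rng)))
        with pytest.raises(DesignError):
            sample_position(model, state, rng, 8)


class TestHistoryRevert:
    def test_revert_one_restores_previous(self, two_structure_spec):
        sampler = DesignSampler(two_structure_spec, seed=3)
        first = sampler.sequence
        sampler.sample()
        assert sampler.revert(1) == first

    def test_revert_zero_noop(self, two_structure_spec):
        sampler = DesignSampler(two_structure_spec, seed=4)
        seq = sampler.sample()
        assert sampler.revert(0) == seq

    def test_revert_beyond_depth(self, two_structure_spec):
        sampler = DesignSampler(two_structure_spec, seed=5)
        with pytest.raises(DesignError):
            sampler.revert(10)

    def test_history_cap_evicts_oldest(self):
        state = SequenceState(assignment=list("A"), max_history=3)
        for k in range(5):
            state.record(f"m{k}")
        assert len(state.history) == 3
        assert state.history[0][1] == "m2"
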