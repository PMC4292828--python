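import numpy as np
import pytest

from fcmalloc import (
    AllocationConfig,
    ExpectedChange,
    ParticipantRecord,
    ValidationError,
    allocate_fcm_sorted,
    allocate_permuted_blocks,
    allocate_sequential,
    allocate_simple,
    allocate_stratified,
    enumerate_block_sequences,
    impute,
    partial_shuffle,
    split_batches,
)
from fcmalloc.allocation import apply_swaps


def changes(values):
    return [ExpectedChange(f"P{i:02d}", v) for i, v in enumerate(values)]


class TestFcmSorted:
    def test_worked_cyclic_assignment(self):
        # sorted responses 1,3,5,6,8,9 into 3 groups -> {1,6},{3,8},{5,9}
        alloc = allocate_fcm_sorted(changes([1, 3, 5, 6, 8, 9]), 3)
        by_group = {g: sorted(alloc.group_members(g)) for g in range(3)}
        assert by_group == {0: ["P00", "P03"], 1: ["P01", "P04"],
                            2: ["P02", "P05"]}

    def test_one_participant_per_group(self):
        alloc = allocate_fcm_sorted(changes([0.2, 0.1, 0.3]), 3)
        assert sorted(alloc.sizes()) == [1, 1, 1]

    def test_constant_e_still_balanced_and_deterministic(self):
        alloc1 = allocate_fcm_sorted(changes([0.5] * 10), 4)
        alloc2 = allocate_fcm_sorted(changes([0.5] * 10)[::-1], 4)
        assert max(alloc1.sizes()) - min(alloc1.sizes()) <= 1
        assert dict(alloc1.groups) == dict(alloc2.groups)

    def test_fewer_participants_than_groups(self):
        with pytest.raises(ValidationError):
            allocate_fcm_sorted(changes([1.0]), 2)


class TestSimple:
    def test_seeded_reproducibility(self):
        ids = [f"P{i}" for i in range(50)]
        a = allocate_simple(ids, 4, seed=11)
        b = allocate_simple(ids, 4, seed=11)
        assert dict(a.groups) == dict(b.groups)
        c = allocate_simple(ids, 4, seed=12)
        assert dict(a.groups) != dict(c.groups)

    def test_mean_group_size_matches_multinomial(self):
        # mean size per group over many seeds approaches n / n_groups
        ids = [f"P{i}" for i in range(100)]
        sizes = np.zeros(4)
        n_rep = 500
        for s in range(n_rep):
            sizes += allocate_simple(ids, 4, seed=s).sizes()
        assert np.allclose(sizes / n_rep, 25, atol=1.0)

    def test_empty_ids_rejected(self):
        with pytest.raises(ValidationError):
            allocate_simple([], 2, seed=0)


class TestBlocks:
    @pytest.mark.parametrize("block,groups,count", [
        (4, 2, 6), (2, 2, 2), (4, 4, 24), (6, 3, 90),
    ])
    def test_sequence_counts_match_multinomial_coefficient(self, block, groups, count):
        seqs = enumerate_block_sequences(block, groups)
        assert len(seqs) == count
        assert len(set(seqs)) == count
        per = block // groups
        assert all(seq.count(g) == per for seq in seqs for g in range(groups))

    def test_forced_last_assignment(self):
        # knowing the first 3 of a block of 4 (2 groups) forces the 4th
        seqs = enumerate_block_sequences(4, 2)
        by_prefix = {}
        for s in seqs:
            by_prefix.setdefault(s[:3], set()).add(s[3])
        assert all(len(v) == 1 for v in by_prefix.values())

    def test_full_blocks_balance_exactly(self):
        ids = [f"P{i}" for i in range(8)]
        alloc = allocate_permuted_blocks(ids, 2, 4, seed=5)
        assert alloc.sizes() == [4, 4]

    def test_partial_block_sizes(self):
        # n=6, block 4, 2 groups -> 3/3 or 4/2 depending on the last draw
        seen = set()
        for s in range(40):
            alloc = allocate_permuted_blocks(
                [f"P{i}" for i in range(6)], 2, 4, seed=s)
            seen.add(tuple(sorted(alloc.sizes())))
        assert seen <= {(3, 3), (2, 4)}
        assert (3, 3) in seen and (2, 4) in seen

    def test_invalid_block_size(self):
        with pytest.raises(ValidationError):
            allocate_permuted_blocks(["P1", "P2"], 2, 3, seed=0)


class TestStratified:
    @staticmethod
    def records(values, factor="x"):
        return [ParticipantRecord(f"P{i:02d}", {factor: v})
                for i, v in enumerate(values)]

    def test_single_stratum_equals_permuted_blocks_balance(self):
        recs = self.records(np.linspace(0, 1, 8))
        alloc = allocate_stratified(recs, "x", 1, 2, 4, seed=3)
        assert alloc.sizes() == [4, 4]

    def test_two_strata_balance_within_each(self):
        recs = self.records([0.1, 0.15, 0.2, 0.25, 0.8, 0.82, 0.9, 0.95])
        alloc = allocate_stratified(recs, "x", 2, 2, 4, seed=1)
        low = [alloc.groups[f"P{i:02d}"] for i in range(4)]
        high = [alloc.groups[f"P{i:02d}"] for i in range(4, 8)]
        assert sorted(low) == [0, 0, 1, 1]
        assert sorted(high) == [0, 0, 1, 1]

    def test_constant_factor_collapses_to_one_stratum(self):
        recs = self.records([0.5] * 8)
        alloc = allocate_stratified(recs, "x", 4, 2, 4, seed=2)
        assert alloc.sizes() == [4, 4]

    def test_missing_factor_value_rejected(self):
        recs = self.records([0.1, None, 0.3, 0.4])
        with pytest.raises(ValidationError):
            allocate_stratified(recs, "x", 2, 2, 2, seed=0)


class TestPartialShuffle:
    def test_single_swap_reproduces_worked_example(self):
        # swapping positions 1 and 3 of 1,3,5,6,8,9 gives 1,6,5,3,8,9
        assert apply_swaps([1, 3, 5, 6, 8, 9], [(1, 3)]) == [1, 6, 5, 3, 8, 9]

    def test_identity_at_p_zero(self):
        seq = list(range(20))
        for mode in ("uniform", "distance", "binned"):
            assert partial_shuffle(seq, 0.0, mode, seed=1) == seq

    def test_uniform_moves_about_p_fraction(self):
        seq = list(range(200))
        out = partial_shuffle(seq, 0.5, "uniform", seed=9)
        moved = sum(a != b for a, b in zip(seq, out))
        assert moved == 100  # round(p*N/2) disjoint swaps move exactly p*N

    def test_binned_with_singleton_bins_is_identity(self):
        seq = list(range(15))
        assert partial_shuffle(seq, 0.5, "binned", n_bins=15, seed=4) == seq

    def test_binned_keeps_members_within_bins(self):
        seq = list(range(30))
        out = partial_shuffle(seq, 1.0, "binned", n_bins=3, seed=8)
        for b in range(3):
            assert sorted(out[10 * b:10 * (b + 1)]) == seq[10 * b:10 * (b + 1)]

    def test_distance_mode_is_permutation(self):
        seq = list(range(50))
        out = partial_shuffle(seq, 0.6, "distance", seed=2)
        assert sorted(out) == seq
        assert out != seq

    def test_invalid_proportion(self):
        with pytest.raises(ValidationError):
            partial_shuffle([1, 2], 1.5, "uniform", seed=0)


class TestImpute:
    @staticmethod
    def records():
        return [
            ParticipantRecord("P1", {"x": 0.2, "y": 0.9}),
            ParticipantRecord("P2", {"x": 0.4, "y": None}),
            ParticipantRecord("P3", {"x": None, "y": 0.1}),
        ]

    def test_mean_strategy(self):
        out = impute(self.records(), "mean")
        assert out[2].factor_values["x"] == pytest.approx(0.3)
        assert out[1].factor_values["y"] == pytest.approx(0.5)

    def test_constant_strategy(self):
        out = impute(self.records(), "constant")
        assert out[1].factor_values["y"] == 0.5
        assert out[2].factor_values["x"] == 0.5

    def test_normal_strategy_bounded_and_seeded(self):
        a = impute(self.records(), "normal", seed=3)
        b = impute(self.records(), "normal", seed=3)
        assert a[1].factor_values["y"] == b[1].factor_values["y"]
        assert 0.0 <= a[1].factor_values["y"] <= 1.0

    def test_observed_values_untouched(self):
        for strategy in ("mean", "normal", "constant"):
            out = impute(self.records(), strategy, seed=0)
            assert out[0].factor_values == {"x": 0.2, "y": 0.9}

    def test_no_missing_is_identity(self):
        recs = [ParticipantRecord("P1", {"x": 0.2}),
                ParticipantRecord("P2", {"x": 0.7})]
        for strategy in ("mean", "normal", "constant"):
            assert impute(recs, strategy, seed=0) == recs

    def test_fully_missing_factor_rejected(self):
        recs = [ParticipantRecord("P1", {"x": None}),
                ParticipantRecord("P2", {"x": None})]
        with pytest.raises(ValidationError):
            impute(recs, "mean")


class TestSequential:
    def test_single_batch_reproduces_fixed_sample(self, small_design, scale):
        from fcmalloc import build_weight_matrix, expected_changes
        from fcmalloc.fuzzy import RelationshipAnswer
        rng = np.random.default_rng(5)
        records, answers = _mini_cohort(small_design, scale, 12, rng)
        alloc = allocate_sequential([(records, answers)], small_design,
                                    AllocationConfig(n_groups=3), scale)
        W = build_weight_matrix(small_design, answers, scale)
        fixed = allocate_fcm_sorted(expected_changes(W, records), 3)
        assert dict(alloc.groups) == dict(fixed.groups)
        assert set(alloc.batch.values()) == {0}

    def test_group_cycle_continues_across_batches(self, small_design, scale):
        rng = np.random.default_rng(6)
        records, answers = _mini_cohort(small_design, scale, 12, rng)
        batches = split_batches(records, answers, 3)
        assert [len(b[0]) for b in batches] == [4, 4, 4]
        alloc = allocate_sequential(batches, small_design,
                                    AllocationConfig(n_groups=4), scale)
        assert max(alloc.sizes()) - min(alloc.sizes()) <= 1
        assert sorted(set(alloc.batch.values())) == [0, 1, 2]

    def test_empty_batch_rejected(self, small_design, scale):
        with pytest.raises(ValidationError):
            allocate_sequential([([], [])], small_design,
                                AllocationConfig(n_groups=2), scale)


def _mini_cohort(design, scale, n, rng):
    from fcmalloc.fuzzy import RelationshipAnswer
    records = [
        ParticipantRecord(f"P{i:02d}",
                          {f: float(rng.uniform()) for f in design.factor_names})
        for i in range(n)
    ]
    answers = []
    for i in range(n):
        for s, t in sorted(design.active_relationships):
            answers.append(RelationshipAnswer(
                f"P{i:02d}", s, t, scale.terms[rng.integers(5)],
                int(rng.choice([-1, 1]))))
    return records, answers
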