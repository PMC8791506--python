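"""Universe construction, Bell counting/enumeration, the partition distance
metric, the two modifiers, and JSON round-tripping."""

import itertools
import json
import math

import numpy as np
import pytest

from ptmnet.partitions import (
    Partition,
    RandomSource,
    SpeciesLabel,
    bell_number,
    block_difference,
    build_universe,
    count_networks,
    distance_matrix,
    enumerate_partitions,
    join_modifier,
    partition_distance,
    partition_from_json,
    partition_to_json,
    separate_modifier,
)


def L(s):
    return SpeciesLabel.parse(s)


class TestUniverse:
    @pytest.mark.parametrize("n,expected", [
        (1, ["S1", "E1", "P1"]),
        (2, ["S1", "E1", "P1", "S2", "E2", "P2"]),
    ])
    def test_labels_in_order(self, n, expected):
        assert [str(l) for l in build_universe(n).labels] == expected

    def test_size_3n(self):
        assert build_universe(4).size == 12

    @pytest.mark.parametrize("n", [0, -3])
    def test_rejects_nonpositive(self, n):
        with pytest.raises(ValueError):
            build_universe(n)


class TestCounting:
    def test_matches_printed_value_for_four_reactions(self):
        assert count_networks(4) == 4213597

    def test_single_reaction_count_by_exhaustion(self):
        # brute force: all partitions of a 3-element set
        assert count_networks(1) == 5

    def test_cross_check_bell_triangle(self):
        # independent oracle: Bell triangle dynamic program
        row = [1]
        triangle_bells = [1]
        for _ in range(15):
            new = [row[-1]]
            for v in row:
                new.append(new[-1] + v)
            row = new
            triangle_bells.append(row[0])
        for n in range(16):
            assert bell_number(n) == triangle_bells[n]


class TestEnumeration:
    @pytest.mark.parametrize("n", [1, 2])
    def test_count_matches_bell(self, n):
        parts = list(enumerate_partitions(build_universe(n)))
        assert len(parts) == count_networks(n)
        assert len(set(parts)) == len(parts)  # canonical uniqueness

    def test_single_reaction_contains_motifs(self):
        parts = set(enumerate_partitions(build_universe(1)))
        assert Partition.from_strings(1, [["S1"], ["E1", "P1"]]) in parts
        assert Partition.from_strings(1, [["S1", "P1"], ["E1"]]) in parts
        assert Partition.from_strings(1, [["S1", "P1", "E1"]]) in parts

    def test_guard_refuses_large_universe(self):
        with pytest.raises(ValueError, match="guard"):
            next(enumerate_partitions(build_universe(5)))


class TestValidation:
    def test_rejects_duplicate_label(self):
        with pytest.raises(ValueError, match="more than one block"):
            Partition.from_strings(1, [["S1", "E1"], ["E1", "P1"]])

    def test_rejects_missing_label(self):
        with pytest.raises(ValueError, match="missing"):
            Partition.from_strings(1, [["S1"], ["E1"]])

    def test_canonical_equality_and_hash(self):
        a = Partition.from_strings(2, [["P2"], ["E1", "S1"], ["P1", "S2", "E2"]])
        b = Partition.from_strings(2, [["S1", "E1"], ["S2", "E2", "P1"], ["P2"]])
        assert a == b and hash(a) == hash(b)


class TestDistance:
    # worked example over a 6-element universe: x1=S1 x2=P2 x3=E2 x4=P1 x5=E1 x6=S2
    A = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1"], ["S2"]])
    B = Partition.from_strings(2, [["S1", "P2"], ["E2", "P1", "E1", "S2"]])
    C = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1", "S2"]])

    def test_block_difference(self):
        assert block_difference([L("S1"), L("P2"), L("E2")], [L("S1"), L("P2")]) == 1
        assert block_difference([L("S1")], [L("S1")]) == 0
        assert block_difference([L("S1")], [L("E1"), L("P1")]) == 3

    @pytest.mark.parametrize("X,Y,expected", [
        (A, B, 3), (B, C, 1), (A, C, 2), (A, A, 0),
    ])
    def test_worked_example(self, X, Y, expected):
        assert partition_distance(X, Y) == expected
        assert partition_distance(Y, X) == expected

    def test_distance_matrix(self):
        mat = distance_matrix([self.A, self.B, self.C])
        assert mat.tolist() == [[0, 3, 2], [3, 0, 1], [2, 1, 0]]
        assert distance_matrix([self.A]).tolist() == [[0]]

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            partition_distance(self.A, Partition.discrete(build_universe(1)))

    def test_metric_properties_on_random_triples(self, make_random_partition):
        # identity, symmetry, triangle inequality over seeded random triples
        for seed in range(1000):
            n = 1 + seed % 2
            X = make_random_partition(n, 3 * seed)
            Y = make_random_partition(n, 3 * seed + 1)
            Z = make_random_partition(n, 3 * seed + 2)
            dxy = partition_distance(X, Y)
            assert dxy == partition_distance(Y, X) >= 0
            assert (dxy == 0) == (X == Y)
            assert partition_distance(X, Z) <= dxy + partition_distance(Y, Z)


class TestModifiers:
    def test_separate_block_count_and_validity(self, rng):
        P = Partition.from_strings(2, [["S1", "E1", "P1"], ["S2", "E2", "P2"]])
        for _ in range(20):
            Q = separate_modifier(P, rng)
            assert Q is not None and Q.n_blocks == P.n_blocks + 1

    def test_separate_all_singletons_noop(self, rng):
        P = Partition.discrete(build_universe(1))
        assert separate_modifier(P, rng) is None

    def test_separate_recovers_worked_example(self, rng):
        # splitting {P1,E1,S2} of network C into {P1,E1} and {S2} yields A
        C = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1", "S2"]])
        A = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1"], ["S2"]])
        found = False
        for seed in range(200):
            Q = separate_modifier(C, RandomSource(seed))
            if Q == A:
                found = True
                break
        assert found

    def test_separate_covers_all_bipartitions(self):
        # 3-element block: all 3 proper (unordered) bipartitions must occur
        P = Partition.from_strings(1, [["S1", "E1", "P1"]])
        seen = set()
        for seed in range(200):
            Q = separate_modifier(P, RandomSource(seed))
            seen.add(Q)
        assert len(seen) == 3  # oracle: enumerate bipartitions of a 3-set

    def test_join_block_count_and_worked_example(self):
        A = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1"], ["S2"]])
        C = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1", "S2"]])
        outcomes = set()
        for seed in range(100):
            Q = join_modifier(A, RandomSource(seed))
            assert Q.n_blocks == A.n_blocks - 1
            outcomes.add(Q)
        assert C in outcomes

    def test_join_single_block_noop(self, rng):
        P = Partition.from_strings(1, [["S1", "E1", "P1"]])
        assert join_modifier(P, rng) is None

    def test_join_respects_forbidden_pair(self):
        P = Partition.from_strings(2, [["E1"], ["P2"], ["S1", "S2", "E2", "P1"]])
        forbidden = (L("E1"), L("P2"))
        for seed in range(100):
            Q = join_modifier(P, RandomSource(seed), forbidden_pair=forbidden)
            if Q is None:
                continue
            assert Q.block_index_of(L("E1")) != Q.block_index_of(L("P2"))

    def test_join_then_separate_roundtrip(self):
        P = Partition.from_strings(2, [["S1", "P2", "E2"], ["P1", "E1"], ["S2"]])
        for seed in range(50):
            rng = RandomSource(seed)
            Q = join_modifier(P, rng)
            back = False
            for s2 in range(500):
                R = separate_modifier(Q, RandomSource(s2))
                if R is not None and partition_distance(R, P) == 0:
                    back = True
                    break
            assert back


class TestJson:
    def test_round_trip_canonical(self):
        P = Partition.from_strings(2, [["P1", "S2", "E2"], ["S1", "E1"], ["P2"]])
        assert partition_from_json(partition_to_json(P)) == P

    def test_writer_emits_canonical_order(self):
        P = Partition.from_strings(1, [["P1", "E1"], ["S1"]])
        obj = json.loads(partition_to_json(P))
        assert obj["blocks"] == [["S1"], ["E1", "P1"]]

    def test_reader_rejects_duplicates(self):
        with pytest.raises(ValueError):
            partition_from_json(
                '{"n_reactions": 1, "blocks": [["S1","E1"],["E1","P1"]]}'
            )

    def test_reader_rejects_malformed(self):
        with pytest.raises(ValueError):
            partition_from_json('{"blocks": []}')


class TestPartitionProperties:
    """Hypothesis-driven invariants of canonicalization and the metric."""

    @staticmethod
    def partition_from_assignment(n_reactions, assignment):
        uni = build_universe(n_reactions)
        blocks = {}
        for lab, g in zip(uni.labels, assignment):
            blocks.setdefault(g, []).append(lab)
        return Partition(uni, list(blocks.values()))

    def test_canonicalization_independent_of_block_presentation(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(
            st.lists(st.integers(0, 5), min_size=6, max_size=6),
            st.randoms(use_true_random=False),
        )
        def check(assignment, rand):
            P = self.partition_from_assignment(2, assignment)
            shuffled = [list(b) for b in P.blocks]
            rand.shuffle(shuffled)
            for b in shuffled:
                rand.shuffle(b)
            Q = Partition(P.universe, shuffled)
            assert P == Q and hash(P) == hash(Q)
            assert partition_distance(P, Q) == 0

        check()

    def test_distance_bounded_by_universe_size(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(
            st.lists(st.integers(0, 5), min_size=6, max_size=6),
            st.lists(st.integers(0, 5), min_size=6, max_size=6),
        )
        def check(a1, a2):
            P = self.partition_from_assignment(2, a1)
            Q = self.partition_from_assignment(2, a2)
            d = partition_distance(P, Q)
            assert 0 <= d <= P.universe.size
            assert d == partition_distance(Q, P)

        check()
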