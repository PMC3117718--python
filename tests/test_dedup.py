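"""Duplicate detection: seeding, co-start scoring, graph criteria, clustering."""

import numpy as np
import pytest

from pyroclean import (
    AlignmentHit,
    DedupConfig,
    Read,
    ReadSet,
    SimConfig,
    deduplicate,
    duplication_profile,
    inject_duplicates,
    random_genome,
    simulate_shotgun_reads,
)
from pyroclean.dedup import (
    build_duplicate_graph,
    extract_clusters,
    find_candidate_pairs,
    score_co_start_alignment,
)

from conftest import random_dna
from oracles import brute_force_prefix_pairs, costart_score

CFG = DedupConfig()


def _mutate(seq: str, positions: list[int]) -> str:
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = sub[chars[p]]
    return "".join(chars)


class TestCandidatePairs:
    def test_shared_prefix_pairs_found(self, rng):
        stem = random_dna(rng, 16)
        rs = ReadSet([
            Read("a", stem + random_dna(rng, 100)),
            Read("b", stem + random_dna(rng, 120)),
            Read("c", random_dna(rng, 120)),
        ])
        assert find_candidate_pairs(rs, CFG) == {("a", "b")}

    def test_distinct_first_bases_no_pairs(self, rng):
        rs = ReadSet([Read("a", "A" + random_dna(rng, 50)),
                      Read("b", "C" + random_dna(rng, 50))])
        assert find_candidate_pairs(rs, CFG) == set()

    def test_short_reads_never_candidates(self):
        # 11-base reads fall below seed_k=16 and are skipped outright
        rs = ReadSet([Read("a", "ACGTACGTACG"), Read("b", "ACGTACGTACG")])
        assert find_candidate_pairs(rs, CFG) == set()

    def test_matches_brute_force_on_simulated_reads(self, rng):
        genome = random_genome(SimConfig(genome_len=50_000, n_reads=1, seed=3))
        cfg = SimConfig(genome_len=50_000, n_reads=100, read_len=200, seed=3)
        rs, _ = simulate_shotgun_reads(genome, cfg)
        rs, _ = inject_duplicates(rs, 10, [2] * 10, cfg,
                                  protect_prefix=CFG.seed_k)
        expected = brute_force_prefix_pairs([(r.id, r.seq) for r in rs], CFG.seed_k)
        assert find_candidate_pairs(rs, CFG) == expected


class TestCoStartScoring:
    def test_identical_200mers_score_200(self, rng):
        s = random_dna(rng, 200)
        h = score_co_start_alignment(Read("a", s), Read("b", s), CFG)
        assert (h.score, h.mismatches, h.gaps) == (200, 0, 0)
        assert h.co_start and h.same_strand

    def test_identical_90mers_below_default_threshold(self, rng):
        s = random_dna(rng, 90)
        h = score_co_start_alignment(Read("a", s), Read("b", s), CFG)
        assert h.score == 90  # such reads can never be called duplicates

    def test_five_substitutions_cost_three_each(self, rng):
        s = random_dna(rng, 200)
        h = score_co_start_alignment(
            Read("a", s), Read("b", _mutate(s, [30, 60, 90, 120, 150])), CFG
        )
        assert h.score == 195 * 1 + 5 * (-2) == 185
        assert h.mismatches == 5

    @pytest.mark.parametrize("n_sub,n_indel", [(0, 0), (3, 0), (0, 2), (4, 3)])
    def test_agrees_with_unbanded_dp_on_near_duplicates(self, rng, n_sub, n_indel):
        for _ in range(10):
            s = random_dna(rng, 300)
            t = _mutate(s, sorted(rng.choice(300, n_sub, replace=False)))
            for _k in range(n_indel):
                p = int(rng.integers(10, len(t) - 10))
                t = t[:p] + "ACGT"[rng.integers(0, 4)] + t[p:] if rng.random() < 0.5 \
                    else t[:p] + t[p + 1:]
            got = score_co_start_alignment(Read("a", s), Read("b", t), CFG).score
            assert got == costart_score(s, t)

    def test_banded_never_exceeds_unbanded(self, rng):
        for _ in range(20):
            s = random_dna(rng, int(rng.integers(50, 250)))
            t = random_dna(rng, int(rng.integers(50, 250)))
            assert score_co_start_alignment(Read("a", s), Read("b", t), CFG).score \
                <= costart_score(s, t)

    def test_score_bounded_by_shorter_length(self, rng):
        s = random_dna(rng, 150)
        h = score_co_start_alignment(Read("a", s), Read("b", s + random_dna(rng, 60)), CFG)
        assert h.score <= 150


def _hit(score, a="a", b="b"):
    return AlignmentHit(a, b, score, aligned_len=score, mismatches=0, gaps=0)


class TestEdgeCriteria:
    def _rs(self, len_a, len_b, rng):
        return ReadSet([Read("a", random_dna(rng, len_a)),
                        Read("b", random_dna(rng, len_b))])

    def test_score_threshold_is_strict(self, rng):
        rs = self._rs(200, 200, rng)
        assert build_duplicate_graph([_hit(100)], rs, CFG) == []
        assert build_duplicate_graph([_hit(101)], rs, CFG) == [("a", "b")]

    def test_length_difference_bound_is_strict(self, rng):
        assert build_duplicate_graph([_hit(150)], self._rs(400, 330, rng), CFG) == []
        assert build_duplicate_graph([_hit(150)], self._rs(400, 331, rng), CFG) \
            == [("a", "b")]

    def test_aggressive_ignores_length(self, rng):
        cfg = DedupConfig(aggressive=True)
        assert build_duplicate_graph([_hit(150)], self._rs(400, 200, rng), cfg) \
            == [("a", "b")]


class TestClusters:
    def test_longest_member_is_representative(self, rng):
        rs = ReadSet([Read("A", random_dna(rng, 400)),
                      Read("B", random_dna(rng, 450)),
                      Read("C", random_dna(rng, 420))])
        (c,) = extract_clusters([("A", "B"), ("B", "C")], rs)
        assert c.member_ids == {"A", "B", "C"} and c.representative_id == "B"

    def test_no_edges_all_singletons(self, rng):
        rs = ReadSet([Read(f"r{i}", random_dna(rng, 100)) for i in range(5)])
        cl = extract_clusters([], rs)
        assert len(cl) == 5 and all(len(c) == 1 for c in cl)

    def test_equal_length_tie_breaks_to_smallest_id(self, rng):
        s = random_dna(rng, 300)
        rs = ReadSet([Read("z", s), Read("m", s), Read("a", s)])
        (c,) = extract_clusters([("z", "m"), ("m", "a")], rs)
        assert c.representative_id == "a"

    def test_random_graphs_match_reachability_closure(self, rng):
        import networkx  # noqa: F401  (implementation route)
        for trial in range(5):
            n = int(rng.integers(20, 200))
            rs = ReadSet([Read(f"v{i}", random_dna(rng, 100)) for i in range(n)])
            ids = [r.id for r in rs]
            edges = [
                (ids[int(i)], ids[int(j)])
                for i, j in rng.integers(0, n, size=(n // 2, 2))
                if i != j
            ]
            got = {c.member_ids for c in extract_clusters(edges, rs)}
            # independent closure via iterated union of neighbourhoods
            adj = np.eye(n, dtype=bool)
            idx = {v: k for k, v in enumerate(ids)}
            for a, b in edges:
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
            reach = adj.copy()
            while True:
                nxt = reach | (reach @ reach)
                if (nxt == reach).all():
                    break
                reach = nxt
            expected = {
                frozenset(ids[int(k)] for k in np.flatnonzero(row)) for row in reach
            }
            assert got == expected


class TestDeduplicate:
    def test_three_copies_two_removed(self, rng):
        s = random_dna(rng, 300)
        rs = ReadSet([Read("d1", s), Read("d2", s), Read("d3", s),
                      Read("u1", random_dna(rng, 300)),
                      Read("u2", random_dna(rng, 300))])
        kept, removed, clusters = deduplicate(rs, CFG)
        assert len(kept) == 3 and len(removed) == 2
        assert {r.id for r in kept} == {"d1", "u1", "u2"}

    def test_empty_readset(self):
        kept, removed, clusters = deduplicate(ReadSet(), CFG)
        assert len(kept) == 0 and removed == [] and clusters == []

    def test_recovers_injected_clusters_exactly(self, rng):
        genome = random_genome(SimConfig(genome_len=80_000, n_reads=1, seed=7))
        cfg = SimConfig(genome_len=80_000, n_reads=60, read_len=400, seed=7)
        rs, _ = simulate_shotgun_reads(genome, cfg)
        rs, truth = inject_duplicates(rs, 8, [2, 3, 2, 4, 2, 2, 3, 2], cfg)
        _, _, clusters = deduplicate(rs, CFG)
        got = {frozenset(c.member_ids) for c in clusters if len(c) > 1}
        assert got == {frozenset(t) for t in truth}

    def test_partition_and_idempotence(self, rng):
        s = random_dna(rng, 300)
        rs = ReadSet([Read("a", s), Read("b", s + "ACGT"),
                      Read("c", random_dna(rng, 250))])
        kept, removed, clusters = deduplicate(rs, CFG)
        assert {r.id for r in kept} | {i for i, _ in removed} == {"a", "b", "c"}
        assert not ({r.id for r in kept} & {i for i, _ in removed})
        assert sum(len(c) for c in clusters) == len(rs)
        kept2, removed2, _ = deduplicate(kept, CFG)
        assert removed2 == [] and len(kept2) == len(kept)

    def test_kept_preserves_input_order(self, rng):
        reads = [Read(f"r{i}", random_dna(rng, 200)) for i in range(10)]
        kept, _, _ = deduplicate(ReadSet(reads), CFG)
        order = [r.id for r in reads]
        assert [r.id for r in kept] == sorted(
            (r.id for r in kept), key=order.index
        )

    def test_monotone_in_thresholds(self, rng):
        s = random_dna(rng, 300)
        reads = [Read("a", s), Read("b", _mutate(s, [5, 50])),
                 Read("c", s[:220]), Read("d", random_dna(rng, 300))]
        rs = ReadSet(reads)
        kept_default, _, _ = deduplicate(rs, DedupConfig())
        for cfg in (DedupConfig(score_threshold=50),
                    DedupConfig(length_diff_max=200),
                    DedupConfig(aggressive=True)):
            kept, _, _ = deduplicate(rs, cfg)
            assert len(kept) <= len(kept_default)


class TestProfile:
    def test_histogram_and_rates(self, rng):
        rs = ReadSet([Read(f"r{i}", random_dna(rng, 100)) for i in range(7)])
        clusters = extract_clusters(
            [("r0", "r1"), ("r2", "r3"), ("r3", "r4")], rs
        )
        prof = duplication_profile(clusters)
        assert prof.histogram == {1: 2, 2: 1, 3: 1}
        assert prof.dup_membership_rate == pytest.approx(5 / 7)
        assert prof.removal_rate == pytest.approx(3 / 7)
        assert sum(s * c for s, c in prof.histogram.items()) == 7

    def test_all_singletons_zero_rates(self, rng):
        rs = ReadSet([Read(f"r{i}", random_dna(rng, 100)) for i in range(4)])
        prof = duplication_profile(extract_clusters([], rs))
        assert prof.dup_membership_rate == 0 and prof.removal_rate == 0

    def test_single_pair(self, rng):
        rs = ReadSet([Read("a", random_dna(rng, 100)), Read("b", random_dna(rng, 100))])
        prof = duplication_profile(extract_clusters([("a", "b")], rs))
        assert prof.dup_membership_rate == 1.0 and prof.removal_rate == 0.5
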