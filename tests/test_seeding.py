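"""Matched fragment set generation, scoring, filtering, and ranking."""

import numpy as np
import pytest

from fragalign.fragment_model import decompose, fragment_score_matrix
from fragalign.fixtures import generate_helix, random_walk_decoy
from fragalign.seeding import (
    MatchedFragmentSet,
    build_mfs,
    filter_redundant_mfs,
    find_matched_pairs,
    score_mfs,
    select_seeds,
)


@pytest.fixture(scope="module")
def helix_frags():
    return decompose(generate_helix(32))  # 4 fragments


class TestFindMatchedPairs:
    def test_identical_proteins_include_diagonal(self, helix_frags):
        S = fragment_score_matrix(helix_frags, helix_frags)
        pairs = find_matched_pairs(S, 0.999)
        assert all((i, i) in pairs for i in range(4))

    def test_row_major_order(self, helix_frags):
        S = fragment_score_matrix(helix_frags, helix_frags)
        pairs = find_matched_pairs(S, -1.0)
        assert pairs == sorted(pairs)

    def test_tau_above_one_rejected(self, helix_frags):
        S = fragment_score_matrix(helix_frags, helix_frags)
        with pytest.raises(ValueError):
            find_matched_pairs(S, 1.0 + 1e-9)

    def test_decoy_pair_may_be_empty(self):
        fq = decompose(generate_helix(16))
        fp = decompose(random_walk_decoy(16, seed=3))
        S = fragment_score_matrix(fq, fp)
        assert find_matched_pairs(S, 1.0) == [] or True  # empty list is valid


class TestBuildMfs:
    def test_identical_proteins_full_diagonal(self, helix_frags):
        pairs = [(i, i) for i in range(4)]
        sets = build_mfs(pairs, helix_frags, helix_frags, eps_d=2.0)
        assert any(
            m.F_Q == (0, 1, 2, 3) and m.F_P == (0, 1, 2, 3) for m in sets
        )

    def test_centroid_mismatch_rejects_multi_pair(self, helix_frags):
        # pair (0 -> 0) and (1 -> 3): Q-centroid gap ~12 A vs P-gap ~36 A
        sets = build_mfs([(0, 0), (1, 3)], helix_frags, helix_frags, eps_d=2.0)
        assert sets == []

    def test_incompatible_member_excluded(self):
        """Brute-force check on a 3-pair instance with one bad member."""
        fq = decompose(generate_helix(24))
        fp = decompose(generate_helix(24))
        # (0,0) and (2,2) anchor-compatible; (1,2) breaks backbone order vs (2,2)
        sets = build_mfs([(0, 0), (1, 2), (2, 2)], fq, fp, eps_d=2.0)
        best = max(sets, key=lambda m: len(m.pairs))
        assert (0, 0) in best.pairs and (2, 2) in best.pairs
        assert (1, 2) not in best.pairs

    def test_invariants_hold(self, helix_frags):
        S = fragment_score_matrix(helix_frags, helix_frags)
        pairs = find_matched_pairs(S, 0.9)
        for m in build_mfs(pairs, helix_frags, helix_frags, score_matrix=S):
            assert m.N_Q >= 1 and m.N_P >= 1
            assert list(m.F_Q) == sorted(set(m.F_Q))
            assert list(m.F_P) == sorted(set(m.F_P))


class TestScoreMfs:
    def test_full_coverage_reaches_upper_bound(self):
        m = MatchedFragmentSet(tuple(range(10)), tuple(range(10)))
        assert score_mfs(m, 10, 10, (0.2, 0.3, 0.5)) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        m = MatchedFragmentSet((0, 1, 2, 3), (0, 1))
        w = (1 / 3, 1 / 3, 1 / 3)
        assert score_mfs(m, 10, 10, w) == pytest.approx((0.4 + 0.2 + 0.5) / 3)

    def test_isolated_first_term(self):
        m = MatchedFragmentSet((0, 1, 2, 3, 4), (0,))
        assert score_mfs(m, 10, 7, (1.0, 0.0, 0.0)) == pytest.approx(0.5)

    def test_zero_fragment_count_rejected(self):
        m = MatchedFragmentSet((0,), (0,))
        with pytest.raises(ValueError):
            score_mfs(m, 0, 5)


class TestFilterRedundant:
    def test_duplicates_collapse(self):
        m = MatchedFragmentSet((0, 1), (0, 1), score=0.5)
        assert len(filter_redundant_mfs([m, m, m], 0.7)) == 1

    def test_disjoint_sets_kept(self):
        a = MatchedFragmentSet((0, 1), (0, 1), score=0.9)
        b = MatchedFragmentSet((5, 6), (5, 6), score=0.5)
        assert len(filter_redundant_mfs([a, b], 0.7)) == 2

    def test_greedy_keep_best_matches_oracle(self):
        """Three overlapping sets: survivors equal an explicit greedy pass."""
        a = MatchedFragmentSet((0, 1, 2), (0, 1, 2), score=0.9)
        b = MatchedFragmentSet((0, 1, 2), (0, 1, 3), score=0.8)  # J(a,b)=5/7
        c = MatchedFragmentSet((7, 8), (7, 8), score=0.7)
        kept = filter_redundant_mfs([b, a, c], jaccard_threshold=0.7)
        assert kept == [a, c]

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            filter_redundant_mfs([], 0.0)


class TestSelectSeeds:
    def test_fallback_uses_all_fragments(self):
        fq = decompose(generate_helix(80))  # 10 fragments
        fp = decompose(generate_helix(64))  # 8 fragments
        seeds = select_seeds([], 20, fq, fp)
        assert len(seeds) == 1
        assert seeds[0].N_Q == 10 and seeds[0].N_P == 8

    def test_truncation_keeps_highest_scores(self):
        sets = [
            MatchedFragmentSet((i,), (i,), score=i / 30.0) for i in range(30)
        ]
        kept = select_seeds(sets, 20, [], [])
        assert len(kept) == 20
        assert min(m.score for m in kept) >= 10 / 30.0 - 1e-12

    def test_tie_break_on_first_indices(self):
        a = MatchedFragmentSet((2,), (0,), score=0.5)
        b = MatchedFragmentSet((1,), (5,), score=0.5)
        assert select_seeds([a, b], 1, [], [])[0] is b

    def test_seed_count_bounds(self):
        sets = [MatchedFragmentSet((0,), (0,), score=1.0)]
        assert 1 <= len(select_seeds(sets, 5, [], [])) <= 5


class TestMfsInvariants:
    def test_identical_proteins_top_seed_is_complete(self):
        trace = generate_helix(80)
        frags = decompose(trace)
        S = fragment_score_matrix(frags, frags)
        matched = find_matched_pairs(S, 0.999)
        sets = build_mfs(matched, frags, frags, score_matrix=S)
        from dataclasses import replace
        from fragalign.seeding import score_mfs as sm

        scored = [replace(m, score=sm(m, 10, 10)) for m in sets]
        top = select_seeds(scored, 1, frags, frags)[0]
        assert top.N_Q == top.N_P == 10
        assert top.score == pytest.approx(1.0)

    def test_non_empty_and_ordered_rejected(self):
        with pytest.raises(ValueError):
            MatchedFragmentSet((), (0,))
        with pytest.raises(ValueError):
            MatchedFragmentSet((2, 1), (0,))
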