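import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parrondonet.games import (
    BehaviorPattern,
    Transfer,
    matthew_win_prob,
    resolve_game_a,
    resolve_game_b,
    select_branch_b,
)

capitals_strategy = st.lists(st.integers(-20, 20), min_size=2, max_size=8)


class TestMatthewWinProb:
    def test_equal_capitals_give_certain_win(self):
        assert matthew_win_prob([5, 5, 5, 5], 0) == 1.0

    def test_unique_poorest_has_minimal_rank(self):
        assert matthew_win_prob([0, 3, 3, 3, 3], 0) == pytest.approx(1 / 5)

    def test_direct_rank_count(self):
        # fitnesses (0, 0, 2, 5): node with 2 outranks three of four
        assert matthew_win_prob([0, 0, 2, 5], 2) == pytest.approx(3 / 4)

    @given(capitals=capitals_strategy, i=st.integers(0, 7))
    @settings(max_examples=100, deadline=None)
    def test_rank_monotone_in_own_capital(self, capitals, i):
        i = i % len(capitals)
        lo = matthew_win_prob(capitals, i)
        richer = list(capitals)
        richer[i] += 1
        hi = matthew_win_prob(richer, i)
        assert 1 / len(capitals) <= lo <= hi <= 1.0


class TestGameA:
    @pytest.mark.parametrize("pattern", list(BehaviorPattern))
    @given(capitals=capitals_strategy, rand=st.floats(0, 1, exclude_max=True))
    @settings(max_examples=50, deadline=None)
    def test_zero_sum_one_unit_transfer(self, pattern, capitals, rand):
        t = resolve_game_a(capitals, 0, 1, pattern, rand)
        assert isinstance(t, Transfer)
        assert {t.payer, t.payee} == {0, 1}

    def test_cooperation_subject_always_pays(self):
        t = resolve_game_a([9, -3], 0, 1, BehaviorPattern.COOPERATION, 0.99)
        assert (t.payer, t.payee) == (0, 1)

    def test_harmony_rich_pays_poor(self):
        t = resolve_game_a([5, 3], 0, 1, BehaviorPattern.HARMONY, 0.0)
        assert (t.payer, t.payee) == (0, 1)
        # ties: the object pays the subject
        t = resolve_game_a([3, 3], 0, 1, BehaviorPattern.HARMONY, 0.0)
        assert (t.payer, t.payee) == (1, 0)

    @given(ci=st.integers(-5, 5), cj=st.integers(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_harmony_never_widens_the_gap(self, ci, cj):
        t = resolve_game_a([ci, cj], 0, 1, BehaviorPattern.HARMONY, 0.0)
        after_i = ci + (1 if t.payee == 0 else -1)
        after_j = cj + (1 if t.payee == 1 else -1)
        if ci != cj:
            assert abs(after_i - after_j) <= abs(ci - cj)
        else:
            assert abs(after_i - after_j) == 2

    def test_pcrc_rich_subject_donates_deterministically(self):
        for rand in (0.0, 0.5, 0.999):
            t = resolve_game_a([7, 2], 0, 1, BehaviorPattern.PCRC, rand)
            assert (t.payer, t.payee) == (0, 1)

    def test_pcrc_poor_subject_flips_a_fair_coin(self):
        win = resolve_game_a([2, 7], 0, 1, BehaviorPattern.PCRC, 0.49)
        lose = resolve_game_a([2, 7], 0, 1, BehaviorPattern.PCRC, 0.51)
        assert win.payee == 0
        assert lose.payer == 0

    def test_random_pattern_variate_regions(self):
        # [0, .25) competitive win, [.25, .5) competitive loss, [.5, 1) donate
        assert resolve_game_a([0, 0], 0, 1, BehaviorPattern.RANDOM, 0.1).payee == 0
        assert resolve_game_a([0, 0], 0, 1, BehaviorPattern.RANDOM, 0.3).payer == 0
        assert resolve_game_a([0, 0], 0, 1, BehaviorPattern.RANDOM, 0.7).payer == 0

    def test_matthew_uses_rank_probability(self):
        # phi = 1 at equal capitals: subject wins for every variate < 1
        t = resolve_game_a([0, 0, 0], 0, 1, BehaviorPattern.MATTHEW, 0.999)
        assert t.payee == 0

    def test_subject_equals_object_rejected(self):
        with pytest.raises(ValueError):
            resolve_game_a([0, 0], 1, 1, BehaviorPattern.HARMONY, 0.0)


class TestGameB:
    def test_equal_capitals_select_branch_1(self):
        assert select_branch_b([3, 3, 3], [1, 2], 0) == 1

    def test_above_neighbor_mean_selects_branch_2(self):
        assert select_branch_b([3, 1, 2], [1, 2], 0) == 2

    def test_at_or_below_mean_selects_branch_1(self):
        assert select_branch_b([1, 1, 2, 3, 4], [1, 2, 3, 4], 0) == 1

    def test_no_neighbors_rejected(self):
        with pytest.raises(ValueError):
            select_branch_b([0, 0], [], 0)

    def test_certain_win_and_certain_loss(self):
        out = resolve_game_b([0, 0], [1], 0, p1=1.0, p2=0.3, rand=0.999)
        assert (out.branch, out.delta) == (1, 1)
        out = resolve_game_b([5, 0], [1], 0, p1=0.3, p2=0.0, rand=0.001)
        assert (out.branch, out.delta) == (2, -1)

    @given(rand=st.floats(0, 1, exclude_max=True), q=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_equal_branch_probabilities_make_branches_identical(self, rand, q):
        lo = resolve_game_b([0, 1], [1], 0, q, q, rand)
        hi = resolve_game_b([5, 1], [1], 0, q, q, rand)
        assert lo.delta == hi.delta
        assert (lo.branch, hi.branch) == (1, 2)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            resolve_game_b([0, 0], [1], 0, p1=1.2, p2=0.5, rand=0.5)
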