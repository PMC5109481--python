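import numpy as np
import pytest

from parrondonet.engine import (
    GameConfig,
    GameMode,
    mean_fitness_samples,
    run,
    run_reference,
    run_replicates,
)
from parrondonet.games import BehaviorPattern
from parrondonet.oracle import closed_form_uniform

ALL_PATTERNS = list(BehaviorPattern)
ALL_MODES = list(GameMode)


@pytest.mark.parametrize("pattern", ALL_PATTERNS)
@pytest.mark.parametrize("mode", ALL_MODES)
def test_kernel_matches_reference_engine_bit_exactly(lattice5, pattern, mode):
    """The compiled kernel and the pure-Python reference share one RNG
    stream and draw order, so equal seeds give identical trajectories."""
    cfg = GameConfig(
        pattern=pattern, mode=mode, p=0.4, p1=0.3, p2=0.8, plays_per_individual=6
    )
    fast = run(lattice5, cfg, seed=97)
    slow = run_reference(lattice5, cfg, seed=97)
    assert np.array_equal(fast.final_fitness, slow.final_fitness)
    assert np.array_equal(fast.branch1_plays, slow.branch1_plays)
    assert np.array_equal(fast.branch2_plays, slow.branch2_plays)


@pytest.mark.parametrize("pattern", ALL_PATTERNS)
def test_game_a_alone_conserves_total_capital_exactly(lattice5, pattern):
    cfg = GameConfig(pattern=pattern, mode=GameMode.A_ONLY, plays_per_individual=20)
    res = run(lattice5, cfg, seed=3)
    assert res.final_fitness.sum() == 0
    assert res.mean_fitness == 0.0
    assert res.branch1_plays.sum() == 0 and res.branch2_plays.sum() == 0


def test_certain_win_game_b_gains_one_per_round(four_cycle):
    cfg = GameConfig(
        mode=GameMode.B_ONLY, p1=1.0, p2=1.0, plays_per_individual=50
    )
    res = run(four_cycle, cfg, seed=5)
    assert res.final_fitness.sum() == res.rounds_played
    assert res.mean_fitness == 50.0


@pytest.mark.parametrize("q", [0.0, 0.25, 0.5, 0.75, 1.0])
@pytest.mark.parametrize("mode", [GameMode.B_ONLY, GameMode.A_PLUS_B])
def test_uniform_branch_probability_closed_form(lattice5, q, mode):
    """With p1 = p2 = q the game-B rounds are a binomial walk with mean
    plays * (2q - 1) (halved by the mixture), independent of the pattern."""
    cfg = GameConfig(
        pattern=BehaviorPattern.RANDOM,
        mode=mode,
        p=0.5,
        p1=q,
        p2=q,
        plays_per_individual=40,
    )
    d = mean_fitness_samples(lattice5, cfg, n_reps=30, base_seed=11)
    expected = closed_form_uniform(q, 40, 0.5, mode)
    se = d.std(ddof=1) / np.sqrt(len(d))
    assert abs(d.mean() - expected) <= max(4 * se, 1e-12)


def test_identical_seed_gives_bit_identical_results(lattice5):
    cfg = GameConfig(
        pattern=BehaviorPattern.MATTHEW,
        mode=GameMode.A_PLUS_B,
        p1=0.2,
        p2=0.9,
        plays_per_individual=10,
    )
    a = run(lattice5, cfg, seed=123)
    b = run(lattice5, cfg, seed=123)
    assert np.array_equal(a.final_fitness, b.final_fitness)
    assert np.array_equal(a.branch1_plays, b.branch1_plays)
    c = run(lattice5, cfg, seed=124)
    assert not np.array_equal(a.final_fitness, c.final_fitness)


def test_initial_capital_is_irrelevant_to_fitness(lattice5):
    """All rules depend only on capital differences, so a common C_0
    shifts capitals without changing any trajectory of W."""
    for c0 in (-7, 0, 1000):
        cfg = GameConfig(
            pattern=BehaviorPattern.PCRC,
            mode=GameMode.A_PLUS_B,
            p1=0.3,
            p2=0.7,
            plays_per_individual=8,
            initial_capital=c0,
        )
        res = run(lattice5, cfg, seed=55)
        if c0 == -7:
            baseline = res.final_fitness
        else:
            assert np.array_equal(res.final_fitness, baseline)


def test_branch_counts_partition_game_b_rounds(four_cycle):
    cfg = GameConfig(mode=GameMode.B_ONLY, p1=0.4, p2=0.6, plays_per_individual=25)
    res = run(four_cycle, cfg, seed=9)
    assert res.branch1_plays.sum() + res.branch2_plays.sum() == res.rounds_played


def test_single_replicate_aggregate_equals_the_run(lattice5):
    cfg = GameConfig(mode=GameMode.B_ONLY, p1=0.3, p2=0.8, plays_per_individual=10)
    rs = run_replicates(lattice5, cfg, n_reps=1, base_seed=77)
    assert rs.d_mean == run(lattice5, cfg, 77).mean_fitness


def test_replicates_use_consecutive_seeds(lattice5):
    cfg = GameConfig(mode=GameMode.B_ONLY, p1=0.3, p2=0.8, plays_per_individual=5)
    rs = run_replicates(lattice5, cfg, n_reps=3, base_seed=50)
    for r, res in enumerate(rs.results):
        assert res.seed == 50 + r
        assert res.mean_fitness == run(lattice5, cfg, 50 + r).mean_fitness


def test_fresh_graph_source_called_per_replicate(lattice5):
    seen = []

    def source(seed):
        seen.append(seed)
        return lattice5

    cfg = GameConfig(mode=GameMode.B_ONLY, p1=0.5, p2=0.5, plays_per_individual=2)
    run_replicates(source, cfg, n_reps=4, base_seed=10)
    assert seen == [10, 11, 12, 13]


def test_mean_fitness_samples_matches_individual_runs(four_cycle):
    cfg = GameConfig(
        pattern=BehaviorPattern.HARMONY,
        mode=GameMode.A_PLUS_B,
        p1=0.2,
        p2=0.9,
        plays_per_individual=12,
    )
    batch = mean_fitness_samples(four_cycle, cfg, n_reps=5, base_seed=31)
    loop = [run(four_cycle, cfg, 31 + r).mean_fitness for r in range(5)]
    assert np.array_equal(batch, loop)


@pytest.mark.parametrize("axis", ["p1", "p2"])
def test_mean_d_b_statistically_monotone_in_branch_probabilities(four_cycle, axis):
    """d^(B) is non-decreasing in each branch win probability separately
    (coarse grid, common seeds)."""
    means = []
    for q in (0.1, 0.5, 0.9):
        kw = {"p1": q, "p2": 0.5} if axis == "p1" else {"p1": 0.5, "p2": q}
        cfg = GameConfig(mode=GameMode.B_ONLY, plays_per_individual=30, **kw)
        means.append(mean_fitness_samples(four_cycle, cfg, 40, 7).mean())
    assert means[0] <= means[1] <= means[2]


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GameConfig(p1=1.5)
    with pytest.raises(ValueError):
        GameConfig(plays_per_individual=0)
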