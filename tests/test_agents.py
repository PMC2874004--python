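import numpy as np
import pytest

from nestsim import (NestArena, ParameterError, SimConfig, Simulation,
                     apply_move, build_nests_for_day, daily_move,
                     draw_stage_durations, init_environment, move_all,
                     remove_fraction)
from nestsim.agents import DIR_NAMES, DIR_VECTORS, _allowed_directions, reflect_coordinate


class TestMovement:
    def test_step_length_distribution(self, rng):
        # 10,000 one-day moves: mean ~350 squares (700 m), sd ~100 squares
        cfg = SimConfig()
        pos = np.full((10_000, 2), 2500, dtype=np.int64)
        _, steps, dirs = move_all(pos, cfg, rng)
        assert steps.mean() == pytest.approx(350, abs=3)
        assert steps.std() == pytest.approx(100, abs=3)
        assert steps.min() >= 0
        # directions uniform over the 8 compass points away from any edge
        assert np.bincount(dirs, minlength=8).min() > 10_000 / 8 * 0.85

    def test_corner_restricts_directions(self):
        allowed = _allowed_directions(0, 0, 5000)
        vecs = DIR_VECTORS[allowed]
        assert np.all(vecs[:, 0] >= 0) and np.all(vecs[:, 1] >= 0)
        assert len(allowed) == 3  # E, NE, N

    def test_edge_restricts_directions(self):
        allowed = _allowed_directions(0, 2500, 5000)
        assert np.all(DIR_VECTORS[allowed][:, 0] >= 0)
        assert len(allowed) == 5

    def test_moves_from_corner_stay_in_grid(self, rng):
        cfg = SimConfig(grid_side=600)
        for _ in range(200):
            x, y = daily_move((0, 0), cfg, rng)
            assert 0 <= x < 600 and 0 <= y < 600

    def test_deterministic_eastward_move(self):
        east = DIR_NAMES.index("E")
        assert apply_move((100, 100), 350, east, 5000) == (450, 100)

    def test_overshoot_reflects_off_wall(self):
        west = DIR_NAMES.index("W")
        # 100 - 350 = -250 reflects to +250
        assert apply_move((100, 100), 350, west, 5000) == (250, 100)
        # multiple folds for very large overshoot on a small grid
        assert reflect_coordinate(-1, 10) == 1
        assert reflect_coordinate(9, 10) == 9
        assert reflect_coordinate(10, 10) == 8
        assert reflect_coordinate(37, 10) == 1  # 37 mod 18 = 1


class TestNestBuilding:
    def test_overall_build_rate_is_r(self, rng):
        # night nest daily plus Bernoulli(0.2) day nest => 1.2 nests/day
        cfg = SimConfig(grid_side=500, n_orangutans=400, first_survey_day=300)
        sim = Simulation(cfg, rng=rng)
        sim.run_until(50)
        rate = sim.arena.n_built / (400 * 50)
        assert rate == pytest.approx(1.2, abs=0.02)

    def test_day_nests_scaled_by_day_nest_factor(self, rng):
        cfg = SimConfig(grid_side=100)
        env = init_environment(cfg, rng)
        night = draw_stage_durations(env, [50], [50], [False],
                                     np.random.default_rng(99))
        day = draw_stage_durations(env, [50], [50], [True],
                                   np.random.default_rng(99))
        assert np.allclose(day, night / cfg.day_nest_factor)

    def test_durations_scaled_by_altitude(self, rng):
        cfg = SimConfig(grid_side=1001, altitude_slope=0.3, n_tree_types=1)
        env = init_environment(cfg, rng)
        low = draw_stage_durations(env, [0], [5], [False], np.random.default_rng(3))
        mid = draw_stage_durations(env, [500], [5], [False], np.random.default_rng(3))
        assert np.allclose(low / mid, 0.7)

    def test_night_nest_always_built_day_nest_on_path(self, rng):
        cfg = SimConfig(grid_side=1000, day_nest_rate=1.0)
        env = init_environment(cfg, rng)
        arena = NestArena(cfg.grid_side)
        east = DIR_NAMES.index("E")
        idx = build_nests_for_day(arena, env, day=1, start_position=(100, 200),
                                  end_position=(400, 200), step=300,
                                  direction=east, rng=rng)
        assert len(idx) == 2
        night, day = idx[0], idx[1]
        assert (arena.x[night], arena.y[night]) == (400, 200)
        assert arena.y[day] == 200 and 100 < arena.x[day] <= 400

    def test_nest_on_occupied_square_replaces_old(self, rng):
        cfg = SimConfig(grid_side=100)
        env = init_environment(cfg, rng)
        arena = NestArena(cfg.grid_side)
        first = arena.add([10], [10], 0, day=1,
                          durations=np.full((1, 5), 10.0))[0]
        arena.tagged[first] = True
        second = arena.add([10], [10], 0, day=2,
                           durations=np.full((1, 5), 10.0))[0]
        assert not arena.alive[first]
        assert arena.alive[second]
        assert not arena.tagged[second]          # replacement inherits nothing
        assert arena.id[second] != arena.id[first]
        assert arena.n_replaced == 1

    def test_ids_survive_compaction(self, rng):
        arena = NestArena(100)
        idx = arena.add(np.arange(10), np.zeros(10, int), 0, 1,
                        np.full((10, 5), 5.0))
        arena.mark_dead(idx[:5])
        ids_before = set(arena.id[idx[5:]])
        arena.compact()
        assert arena.n == 5
        assert set(arena.id[:5]) == ids_before
        # new ids keep counting upward, never recycled
        new = arena.add([50], [50], 0, 2, np.full((1, 5), 5.0))
        assert arena.id[new[0]] == 10


class TestRemoveFraction:
    def test_five_percent_of_200_leaves_190(self, rng):
        pop = np.zeros((200, 2), dtype=np.int64)
        assert len(remove_fraction(pop, 0.05, rng)) == 190

    def test_successive_yearly_removals_round_half_up(self, rng):
        pop = np.zeros((200, 2), dtype=np.int64)
        sizes = []
        for _ in range(3):
            pop = remove_fraction(pop, 0.05, rng)
            sizes.append(len(pop))
        # round-half-up: 200-10=190, 190-10=180 (9.5 rounds up), 180-9=171
        assert sizes == [190, 180, 171]

    def test_zero_fraction_is_identity(self, rng):
        pop = np.arange(20).reshape(10, 2)
        assert remove_fraction(pop, 0.0, rng) is pop

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_out_of_range_fraction_raises(self, rng, bad):
        with pytest.raises(ParameterError):
            remove_fraction(np.zeros((10, 2)), bad, rng)
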