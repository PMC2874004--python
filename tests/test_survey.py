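import numpy as np
import pytest

from nestsim import (NestArena, PlacementError, SimConfig, Transect,
                     observations_to_frame, place_transects, read_observations,
                     run_survey, sampled_fraction, total_transect_length_m,
                     write_observations)


class TestPlacement:
    def test_13km_design_samples_quarter_percent(self, rng):
        cfg = SimConfig()
        tr = place_transects(13, 500, cfg, rng)   # 13 x 1 km x 20 m
        assert sampled_fraction(tr, cfg) == pytest.approx(0.0026)
        assert total_transect_length_m(tr, cfg) == pytest.approx(13_000)

    def test_low_effort_design_samples_006_percent(self, rng):
        cfg = SimConfig()
        tr = place_transects(6, 250, cfg, rng)    # 6 x 500 m
        assert sampled_fraction(tr, cfg) == pytest.approx(0.0006)

    @pytest.mark.parametrize("seed", range(5))
    def test_transects_disjoint_and_inside_grid(self, seed):
        cfg = SimConfig(grid_side=2000)
        trs = place_transects(40, 300, cfg, np.random.default_rng(seed))
        rects = [t.rect for t in trs]
        for i, a in enumerate(rects):
            assert 0 <= a[0] < a[1] <= 2000 and 0 <= a[2] < a[3] <= 2000
            for b in rects[i + 1:]:
                disjoint = (a[1] <= b[0] or b[1] <= a[0]
                            or a[3] <= b[2] or b[3] <= a[2])
                assert disjoint

    def test_grid_spanning_transect_fits(self, rng):
        cfg = SimConfig(grid_side=600)
        (tr,) = place_transects(1, 600, cfg, rng)
        x0, x1, y0, y1 = tr.rect
        assert x1 - x0 == 600 or y1 - y0 == 600

    def test_oversized_transect_raises(self, rng):
        with pytest.raises(PlacementError):
            place_transects(1, 700, SimConfig(grid_side=600), rng)

    def test_impossible_packing_raises(self, rng):
        cfg = SimConfig(grid_side=60)
        with pytest.raises(PlacementError):
            place_transects(40, 60, cfg, rng)  # 40 * 600 squares > 3600


def _arena_with_nests(n, stage, cfg, tagged=False):
    """n live nests in the given stage, all inside a known transect."""
    arena = NestArena(cfg.grid_side)
    assert n <= 5000, "helper supports at most 500 x 10 nests"
    xs = np.arange(n) % 500
    ys = np.arange(n) // 500
    idx = arena.add(xs, ys, 0, day=0, durations=np.full((n, 5), 50.0))
    arena.stage[idx] = stage
    arena.tagged[idx] = tagged
    transect = Transect(id=0, origin=(0, 0), orientation="horizontal",
                        length=500, width=10)
    return arena, transect


class TestRunSurvey:
    @pytest.mark.parametrize("stage,p", [(0, 0.9), (3, 0.85), (4, 0.8)])
    def test_stage_detection_probabilities(self, rng, stage, p):
        cfg = SimConfig()
        arena, tr = _arena_with_nests(2000, stage, cfg)
        rows = run_survey(arena, [tr], "incomplete", cfg, rng, 1, 1000)
        assert len(rows) == pytest.approx(2000 * p, abs=3 * np.sqrt(2000 * p * (1 - p)))
        assert all(r[4] == "ABCDE"[stage] and r[5] == 1 for r in rows)

    def test_complete_visibility_detects_099(self, rng):
        cfg = SimConfig()
        arena, tr = _arena_with_nests(2000, 3, cfg)
        rows = run_survey(arena, [tr], "complete", cfg, rng, 1, 1000)
        assert len(rows) == pytest.approx(1980, abs=3 * np.sqrt(2000 * 0.0099))

    def test_tagged_nests_always_recorded(self, rng):
        cfg = SimConfig()
        arena, tr = _arena_with_nests(500, 4, cfg, tagged=True)
        rows = run_survey(arena, [tr], "incomplete", cfg, rng, 2, 1030)
        assert len(rows) == 500
        assert all(r[5] == 0 for r in rows)  # tagged => not first detections

    def test_first_detection_set_exactly_once(self, rng):
        cfg = SimConfig()
        arena, tr = _arena_with_nests(1000, 1, cfg)
        rows1 = run_survey(arena, [tr], "incomplete", cfg, rng, 1, 1000)
        rows2 = run_survey(arena, [tr], "incomplete", cfg, rng, 2, 1030)
        seen1 = {r[3] for r in rows1}
        assert all(r[5] == 1 for r in rows1)
        for r in rows2:
            assert r[5] == (0 if r[3] in seen1 else 1)
        # tagging contract: everything recorded at survey 1 reappears
        assert seen1 <= {r[3] for r in rows2}

    def test_missed_twice_probability_compounds(self, rng):
        # stage-E nests (p=0.8): P(missed on both of two passes) = 0.04
        cfg = SimConfig()
        arena, tr = _arena_with_nests(5000, 4, cfg)
        for k in (1, 2):
            run_survey(arena, [tr], "incomplete", cfg, rng, k, 970 + 30 * k)
        never = 5000 - arena.tagged[:5000].sum()
        assert never == pytest.approx(5000 * 0.04, abs=3 * np.sqrt(5000 * 0.04))

    def test_nest_outside_transects_never_recorded(self, rng):
        cfg = SimConfig()
        arena = NestArena(cfg.grid_side)
        arena.add([100], [100], 0, 0, np.full((1, 5), 50.0))
        tr = Transect(id=0, origin=(0, 0), orientation="horizontal",
                      length=50, width=10)
        assert run_survey(arena, [tr], "complete", cfg, rng, 1, 1000) == []


class TestObservationTable:
    def test_frame_schema_and_csv_roundtrip(self, tmp_path, rng):
        cfg = SimConfig()
        arena, tr = _arena_with_nests(50, 2, cfg)
        rows = run_survey(arena, [tr], "complete", cfg, rng, 1, 1000)
        df = observations_to_frame(rows)
        path = tmp_path / "obs.csv"
        write_observations(df, path)
        back = read_observations(path)
        assert back.equals(df)

    def test_reader_rejects_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("survey_index,day\n1,1000\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_observations(path)
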