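import dataclasses

import numpy as np
import pytest

from nestsim import (EstimatorParams, FixtureSpec, InsufficientDataError,
                     ParameterError, SimConfig, Trajectory, Transect,
                     UndefinedDecayError, estimate_with_published_decay,
                     expected_decay_time, fit_transition_matrix,
                     make_observation_fixture, marked_recount_estimate,
                     matrix_estimate, nest_density, orangutan_density)
from nestsim.estimators import DISAPPEARED, TransitionModel


def params(**kw):
    base = dict(L=13_000.0, w=20.0, area=1e8, p=1.0, r=1.2, o=0.925)
    base.update(kw)
    return EstimatorParams(**base).validate()


class TestDensityArithmetic:
    @pytest.mark.parametrize("N,L,w,expected", [
        (26, 13_000, 20, 1.0e-4),
        (0, 13_000, 20, 0.0),
        (10, 1_000, 20, 5.0e-4),
    ])
    def test_nest_density_formula(self, N, L, w, expected):
        assert nest_density(N, L, w) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            nest_density(-1, 1000, 20)

    def test_orangutan_density_worked_example(self):
        d = orangutan_density(1.0e-4, params(t=30.0))
        assert d == pytest.approx(3.003e-6, rel=1e-3)
        assert d * 1e8 == pytest.approx(300.3, rel=1e-3)

    def test_identity_limit(self):
        p = params(o=1.0, r=1.0, t=1.0)
        assert orangutan_density(2.5e-4, p) == pytest.approx(2.5e-4)

    def test_true_density_recovers_200_individuals(self):
        # standing density of 2e-6 /m^2 over 100 km^2 is 200 individuals
        assert 2e-6 * 1e8 == pytest.approx(200)

    def test_missing_t_rejected(self):
        with pytest.raises(ParameterError):
            orangutan_density(1e-4, params())

    @pytest.mark.parametrize("field,value", [("o", 0.0), ("p", 1.5), ("r", -1)])
    def test_invalid_params_rejected(self, field, value):
        with pytest.raises(ParameterError):
            params(**{field: value})


class TestParamsForSurvey:
    def test_o_conventions(self):
        cfg = SimConfig()
        tr = [Transect(0, (0, 0), "horizontal", 500, 10)]
        marked = EstimatorParams.for_survey(cfg, tr, "marked", "incomplete")
        matrix = EstimatorParams.for_survey(cfg, tr, "matrix", "incomplete")
        assert marked.o == pytest.approx(0.925)   # mean of stages A and B
        assert matrix.o == pytest.approx(0.89)    # mean of all five stages
        complete = EstimatorParams.for_survey(cfg, tr, "marked", "complete")
        assert complete.o == pytest.approx(0.99)
        assert marked.L == pytest.approx(1000.0) and marked.w == pytest.approx(20.0)


def _fixture(*trajectories, n_surveys=3):
    spec = FixtureSpec(n_surveys=n_surveys, trajectories=tuple(trajectories))
    return make_observation_fixture(spec)


class TestMarkedRecount:
    def test_counts_only_new_nests_after_first_survey(self):
        obs, exp = _fixture(
            Trajectory(count=5, stages=("C", "C", "D"), first_survey=1),
            Trajectory(count=3, stages=("A", "B"), first_survey=2),
        )
        assert exp["marked_new_nests"] == 3
        rec = marked_recount_estimate(obs, params())
        assert rec.n_obs == 3
        assert rec.t_days == 60.0
        expected = 3 / (13_000 * 20) / (1.2 * 60 * 0.925) * 1e8
        assert rec.estimate == pytest.approx(expected)

    def test_zero_new_nests_gives_zero_estimate(self):
        obs, _ = _fixture(Trajectory(count=4, stages=("C", "C", "C")))
        rec = marked_recount_estimate(obs, params())
        assert rec.status == "ok" and rec.estimate == 0.0

    def test_single_survey_raises(self):
        obs, _ = _fixture(Trajectory(count=4, stages=("A",)), n_surveys=1)
        with pytest.raises(InsufficientDataError):
            marked_recount_estimate(obs, params())


class TestTransitionMatrix:
    def test_absorption_counted_from_tagged_absence(self):
        obs, _ = _fixture(Trajectory(count=1, stages=("E",), first_survey=1),
                          Trajectory(count=2, stages=("C", "C", "C")))
        model = fit_transition_matrix(obs)
        assert model.counts[4, DISAPPEARED] == 1
        assert model.counts[2, 2] == 4

    def test_stage_skipping_allowed(self):
        obs, _ = _fixture(Trajectory(count=1, stages=("B", "D", "D")))
        model = fit_transition_matrix(obs)
        assert model.counts[1, 3] == 1 and model.counts[3, 3] == 1

    def test_counts_match_fixture_ground_truth(self):
        obs, exp = _fixture(
            Trajectory(count=10, stages=("A", "B")),
            Trajectory(count=4, stages=("B", "C", "E")),
            Trajectory(count=2, stages=("D", "E", "E")),
        )
        model = fit_transition_matrix(obs)
        assert np.array_equal(model.counts, exp["transition_counts"])

    def test_no_decay_chain_is_singular(self):
        obs, _ = _fixture(Trajectory(count=10, stages=("A", "A", "A")))
        model = fit_transition_matrix(obs)
        assert model.Q[0, 0] == 1.0
        with pytest.raises(UndefinedDecayError):
            expected_decay_time(model)


def _model(counts):
    counts = np.asarray(counts)
    states = [s for s in range(5) if counts[s].sum() > 0]
    sub = counts[np.ix_(states, states)].astype(float)
    absorbed = counts[states, DISAPPEARED].astype(float)
    Q = sub / (sub.sum(axis=1) + absorbed)[:, None]
    return TransitionModel(counts=counts, states=states, Q=Q)


class TestExpectedDecayTime:
    def test_single_state_geometric_sojourn(self):
        # monthly stay probability 0.5 => 2 intervals => 60 d * 0.89 = 53.4 d
        counts = np.zeros((5, 6), int)
        counts[0, 0] = 5
        counts[0, DISAPPEARED] = 5
        assert expected_decay_time(_model(counts)) == pytest.approx(53.4)

    def test_two_state_hand_inverted_fundamental(self):
        # Q = [[.5,.5],[0,.5]] => (I-Q)^-1 = [[2,2],[0,2]], row-A sum 4
        counts = np.zeros((5, 6), int)
        counts[0, 0] = 2
        counts[0, 1] = 2
        counts[1, 1] = 2
        counts[1, DISAPPEARED] = 2
        assert expected_decay_time(_model(counts)) == pytest.approx(106.8)

    def test_no_absorption_raises(self):
        counts = np.zeros((5, 6), int)
        counts[0, 0] = 3
        with pytest.raises(UndefinedDecayError) as err:
            expected_decay_time(_model(counts))
        assert err.value.reason == "no-complete-decay"


class TestMatrixEstimate:
    def _obs(self):
        return _fixture(
            Trajectory(count=6, stages=("A", "B", "D")),
            Trajectory(count=4, stages=("C", "E")),
            Trajectory(count=5, stages=("E",)),
        )[0]

    def test_uses_mean_standing_count(self):
        obs = self._obs()
        rec = matrix_estimate(obs, params(o=0.89))
        per_survey = obs.groupby("survey_index").size()
        assert rec.n_obs == pytest.approx(per_survey.mean())
        assert rec.status == "ok" and rec.estimate > 0

    def test_estimate_times_t_invariant_in_t(self):
        obs = self._obs()
        p = params(o=0.89)
        e72 = estimate_with_published_decay(obs, 72.0, p)
        e424 = estimate_with_published_decay(obs, 424.0, p)
        assert e72.estimate * 72 == pytest.approx(e424.estimate * 424)
        assert e72.estimate / e424.estimate == pytest.approx(424 / 72)

    def test_undefined_decay_propagates_as_status(self):
        obs, _ = _fixture(Trajectory(count=10, stages=("A", "A", "A")))
        rec = matrix_estimate(obs, params(o=0.89))
        assert rec.status == "undefined"
        assert rec.reason == "no-complete-decay"
        assert rec.estimate is None

    def test_published_equals_fitted_when_same_decay_time(self):
        obs = self._obs()
        p = params(o=0.89)
        fitted = matrix_estimate(obs, p)
        borrowed = estimate_with_published_decay(obs, fitted.t_days, p)
        assert borrowed.estimate == pytest.approx(fitted.estimate)

    def test_nonpositive_assumed_decay_rejected(self):
        obs = self._obs()
        with pytest.raises(ParameterError):
            estimate_with_published_decay(obs, 0.0, params(o=0.89))
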