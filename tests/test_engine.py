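import math

import numpy as np
import pytest

from fcmalloc import (
    EngineConfig,
    FCMState,
    ParticipantRecord,
    ValidationError,
    WeightMatrix,
    expected_change,
    simulate,
    simulate_batch,
    step,
    transfer,
)

CHAIN_A = math.tanh(1.0)            # 0.76159...
CHAIN_OUT = math.tanh(CHAIN_A)      # 0.64201...


class TestTransfer:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0),
        (1.0, CHAIN_A),
        (-1.0, -CHAIN_A),
    ])
    def test_tanh_values(self, x, expected):
        assert transfer(x) == pytest.approx(expected, abs=1e-10)

    def test_slope_scales_argument(self):
        cfg = EngineConfig(slope=2.0)
        assert transfer(0.5, cfg) == pytest.approx(math.tanh(1.0))


class TestStep:
    def test_zero_matrix_zeroes_unclamped(self, chain_matrix):
        W = WeightMatrix(np.zeros((4, 4)), chain_matrix.concepts, "out",
                         "intervention")
        s = FCMState(values=np.array([0.3, 0.9, 0.4, 1.0]))
        nxt = step(W, s, {"intervention": 1.0})
        assert np.allclose(nxt.values[:3], 0.0)
        assert nxt.values[3] == 1.0

    def test_single_edge_propagation(self, chain_matrix):
        s = FCMState(values=np.array([0.0, 0.0, 0.0, 1.0]))
        nxt = step(chain_matrix, s, {"intervention": 1.0})
        assert nxt.values[0] == pytest.approx(CHAIN_A)

    def test_clamp_overrides_incoming_edges(self, chain_matrix):
        s = FCMState(values=np.array([0.9, 0.0, 0.0, 1.0]))
        nxt = step(chain_matrix, s, {"intervention": 1.0, "a": 0.25})
        assert nxt.values[0] == 0.25

    def test_unknown_clamp_label(self, chain_matrix):
        s = FCMState(values=np.zeros(4))
        with pytest.raises(ValidationError):
            step(chain_matrix, s, {"nope": 1.0})


class TestSimulate:
    def test_zero_matrix_fixed_point(self, chain_matrix):
        W = WeightMatrix(np.zeros((4, 4)), chain_matrix.concepts, "out",
                         "intervention")
        final = simulate(W, np.array([0.3, 0.9, 0.4, 0.0]),
                         {"intervention": 1.0})
        assert final.converged
        assert final.iteration <= 2
        assert np.allclose(final.values[:3], 0.0)

    def test_chain_fixed_point(self, chain_matrix):
        final = simulate(chain_matrix, np.array([0.0, 0.5, 0.2, 0.0]),
                         {"intervention": 1.0})
        assert final.converged
        assert final.values[0] == pytest.approx(CHAIN_A, abs=1e-5)
        assert final.values[2] == pytest.approx(CHAIN_OUT, abs=1e-5)

    def test_converged_state_is_a_fixed_point(self, chain_matrix):
        cfg = EngineConfig()
        final = simulate(chain_matrix, np.array([0.1, 0.8, 0.9, 0.0]),
                         {"intervention": 1.0}, cfg)
        again = step(chain_matrix, final, {"intervention": 1.0}, cfg)
        assert np.abs(again.values - final.values).max() < cfg.tol

    def test_trajectory_starts_at_initial_state(self, chain_matrix):
        final, traj = simulate(chain_matrix, np.array([0.0, 0.0, 0.0, 0.0]),
                               {"intervention": 1.0}, return_trajectory=True)
        assert traj[0][3] == 1.0  # clamp applied before first step
        assert np.allclose(traj[-1], final.values)

    def test_batch_matches_single_runs(self, chain_matrix):
        rng = np.random.default_rng(7)
        inits = rng.uniform(0, 1, size=(5, 4))
        vals, conv, _ = simulate_batch(chain_matrix, inits, {"intervention": 1.0})
        for i in range(5):
            single = simulate(chain_matrix, inits[i], {"intervention": 1.0})
            assert np.allclose(vals[i], single.values, atol=1e-12)
            assert conv[i] == single.converged


class TestExpectedChange:
    def test_chain_expected_change(self, chain_matrix):
        rec = ParticipantRecord("P1", {"a": 0.8, "b": 0.1})
        ec = expected_change(chain_matrix, rec)
        assert ec.value == pytest.approx(CHAIN_OUT, abs=1e-5)
        assert ec.converged_with and ec.converged_without

    def test_zero_block_gives_zero_change(self, chain_matrix):
        W = WeightMatrix(np.zeros((4, 4)), chain_matrix.concepts, "out",
                         "intervention")
        rec = ParticipantRecord("P1", {"a": 0.8, "b": 0.1})
        assert expected_change(W, rec).value == 0.0

    def test_flipped_intervention_sign_negates_chain(self, chain_matrix):
        Wneg = np.array(chain_matrix.weights)
        Wneg[3, 0] = -1.0
        W = WeightMatrix(Wneg, chain_matrix.concepts, "out", "intervention")
        rec = ParticipantRecord("P1", {"a": 0.3, "b": 0.6})
        assert expected_change(W, rec).value == pytest.approx(-CHAIN_OUT, abs=1e-5)

    def test_small_slope_kills_expected_change(self, chain_matrix):
        rec = ParticipantRecord("P1", {"a": 0.8, "b": 0.1})
        e = expected_change(chain_matrix, rec, EngineConfig(slope=1e-4)).value
        assert abs(e) < 1e-3

    def test_values_bounded_by_tanh(self, chain_matrix):
        rng = np.random.default_rng(0)
        inits = rng.uniform(0, 1, size=(20, 4))
        vals, _, _ = simulate_batch(chain_matrix, inits, {"intervention": 1.0})
        assert np.all(np.abs(vals) <= 1.0)

    def test_concept_permutation_equivariance(self, small_design, scale):
        from fcmalloc import build_weight_matrix, RelationshipAnswer
        rng = np.random.default_rng(3)
        answers = []
        terms = scale.terms
        for s, t in sorted(small_design.active_relationships):
            for p in range(4):
                answers.append(RelationshipAnswer(
                    f"P{p}", s, t, terms[rng.integers(5)],
                    int(rng.choice([-1, 1]))))
        W = build_weight_matrix(small_design, answers, scale)
        rec = ParticipantRecord("P1", {"a": 0.8, "b": 0.1, "c": 0.5})
        e1 = expected_change(W, rec).value
        # permute concept order in the matrix
        perm = [2, 0, 1, 3, 4]
        Wp = WeightMatrix(
            W.weights[np.ix_(perm, perm)],
            tuple(W.concepts[i] for i in perm), W.outcome, W.intervention)
        e2 = expected_change(Wp, rec).value
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_missing_factor_rejected(self, chain_matrix):
        rec = ParticipantRecord("P1", {"a": 0.8, "b": None})
        with pytest.raises(ValidationError):
            expected_change(chain_matrix, rec)
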