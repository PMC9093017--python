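import itertools

import numpy as np
import pandas as pd
import pytest

from orfunc import (
    GeneratorConfig,
    InsufficientDataError,
    OrthologAlignment,
    ResponseMatrix,
    loo_evaluate,
    predict_response,
    shuffled_control,
    similarity_at_positions,
)
from orfunc.prediction import _weighted_predictions
from orfunc.simulate import generate_dataset


class TestSimilarity:
    def test_self_similarity_is_one(self, toy_alignment):
        assert similarity_at_positions(toy_alignment, [1, 2, 3], "R1", "R1") == 1.0

    def test_hand_counts(self, toy_alignment):
        assert similarity_at_positions(toy_alignment, [2], "R1", "R3") == 0.0
        assert similarity_at_positions(toy_alignment, [1, 2], "R1", "R3") == 0.5

    def test_all_gapped_positions_give_zero(self):
        aln = OrthologAlignment((("a", "-AK"), ("b", "-VK")), "a")
        assert similarity_at_positions(aln, [1], "a", "b") == 0.0

    def test_position_weights_shift_the_fraction(self, toy_alignment):
        # columns 1 and 2: match at 1, mismatch at 2; weight column 2 heavier
        s = similarity_at_positions(toy_alignment, [1, 2], "R1", "R3", [1.0, 3.0])
        assert s == pytest.approx(0.25)


class TestPredictResponse:
    def test_unique_similar_receptor_dominates(self, toy_alignment, toy_responses):
        pred = predict_response(
            toy_alignment, toy_responses.drop("R4"), [2], "R4", alpha=1.0
        )
        np.testing.assert_allclose(pred.to_numpy(), [0.0, 100.0])

    def test_constant_training_rows_predict_the_constant(self, toy_alignment):
        m = ResponseMatrix(
            pd.DataFrame(
                np.full((3, 2), 42.0), index=["R1", "R2", "R3"], columns=["o1", "o2"]
            )
        )
        pred = predict_response(toy_alignment, m, [2], "R4")
        np.testing.assert_allclose(pred.to_numpy(), 42.0)

    def test_zero_weights_fall_back_to_unweighted_mean(self):
        aln = OrthologAlignment(
            (("a", "AAA"), ("b", "AAA"), ("c", "AAA"), ("h", "VVV")), "a"
        )
        m = ResponseMatrix(
            pd.DataFrame(
                [[0.0], [30.0], [60.0]], index=["a", "b", "c"], columns=["o1"]
            )
        )
        pred = predict_response(aln, m, [1, 2, 3], "h")
        assert pred["o1"] == pytest.approx(30.0)

    def test_insufficient_training_receptors(self):
        aln = OrthologAlignment((("a", "AAA"), ("h", "VVV")), "a")
        m = ResponseMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["o1"]))
        with pytest.raises(InsufficientDataError):
            predict_response(aln, m, [1], "h")

    def test_prediction_is_convex_in_training_responses(self, planted_dataset):
        aln, m = planted_dataset.alignment, planted_dataset.responses
        heldout = aln.receptor_ids[3]
        train = [r for r in aln.receptor_ids if r != heldout]
        pred = predict_response(aln, m.drop(heldout), list(range(1, 21)), heldout)
        lo = m.data.loc[train].min(axis=0)
        hi = m.data.loc[train].max(axis=0)
        assert ((pred >= lo - 1e-9) & (pred <= hi + 1e-9)).all()


class TestShuffledControl:
    def test_identical_training_rows_make_control_equal_model(self, toy_alignment):
        m = ResponseMatrix(
            pd.DataFrame(
                np.full((4, 2), 13.0),
                index=["R1", "R2", "R3", "R4"],
                columns=["o1", "o2"],
            )
        )
        pred = predict_response(toy_alignment, m.drop("R4"), [2], "R4")
        control, d_ctrl = shuffled_control(toy_alignment, m, [2], "R4", n_shuffles=10)
        np.testing.assert_allclose(control.to_numpy(), pred.to_numpy())
        np.testing.assert_allclose(d_ctrl.to_numpy(), (pred - m.row("R4")).abs().to_numpy())

    def test_equal_weights_make_shuffling_a_no_op(self, toy_responses):
        # held-out differs from every training receptor at the scored column,
        # so all weights hit the unweighted-mean fallback for every shuffle
        aln = OrthologAlignment(
            (("R1", "MAKG"), ("R2", "MAKG"), ("R3", "MAKG"), ("R4", "MVKG")), "R1"
        )
        pred = predict_response(aln, toy_responses.drop("R4"), [2], "R4")
        _, d_ctrl = shuffled_control(aln, toy_responses, [2], "R4", n_shuffles=24)
        d_pred = (pred - toy_responses.row("R4")).abs()
        np.testing.assert_allclose(d_ctrl.to_numpy(), d_pred.to_numpy())

    def test_exhaustive_enumeration_matches_oracle(self, toy_alignment, toy_responses):
        # 3 training receptors -> 6 permutations, enumerated exactly once
        train = ["R1", "R2", "R3"]
        w = np.array(
            [similarity_at_positions(toy_alignment, [2], "R4", j) for j in train]
        ) ** 10.0
        resp = toy_responses.data.loc[train].to_numpy()
        actual = toy_responses.row("R4").to_numpy()
        errs = []
        for perm in itertools.permutations(range(3)):
            pred = _weighted_predictions(resp[list(perm)], w)
            errs.append(np.abs(pred - actual))
        expected = np.mean(errs, axis=0)
        _, d_ctrl = shuffled_control(
            toy_alignment, toy_responses, [2], "R4", n_shuffles=6
        )
        np.testing.assert_allclose(d_ctrl.to_numpy(), expected)


class TestLooEvaluate:
    def test_planted_signal_beats_control(self, planted_dataset):
        rep = loo_evaluate(
            planted_dataset.alignment, planted_dataset.responses, n_shuffles=200, seed=7
        )
        assert rep.mean_d_pred < rep.mean_d_ctrl
        assert rep.improvement_percent > 0
        assert (rep.entries["d_pred"] >= 0).all()
        assert (rep.entries["d_ctrl"] >= 0).all()
        # overall means recompute from entries
        assert rep.mean_d_pred == pytest.approx(rep.entries["d_pred"].mean())
        assert rep.improvement_percent == pytest.approx(
            100 * (rep.mean_d_ctrl - rep.mean_d_pred) / rep.mean_d_ctrl
        )

    def test_reproducible_and_order_invariant(self, planted_dataset, rng):
        aln, m = planted_dataset.alignment, planted_dataset.responses
        rep1 = loo_evaluate(aln, m, n_shuffles=50, seed=3)
        rep2 = loo_evaluate(aln, m, n_shuffles=50, seed=3)
        pd.testing.assert_frame_equal(rep1.entries, rep2.entries)

        perm = list(rng.permutation(list(aln.receptor_ids)))
        rep3 = loo_evaluate(aln.reorder(perm), m.reorder(perm), n_shuffles=50, seed=3)
        pd.testing.assert_frame_equal(rep3.entries, rep1.entries)

    def test_two_receptors_rejected(self):
        aln = OrthologAlignment((("a", "AAK"), ("b", "AVK")), "a")
        m = ResponseMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["o1"])
        )
        with pytest.raises(InsufficientDataError):
            loo_evaluate(aln, m)
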