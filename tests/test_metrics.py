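"""Loss and metric closed forms against hand computations and loop oracles."""

import numpy as np
import pytest

from spinet.grad import Tensor
from spinet.metrics import (
    SegMetrics,
    compute_metrics,
    confusion,
    total_loss,
    vacancy_ratio,
    vacancy_ratio_error,
    weighted_ce_loss,
)

LN3 = float(np.log(3.0))


class TestWeightedCrossEntropy:
    def test_uniform_logits_single_pixel_closed_forms(self):
        """For x=(0,0,0) the per-pixel loss is weight[class]·ln 3."""
        logits = np.zeros((1, 3, 1, 1))
        w = (0.8, 1.0, 1.2)
        got1 = weighted_ce_loss(logits, np.array([[[1]]]), w, reduction="mean").item()
        got2 = weighted_ce_loss(logits, np.array([[[2]]]), w, reduction="mean").item()
        assert got1 == pytest.approx(1.0 * LN3, abs=1e-4)   # 1.0986
        assert got2 == pytest.approx(1.2 * LN3, abs=1e-4)   # 1.3183
        # the default reduction normalizes by the applied weight instead
        assert weighted_ce_loss(logits, np.array([[[2]]]), w).item() == \
            pytest.approx(LN3, abs=1e-6)

    def test_perfect_confidence_drives_loss_to_zero(self):
        logits = np.zeros((1, 3, 1, 1))
        logits[0, 1] = 50.0
        assert weighted_ce_loss(logits, np.array([[[1]]])).item() < 1e-6

    def test_uniform_weights_match_standard_cross_entropy(self):
        """With equal class weights the loss reduces to plain multinomial
        cross-entropy (closed form via scipy's log-softmax)."""
        from scipy.special import log_softmax
        rng = np.random.default_rng(0)
        for _ in range(100):
            logits = rng.normal(scale=3.0, size=(1, 3, 4, 5))
            mask = rng.integers(0, 3, size=(1, 4, 5))
            ours = weighted_ce_loss(logits, mask, (1.0, 1.0, 1.0)).item()
            ls = log_softmax(logits, axis=1)
            expect = -np.take_along_axis(ls, mask[:, None], axis=1).mean()
            assert ours == pytest.approx(expect, abs=1e-8)

    def test_weighted_reduction_is_weight_normalized_mean(self):
        # two pixels of class 1 and 2 with x=(0,0,0): (1·ln3 + 1.2·ln3)/(1+1.2)
        logits = np.zeros((1, 3, 1, 2))
        mask = np.array([[[1, 2]]])
        got = weighted_ce_loss(logits, mask, (0.8, 1.0, 1.2)).item()
        assert got == pytest.approx((1.0 + 1.2) * LN3 / 2.2, abs=1e-6)

    def test_large_logits_remain_finite(self):
        logits = np.zeros((1, 3, 1, 1))
        logits[0, 0] = 1000.0
        assert np.isfinite(weighted_ce_loss(logits, np.array([[[0]]])).item())

    def test_non_finite_logits_rejected(self):
        logits = np.full((1, 3, 1, 1), np.nan)
        with pytest.raises(ValueError, match="finite"):
            weighted_ce_loss(logits, np.array([[[0]]]))

    def test_gradient_flows_to_logits(self):
        x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 2, 2)), requires_grad=True)
        weighted_ce_loss(x, np.zeros((1, 2, 2), int)).backward()
        assert np.abs(x.grad).max() > 0


class TestTotalLoss:
    def test_zero_aux_lambda_equals_main_loss(self):
        rng = np.random.default_rng(2)
        main = rng.normal(size=(1, 3, 3, 3))
        aux = rng.normal(size=(1, 3, 3, 3))
        mask = rng.integers(0, 3, size=(1, 3, 3))
        assert total_loss(main, aux, mask, aux_lambda=0.0).item() == \
            pytest.approx(weighted_ce_loss(main, mask).item())

    def test_equal_losses_scale_by_one_plus_lambda(self):
        logits = np.zeros((1, 3, 2, 2))
        mask = np.ones((1, 2, 2), int)
        got = total_loss(logits, logits, mask, aux_lambda=0.4).item()
        assert got == pytest.approx(1.4 * LN3, abs=1e-6)

    def test_total_never_below_main(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            main = rng.normal(size=(1, 3, 3, 3))
            aux = rng.normal(size=(1, 3, 3, 3))
            mask = rng.integers(0, 3, size=(1, 3, 3))
            assert total_loss(main, aux, mask).item() >= \
                weighted_ce_loss(main, mask).item() - 1e-12

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            total_loss(np.zeros((1, 3, 1, 1)), None, np.zeros((1, 1, 1), int),
                       aux_lambda=-0.1)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        m = np.array([[0, 1], [2, 1]])
        cm = confusion(m, m)
        assert cm.sum() == 4 and np.all(cm == np.diag([1, 2, 1]))

    def test_hand_counted_example(self):
        ref = np.array([1, 1, 2, 0])
        pred = np.array([1, 2, 2, 0])
        cm = confusion(pred, ref)
        expect = np.zeros((3, 3), int)
        expect[0, 0] = expect[1, 1] = expect[1, 2] = expect[2, 2] = 1
        np.testing.assert_array_equal(cm, expect)

    def test_total_count_conserved(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 3, size=(17, 13))
        pred = rng.integers(0, 3, size=(17, 13))
        assert confusion(pred, ref).sum() == 17 * 13

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), int), np.zeros((3, 3), int))


class TestComputeMetrics:
    def test_perfect_prediction_metrics(self):
        m = compute_metrics(np.diag([10, 80, 10]))
        assert m.pixel_accuracy == 1.0 and m.miou == 1.0 and m.vr_error == 0.0

    def test_four_pixel_worked_example(self):
        """ref [1,1,2,0] vs pred [1,2,2,0]: PA=0.75, IoUs=(1,0.5,0.5), mIoU=2/3."""
        cm = confusion(np.array([1, 2, 2, 0]), np.array([1, 1, 2, 0]))
        m = compute_metrics(cm)
        assert m.pixel_accuracy == pytest.approx(0.75)
        assert m.iou_per_class == pytest.approx((1.0, 0.5, 0.5))
        assert m.miou == pytest.approx(2.0 / 3.0)

    def test_vacancy_ratio_error_hand_example(self):
        """VR_f=0.10 vs VR_p=0.093 gives a relative error of exactly 0.07."""
        assert vacancy_ratio_error(0.10, 0.093) == pytest.approx(0.07)
        cm = np.array([[0, 0, 0], [900, 900, 0], [100, 7, 93]])
        m = compute_metrics(cm)
        assert m.vr_true == pytest.approx(0.10)
        assert m.vr_pred == pytest.approx(0.093)
        assert m.vr_error == pytest.approx(0.07)

    def test_undefined_vacancy_ratio_flagged_not_zero(self):
        # no reference vacancy at all -> VR_f = 0 -> error undefined
        m = compute_metrics(np.diag([5, 5, 0]))
        assert m.vr_true == 0.0 and m.vr_error is None
        # no crop or vacancy anywhere -> VR undefined
        m2 = compute_metrics(np.array([[9, 0, 0], [0, 0, 0], [0, 0, 0]]))
        assert m2.vr_true is None and m2.vr_error is None
        assert vacancy_ratio(0, 0) is None

    def test_metrics_are_scale_free(self):
        cm = np.array([[5, 1, 0], [2, 40, 3], [0, 2, 7]])
        a, b = compute_metrics(cm), compute_metrics(cm * 17)
        assert a.pixel_accuracy == pytest.approx(b.pixel_accuracy)
        assert a.miou == pytest.approx(b.miou)
        assert a.vr_error == pytest.approx(b.vr_error)

    def test_error_decreases_as_true_ratio_grows_at_fixed_gap(self):
        """The relative form is forgiving at high vacancy rates: for a fixed
        |VR_f − VR_p| the error strictly decreases in VR_f."""
        gap = 0.02
        errors = [vacancy_ratio_error(vrf, vrf - gap)
                  for vrf in np.linspace(0.03, 0.5, 25)]
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_miou_ignores_absent_classes(self):
        cm = np.array([[10, 0, 0], [0, 20, 0], [0, 0, 0]])   # no vacancy anywhere
        m = compute_metrics(cm)
        assert np.isnan(m.iou_per_class[2])
        assert m.miou == pytest.approx(1.0)

    def test_agrees_with_per_pixel_loop_oracle_on_random_masks(self):
        """Confusion-matrix metrics equal a naive per-pixel loop on 100 pairs."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            ref = rng.integers(0, 3, size=(6, 6))
            pred = rng.integers(0, 3, size=(6, 6))
            m = compute_metrics(confusion(pred, ref))
            correct = sum(int(pred[i, j] == ref[i, j])
                          for i in range(6) for j in range(6))
            assert m.pixel_accuracy == pytest.approx(correct / 36)
            for k in range(3):
                inter = sum(int(pred[i, j] == k and ref[i, j] == k)
                            for i in range(6) for j in range(6))
                union = sum(int(pred[i, j] == k or ref[i, j] == k)
                            for i in range(6) for j in range(6))
                if union:
                    assert m.iou_per_class[k] == pytest.approx(inter / union)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.zeros((3, 3)))
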