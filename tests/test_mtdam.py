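"""Dual-branch model: losses, matching, fusion equivalence, training."""

import itertools

import numpy as np
import pytest

from cdpd.autodiff import Tensor
from cdpd.dynamic_augmentation import scenes_to_batch
from cdpd.mtdam import (Detections, TrainConfig, cell_assignment,
                        detection_train_loss, dice_loss, forward_fused, iou,
                        iou_matrix, make_dual_branch_model, make_optimizer,
                        make_toy_backbone, match_boxes, total_train_loss,
                        train_step)
from cdpd.nn import SGD
from cdpd.synthetic_scenes import LabeledScene


def make_detections(boxes, class_probs, conf):
    return Detections(boxes=Tensor(np.asarray(boxes, float).reshape(-1, 4)),
                      class_probs=Tensor(np.asarray(class_probs, float)),
                      confidence=Tensor(np.asarray(conf, float).reshape(-1)))


def make_scene(boxes, class_ids, size=48):
    mask = np.zeros((size, size), dtype=int)
    for (x0, y0, x1, y1), c in zip(boxes, class_ids):
        mask[int(y0):int(y1), int(x0):int(x1)] = c + 1
    return LabeledScene(image=np.zeros((size, size, 3)),
                        boxes=np.asarray(boxes, float).reshape(-1, 4),
                        class_ids=np.asarray(class_ids, int), mask=mask)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_direct_value(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-9)

    def test_degenerate_box_gives_zero(self):
        assert iou((1, 1, 1, 3), (0, 0, 2, 2)) == 0.0


class TestMatchBoxes:
    def test_perfect_pairing(self):
        boxes = np.array([[0, 0, 4, 4], [10, 10, 14, 14]], float)
        pairs = match_boxes(boxes, boxes)
        assert pairs == [(0, 0), (1, 1)]

    def test_no_predictions(self):
        assert match_boxes(np.zeros((0, 4)), np.array([[0, 0, 2, 2]])) == []

    def test_matches_exhaustive_assignment_oracle(self):
        rng = np.random.default_rng(1)   # a case with 2 overlapping pairs
                                         # and no IoU ties
        preds = np.stack([_rand_box(rng) for _ in range(3)])
        tgts = np.stack([_rand_box(rng) for _ in range(3)])
        pairs = match_boxes(preds, tgts, iou_threshold=0.0)
        mat = iou_matrix(preds, tgts)
        best, best_total = [], -1.0
        for perm in itertools.permutations(range(3)):
            pl = [(p, t) for p, t in enumerate(perm) if mat[p, t] > 0.0]
            total = sum(mat[p, t] for p, t in pl)
            if total > best_total:
                best, best_total = pl, total
        assert sorted(pairs) == sorted(best)

    def test_below_threshold_unmatched(self):
        preds = np.array([[0, 0, 4, 4]], float)
        tgts = np.array([[3, 3, 7, 7]], float)   # IoU = 1/31
        assert match_boxes(preds, tgts, iou_threshold=0.5) == []


def _rand_box(rng, size=48):
    x0, y0 = rng.uniform(0, size - 12, 2)
    w, h = rng.uniform(6, 12, 2)
    return np.array([x0, y0, x0 + w, y0 + h])


class TestDetectionLoss:
    def test_perfect_predictions_vanish(self):
        boxes = [[4, 4, 12, 12], [20, 20, 30, 30]]
        scene = make_scene(boxes, [0, 1])
        probs = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        det = make_detections(boxes, probs, [1.0, 1.0])
        assert float(detection_train_loss(det, scene).data) == \
            pytest.approx(0.0, abs=1e-5)

    def test_single_pair_half_probability(self):
        # one class, identical boxes, p_cls = 0.5, p_conf = 1
        boxes = [[4, 4, 12, 12]]
        scene = make_scene(boxes, [0])
        det = make_detections(boxes, [[0.5]], [1.0])
        assert float(detection_train_loss(det, scene).data) == \
            pytest.approx(-np.log(0.5), abs=1e-5)

    def test_no_matches_worst_case_iou_term(self):
        scene = make_scene([[30, 30, 40, 40]], [0])
        det = make_detections([[0, 0, 5, 5]], [[0.5, 0.2, 0.1]], [0.5])
        loss = float(detection_train_loss(det, scene).data)
        # cls term 0, IoU term 1, conf BCE of 0.5 against 0
        assert loss == pytest.approx(1.0 - np.log(0.5), abs=1e-6)

    def test_matches_loop_oracle(self, rng):
        eps = 1e-7
        for _ in range(100):
            n_pred, n_tgt, k = 3, 3, 3
            pred_boxes = np.stack([_rand_box(rng) for _ in range(n_pred)])
            tgt_boxes = np.stack([_rand_box(rng) for _ in range(n_tgt)])
            probs = rng.uniform(0.05, 0.95, (n_pred, k))
            conf = rng.uniform(0.05, 0.95, n_pred)
            cids = rng.integers(0, k, n_tgt)
            scene = make_scene(tgt_boxes, cids)
            det = make_detections(pred_boxes, probs, conf)
            pairing = match_boxes(pred_boxes, tgt_boxes, 0.1)
            got = float(detection_train_loss(det, scene, pairing=pairing).data)

            # independent loop computation
            if pairing:
                cls = 0.0
                ious = []
                for p, t in pairing:
                    for c in range(k):
                        y = 1.0 if c == cids[t] else 0.0
                        pr = min(max(probs[p, c], eps), 1 - eps)
                        cls -= y * np.log(pr) + (1 - y) * np.log(1 - pr)
                    ious.append(iou(pred_boxes[p], tgt_boxes[t]))
                cls /= len(pairing)
                iou_term = 1.0 - np.mean(ious)
            else:
                cls, iou_term = 0.0, 1.0
            conf_term = 0.0
            matched_p = {p for p, _ in pairing}
            for p in range(n_pred):
                y = 1.0 if p in matched_p else 0.0
                pr = min(max(conf[p], eps), 1 - eps)
                conf_term -= (y * np.log(pr) + (1 - y) * np.log(1 - pr)) / n_pred
            assert got == pytest.approx(cls + iou_term + conf_term, abs=1e-6)


class TestDiceLoss:
    def test_perfect_mask(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1.0
        assert float(dice_loss(Tensor(t), t).data) == pytest.approx(0.0, abs=1e-12)

    def test_empty_prediction_on_nonempty_target(self):
        t = np.zeros((8, 8))
        t[0, 0] = 1.0
        assert float(dice_loss(Tensor(np.zeros((8, 8))), t).data) == 1.0

    def test_both_empty_is_zero(self):
        assert float(dice_loss(Tensor(np.zeros((4, 4))), np.zeros((4, 4))).data) \
            == 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(size=(16, 16))
            t = rng.integers(0, 2, (16, 16)).astype(float)
            num = den_p = den_t = 0.0
            for i in range(16):
                for j in range(16):
                    num += p[i, j] * t[i, j]
                    den_p += p[i, j] ** 2
                    den_t += t[i, j] ** 2
            expected = 1.0 - 2 * num / (den_p + den_t)
            assert float(dice_loss(Tensor(p), t).data) == \
                pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.zeros((4, 4))), np.zeros((5, 5)))


class TestTotalLoss:
    def test_zero_weight_reduces_to_main(self):
        assert float(total_train_loss(Tensor(0.7), Tensor(0.3), 0.0).data) == 0.7

    def test_weighted_sum(self):
        assert float(total_train_loss(Tensor(0.5), Tensor(0.25), 1.0).data) == 0.75

    def test_linear_in_lambda(self):
        l_main, l_aux = Tensor(0.4), Tensor(0.9)
        v1 = float(total_train_loss(l_main, l_aux, 1.0).data)
        v2 = float(total_train_loss(l_main, l_aux, 2.0).data)
        assert v2 - v1 == pytest.approx(0.9, abs=1e-12)


class TestForward:
    def test_identity_fusion_equals_independent_branches(self, rng):
        model = make_dual_branch_model(3, image_size=48, seed=5)
        model.zero_fusion()
        images = Tensor(rng.uniform(size=(2, 3, 48, 48)))
        dets_f, mask_f = forward_fused(model, images, fusion=True)
        dets_i, mask_i = forward_fused(model, images, fusion=False)
        assert np.array_equal(mask_f.data, mask_i.data)
        for df, di in zip(dets_f, dets_i):
            assert np.array_equal(df.boxes.data, di.boxes.data)
            assert np.array_equal(df.confidence.data, di.confidence.data)
            assert np.array_equal(df.class_probs.data, di.class_probs.data)

    def test_mask_shape_and_range(self, rng):
        model = make_dual_branch_model(3, image_size=48, seed=1)
        _, mask = forward_fused(model, Tensor(rng.uniform(size=(2, 3, 48, 48))))
        assert mask.shape == (2, 48, 48)
        assert mask.data.min() >= 0 and mask.data.max() <= 1

    def test_forward_deterministic(self, rng):
        model = make_dual_branch_model(3, image_size=48, seed=2)
        images = Tensor(rng.uniform(size=(1, 3, 48, 48)))
        d1, m1 = forward_fused(model, images)
        d2, m2 = forward_fused(model, images)
        assert np.array_equal(m1.data, m2.data)
        assert np.array_equal(d1[0].boxes.data, d2[0].boxes.data)


class TestTraining:
    def test_zero_lr_leaves_parameters_unchanged(self, toy_scenes):
        cfg = TrainConfig(epochs=1, image_size=48, batch_size=8, seed=0)
        model = make_dual_branch_model(3, image_size=48, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        opt = SGD({"main": (model.main_parameters(), 0.0),
                   "aux": (model.aux_parameters(), 0.0),
                   "dag": (model.dag_parameters(), 0.0)})
        train_step(model, toy_scenes, cfg, opt)
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_one_step_descends_total_loss(self, toy_scenes):
        cfg = TrainConfig(epochs=1, image_size=48, batch_size=8,
                          lr_init=1e-3, lr_final=1e-3, dag_lr=1e-3,
                          momentum=0.0, seed=0)
        model = make_dual_branch_model(3, image_size=48, seed=0)
        opt = make_optimizer(model, cfg)
        r0 = train_step(model, toy_scenes, cfg, opt)
        r1 = train_step(model, toy_scenes, cfg, opt)
        assert r1["loss_total"] < r0["loss_total"]

    def test_frozen_dag_group_bitwise_unchanged(self, toy_scenes):
        cfg = TrainConfig(epochs=1, image_size=48, batch_size=8, seed=0)
        model = make_dual_branch_model(3, image_size=48, seed=0)
        gates_before = [p.data.copy() for p in model.dag_parameters()]
        opt = SGD({"main": (model.main_parameters(), 0.01),
                   "aux": (model.aux_parameters(), 0.01),
                   "dag": (model.dag_parameters(), 0.0)})
        train_step(model, toy_scenes, cfg, opt)
        for before, p in zip(gates_before, model.dag_parameters()):
            assert np.array_equal(before, p.data)

    def test_cell_assignment_places_targets_in_their_cells(self):
        scene = make_scene([[4, 4, 12, 12], [30, 30, 44, 44]], [0, 1])
        pairs = cell_assignment(scene, grid=6, image_size=48)
        assert (1 * 6 + 1, 0) in pairs   # centre (8, 8) -> cell (1, 1)
        assert (4 * 6 + 4, 1) in pairs   # centre (37, 37) -> cell (4, 4)


class TestToyBackbone:
    def test_shapes_and_determinism(self, rng):
        stages = make_toy_backbone(3, [4, 8, 8], seed=3)
        x = Tensor(rng.uniform(size=(1, 3, 64, 64)))
        shapes = []
        for s in stages:
            x = s(x)
            shapes.append(x.shape)
        assert shapes == [(1, 4, 32, 32), (1, 8, 16, 16), (1, 8, 8, 8)]
        again = make_toy_backbone(3, [4, 8, 8], seed=3)
        for a, b in zip(stages, again):
            assert np.array_equal(a.conv.weight.data, b.conv.weight.data)

    def test_forward_backward_finite(self, rng):
        stages = make_toy_backbone(2, [4, 4], seed=1)
        x = Tensor(rng.normal(size=(2, 3, 16, 16)), requires_grad=True)
        out = stages[1](stages[0](x)).sum()
        out.backward()
        assert np.all(np.isfinite(x.grad))
        for s in stages:
            assert np.all(np.isfinite(s.conv.weight.grad))
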