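"""Two-stage detector: determinism, wiring of the dynamic components,
classification loss, overfitting behavior and the inference contract."""

import numpy as np
import pytest

from dyndet.data_synth import PhantomConfig, generate_dataset
from dyndet.detector import (
    Detector,
    DetectorConfig,
    build_detector,
    nms,
    softmax_classification_loss,
    train_detector,
)
from dyndet.exceptions import ConfigError, InvalidInputError
from dyndet.scheduler import iou, iou_matrix


def tiny_config(**kwargs):
    defaults = dict(input_size=96, seed=0, cadence=5)
    defaults.update(kwargs)
    return DetectorConfig(**defaults)


class TestBuild:
    def test_same_seed_gives_identical_parameters(self):
        a = build_detector(tiny_config())
        b = build_detector(tiny_config())
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert pa.data.tobytes() == pb.data.tobytes()

    def test_different_seed_differs(self):
        a = build_detector(tiny_config(seed=0))
        b = build_detector(tiny_config(seed=1))
        assert any(pa.data.tobytes() != pb.data.tobytes()
                   for pa, pb in zip(a.parameters(), b.parameters()))

    def test_scconv_parameter_delta_is_analytic(self):
        """Replacing the 3x3 RPN conv (C^2*9 weights + C biases) with the
        bias-free four-group block (4*(C/2)^2*9 = C^2*9 weights) removes
        exactly C parameters for C=64."""
        with_sc = build_detector(tiny_config(use_scconv=True,
                                             scconv_placement=("rpn",)))
        without = build_detector(tiny_config(use_scconv=False))
        c = 64
        expected_delta = (4 * (c // 2) ** 2 * 9) - (c * c * 9 + c)
        assert with_sc.n_parameters() - without.n_parameters() == expected_delta

    def test_input_size_must_match_stride(self):
        with pytest.raises(ConfigError):
            build_detector(tiny_config(input_size=100))

    def test_invalid_scconv_placement_rejected(self):
        with pytest.raises(ConfigError):
            build_detector(tiny_config(scconv_placement=("fpn",)))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            build_detector(tiny_config(backbone="resnet50"))

    def test_save_load_roundtrip(self, tmp_path):
        det = build_detector(tiny_config())
        state = det.new_training_state()
        state.iteration = 7
        state.history.append({"iteration": 7, "total": 1.25})
        det.save(tmp_path / "w.npz", state)
        loaded, restored = Detector.load(tmp_path / "w.npz")
        for pa, pb in zip(det.parameters(), loaded.parameters()):
            assert pa.data.tobytes() == pb.data.tobytes()
        assert restored.iteration == 7
        assert restored.history == state.history
        assert restored.loss_state.alpha_now == state.loss_state.alpha_now
        assert restored.assign_state.T_now == state.assign_state.T_now


class TestClassificationLoss:
    def test_uniform_logits(self):
        logits = np.zeros((5, 4))
        labels = np.array([0, 1, 2, 3, 0])
        assert softmax_classification_loss(logits, labels) == \
            pytest.approx(np.log(4.0), abs=1e-9)

    def test_confident_correct(self):
        logits = np.full((3, 4), -20.0)
        logits[np.arange(3), [0, 1, 2]] = 20.0
        assert softmax_classification_loss(logits, [0, 1, 2]) < 0.01

    def test_closed_form_value(self):
        # -log(e^2 / (e^2 + 2)) = log(1 + 2*e^-2)
        loss = softmax_classification_loss(np.array([[2.0, 0.0, 0.0]]), [0])
        assert loss == pytest.approx(np.log(1 + 2 * np.exp(-2.0)), abs=1e-9)
        assert round(loss, 4) == 0.2395

    def test_out_of_range_label_rejected(self):
        with pytest.raises(InvalidInputError):
            softmax_classification_loss(np.zeros((2, 4)), [0, 4])


@pytest.fixture(scope="module")
def batch():
    ds = generate_dataset(PhantomConfig(image_size=96, class_counts=(2, 1, 1),
                                        seed=9))
    return [(ds.images[i], ds.boxes[i]) for i in range(4)]


class TestTrainingDynamics:
    def test_two_seeded_runs_are_identical(self, batch):
        def run():
            det = build_detector(tiny_config())
            state = det.new_training_state()
            out = []
            for _ in range(6):
                losses, state = det.training_step(batch, state)
                out.append(losses["total"])
            return out

        assert run() == run()

    def test_loss_choice_isolated_to_regression_term(self, batch):
        """On the first step (identical parameters and sampling), swapping the
        regression loss changes only the Box_Head regression value."""
        first = {}
        for loss in ("dbs_l1", "smooth_l1"):
            det = build_detector(tiny_config(loss=loss))
            losses, _ = det.training_step(batch, det.new_training_state())
            first[loss] = losses
        a, b = first["dbs_l1"], first["smooth_l1"]
        for key in ("rpn_cls", "rpn_reg", "cls"):
            assert a[key] == b[key]
        assert a["reg"] != b["reg"]

    def test_cadence_boundary_updates_both_schedules_together(self, batch):
        det = build_detector(tiny_config(cadence=3))
        state = det.new_training_state()
        t_hist, a_hist = [], []
        for _ in range(9):
            _, state = det.training_step(batch, state)
            t_hist.append(state.assign_state.T_now)
            a_hist.append(state.loss_state.alpha_now)
        t_changes = {i for i in range(1, 9) if t_hist[i] != t_hist[i - 1]}
        a_changes = {i for i in range(1, 9) if a_hist[i] != a_hist[i - 1]}
        # updates may land on the same value, but buffers flush in lockstep
        boundaries = {2, 5, 8}
        assert t_changes <= boundaries and a_changes <= boundaries

    def test_image_without_annotations_contributes_background(self, batch):
        det = build_detector(tiny_config())
        state = det.new_training_state()
        empty_batch = [(batch[0][0], [])]
        losses, state = det.training_step(empty_batch, state)
        assert np.isfinite(losses["total"])
        assert losses["reg"] == 0.0


class TestOverfit:
    def test_loss_collapses_on_fixed_batch(self, overfit_run):
        _, _, _, first, last = overfit_run
        assert last < 0.1 * first

    def test_ground_truth_recovered(self, overfit_run):
        det, _, ds, _, _ = overfit_run
        dets = det.predict(ds.images[0])
        for g in ds.boxes[0]:
            assert any(d.class_id == g.class_id and d.score >= 0.5
                       and iou(d, g) >= 0.5 for d in dets)

    def test_dynamic_trajectories(self, overfit_run):
        """After warm-up, the recorded IoU threshold never falls and the loss
        factor never rises as proposal quality improves on the fixed batch."""
        _, state, _, _, _ = overfit_run
        cadence = 50
        t_seq = [h["T_now"] for h in state.history][cadence:]
        a_seq = [h["alpha_now"] for h in state.history][cadence:]
        assert all(b >= a - 1e-12 for a, b in zip(t_seq, t_seq[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(a_seq, a_seq[1:]))


class TestPredict:
    def test_untrained_detector_returns_cleanly(self, small_phantoms):
        det = build_detector(tiny_config())
        dets = det.predict(small_phantoms.images[0])
        assert isinstance(dets, list)
        for d in dets:
            assert 0 <= d.score <= 1

    def test_detections_score_sorted(self, overfit_run):
        det, _, ds, _, _ = overfit_run
        dets = det.predict(ds.images[0])
        scores = [d.score for d in dets]
        assert scores == sorted(scores, reverse=True)

    def test_nms_contract(self, overfit_run):
        """No two same-class detections overlap above the NMS threshold."""
        det, _, ds, _, _ = overfit_run
        for img in ds.images:
            dets = det.predict(img)
            for c in {d.class_id for d in dets}:
                boxes = np.array([d.as_array() for d in dets if d.class_id == c])
                if len(boxes) < 2:
                    continue
                m = iou_matrix(boxes, boxes)
                np.fill_diagonal(m, 0.0)
                assert m.max() <= det.config.nms_iou + 1e-9

    def test_mismatched_image_resized(self, overfit_run, caplog):
        det, _, _, _, _ = overfit_run
        rng = np.random.default_rng(0)
        with caplog.at_level("INFO", logger="dyndet.detector"):
            dets = det.predict(rng.uniform(0, 1, size=(64, 64)).astype(np.float32))
        assert isinstance(dets, list)
        assert any("resizing" in r.message for r in caplog.records)
        for d in dets:  # boxes mapped back to the original frame
            assert d.x_max <= 64 and d.y_max <= 64


class TestNMSFunction:
    def test_keeps_highest_and_suppresses_overlaps(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [30, 30, 40, 40]], float)
        scores = np.array([0.9, 0.8, 0.7])
        keep = nms(boxes, scores, 0.5)
        assert list(keep) == [0, 2]

    def test_tie_broken_by_order(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = nms(boxes, np.array([0.5, 0.5]), 0.5)
        assert list(keep) == [0]
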