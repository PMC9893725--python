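"""Network contracts: LSTM cell, attention, detector, temporal heads, training."""

import math

import numpy as np
import pytest

from ustrack.boxes import Box
from ustrack.nets import (
    ATTENTION_PATCH_SIZE,
    AttentionNet,
    Detector,
    DetectorConfig,
    LSTMParams,
    LSTMState,
    TemporalHead,
    TrainConfig,
    attention_forward,
    crop_patch,
    detector_forward,
    load_weights,
    lstm_step,
    save_weights,
    temporal_head,
    train_model,
)
from ustrack.nets import ModelWeights
from ustrack.synth import SyntheticConfig, simulate_sequence


def scalar_lstm_oracle(x, h, c, p: LSTMParams):
    """Independent scalar-by-scalar LSTM re-implementation (python floats)."""
    nh = p.hidden_size

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def dot(row, vec):
        return sum(float(row[j]) * float(vec[j]) for j in range(len(vec)))

    h_new, c_new = [], []
    for r in range(nh):
        i = sig(dot(p.W_ii[r], x) + p.b_ii[r] + dot(p.W_hi[r], h) + p.b_hi[r])
        f = sig(dot(p.W_if[r], x) + p.b_if[r] + dot(p.W_hf[r], h) + p.b_hf[r])
        g = math.tanh(dot(p.W_ig[r], x) + p.b_ig[r] + dot(p.W_hg[r], h) + p.b_hg[r])
        o = sig(dot(p.W_io[r], x) + p.b_io[r] + dot(p.W_ho[r], h) + p.b_ho[r])
        ct = f * float(c[r]) + i * g
        c_new.append(ct)
        h_new.append(o * math.tanh(ct))
    return np.array(h_new), np.array(c_new)


class TestLSTMCell:
    def test_zero_weights_closed_form(self):
        p = LSTMParams.zeros(input_size=3, hidden_size=2)
        out = lstm_step(np.array([1.0, -2.0, 0.5]), LSTMState.zeros(2), p)
        # sigma(0)=0.5 gates, tanh(0)=0 candidate -> everything stays 0
        assert np.allclose(out.c, 0.0)
        assert np.allclose(out.h, 0.0)

    def test_zero_weights_nonzero_cell_state(self):
        p = LSTMParams.zeros(input_size=1, hidden_size=1)
        out = lstm_step(np.array([0.7]), LSTMState(h=np.zeros(1), c=np.ones(1)), p)
        assert out.c[0] == pytest.approx(0.5)
        assert out.h[0] == pytest.approx(0.5 * math.tanh(0.5))
        assert out.h[0] == pytest.approx(0.23105, abs=1e-5)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(10):
            p = LSTMParams.zeros(input_size=3, hidden_size=2)
            for name in vars(p):
                arr = getattr(p, name)
                arr[...] = rng.normal(size=arr.shape)
            x = rng.normal(size=3)
            state = LSTMState(h=rng.normal(size=2), c=rng.normal(size=2))
            out = lstm_step(x, state, p)
            h_ref, c_ref = scalar_lstm_oracle(x, state.h, state.c, p)
            assert np.allclose(out.h, h_ref, atol=1e-10)
            assert np.allclose(out.c, c_ref, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = LSTMParams.zeros(3, 2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), LSTMState.zeros(2), p)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(3), LSTMState.zeros(3), p)


class TestAttention:
    def test_untrained_returns_anchor(self, rng):
        net = AttentionNet(np.random.default_rng(0))
        patch = rng.uniform(0, 255, size=(100, 100))
        anchor = Box(49.5, 49.5, 100, 100)
        out = attention_forward(patch, net, anchor=anchor)
        # final layer is zero-initialized: zero delta decodes to the anchor
        assert (out.x, out.y, out.w, out.h) == pytest.approx((49.5, 49.5, 100, 100))

    def test_wrong_patch_size_rejected(self):
        net = AttentionNet(np.random.default_rng(0))
        with pytest.raises(ValueError, match="100x100"):
            net.forward(np.zeros((64, 64)))

    def test_output_intersects_frame_for_random_weights(self, rng):
        patch = rng.uniform(0, 255, size=(100, 100))
        anchor = Box(5.0, 5.0, 100, 100)  # patch hangs off the frame corner
        for i in range(200):
            net = AttentionNet(np.random.default_rng(i))
            for p in net.parameters():
                p.data = rng.normal(scale=0.5, size=p.data.shape)
            box = attention_forward(patch, net, anchor=anchor, frame_shape=(64, 64))
            assert box.x1 > 0 and box.x0 < 64 and box.y1 > 0 and box.y0 < 64
            assert 0 <= box.x <= 63 and 0 <= box.y <= 63


@pytest.fixture(scope="module")
def det_setup():
    rng = np.random.default_rng(1)
    cfg = DetectorConfig()
    det = Detector(cfg, rng)
    seq, truth, _ = simulate_sequence(SyntheticConfig(seed=11, n_frames=10))
    p = truth[0].points[3]
    return det, seq.frames[3], Box(p[0], p[1], 32, 32)


class TestDetector:
    def test_single_anchor_single_proposal(self, det_setup):
        det, frame, sbox = det_setup
        from ustrack.boxes import Anchor

        out = detector_forward(frame, det, sbox, top_k=1, anchors=[Anchor(sbox)])
        assert len(out.records) == 1
        assert len(out.masks) == 1

    def test_mask_values_in_unit_interval(self, det_setup):
        det, frame, sbox = det_setup
        out = detector_forward(frame, det, sbox)
        for m in out.masks:
            assert m.shape == (det.config.mask_grid, det.config.mask_grid)
            assert np.all(m > 0) and np.all(m < 1)

    def test_scores_bounded(self, det_setup):
        det, frame, sbox = det_setup
        out = detector_forward(frame, det, sbox)
        for r, s in zip(out.records, out.cls_scores):
            assert 0 <= r.objectness <= 1
            assert 0 <= s <= 1

    def test_anchor_permutation_invariance(self, det_setup):
        det, frame, sbox = det_setup
        from ustrack.boxes import generate_anchors

        anchors = generate_anchors(sbox, det.config.window_sizes,
                                   det.config.anchor_stride_px)
        out1 = detector_forward(frame, det, sbox, anchors=anchors)
        perm = list(reversed(anchors))
        out2 = detector_forward(frame, det, sbox, anchors=perm)
        boxes1 = {(round(r.box.x, 9), round(r.box.y, 9)) for r in out1.records}
        boxes2 = {(round(r.box.x, 9), round(r.box.y, 9)) for r in out2.records}
        assert boxes1 == boxes2

    def test_deterministic_forward(self, det_setup):
        det, frame, sbox = det_setup
        out1 = detector_forward(frame, det, sbox)
        out2 = detector_forward(frame, det, sbox)
        assert np.array_equal(out1.masks[0], out2.masks[0])
        assert out1.cls_scores == out2.cls_scores


class TestTemporalHead:
    def test_single_step_matches_lstm_step(self, det_setup):
        det, frame, sbox = det_setup
        from dataclasses import replace

        cfg = replace(det.config, n_temporal=1)
        head = TemporalHead(cfg, np.random.default_rng(2))
        out = detector_forward(frame, det, sbox)
        records = [out.records[0]] * 5
        score, center, state = temporal_head(records, head)
        # oracle: one lstm_step on the last record, then the FC heads
        x = head.inputs_from_records([records[-1]])[0]
        ref = lstm_step(x, LSTMState.zeros(cfg.lstm_hidden), head.lstm_params())
        assert np.allclose(state.h, ref.h, atol=1e-12)
        logit = head.fc_score.W.data @ ref.h + head.fc_score.b.data
        assert score == pytest.approx(1 / (1 + math.exp(-logit[0])))

    def test_state_accumulates_over_repeats(self, det_setup):
        det, frame, sbox = det_setup
        head = TemporalHead(det.config, np.random.default_rng(3))
        out = detector_forward(frame, det, sbox)
        rec = out.records[0]
        s1, _, _ = temporal_head([rec], head)
        s5, _, _ = temporal_head([rec] * 5, head)
        assert s1 != s5

    def test_mask_not_touched_by_temporal_stage(self, det_setup):
        det, frame, sbox = det_setup
        head = TemporalHead(det.config, np.random.default_rng(4))
        out = detector_forward(frame, det, sbox)
        masks_before = [m.copy() for m in out.masks]
        temporal_head(out.records, head)
        temporal_head(out.records * 2, head)
        for a, b in zip(masks_before, out.masks):
            assert np.array_equal(a, b)

    def test_empty_window_rejected(self, det_setup):
        det, _, _ = det_setup
        head = TemporalHead(det.config, np.random.default_rng(5))
        with pytest.raises(ValueError):
            temporal_head([], head)


def tiny_train_config(seed=0, **kw):
    defaults = dict(epochs_attention=2, epochs_detector=2, epochs_temporal=2, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


def tiny_dataset(seed=5):
    seq, _truth, ann = simulate_sequence(
        SyntheticConfig(seed=seed, n_frames=40, n_landmarks=1, n_confounders=1,
                        annotation_fraction=0.13))
    return [(seq, ann)]


class TestTraining:
    def test_smoke_two_epochs(self):
        weights, log = train_model(tiny_dataset(), tiny_train_config())
        for key in ("attention_loss", "detector_loss", "temporal_loss"):
            assert all(np.isfinite(v) for v in log[key])

    def test_same_seed_reproduces_weights(self):
        w1, _ = train_model(tiny_dataset(), tiny_train_config(seed=9))
        w2, _ = train_model(tiny_dataset(), tiny_train_config(seed=9))
        for a, b in zip(w1.detector.parameters(), w2.detector.parameters()):
            assert np.array_equal(a.data, b.data)
        for a, b in zip(w1.attention.parameters(), w2.attention.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_no_annotations_rejected(self):
        seq, _t, _a = simulate_sequence(SyntheticConfig(seed=1, n_frames=10))
        with pytest.raises(ValueError, match="annotated"):
            train_model([(seq, [])], tiny_train_config())

    def test_loss_decreases_on_easy_data(self):
        """Stochastic: trained losses fall below their starting values."""
        firsts, lasts = [], []
        for seed in range(5):
            _w, log = train_model(
                tiny_dataset(seed=20 + seed),
                tiny_train_config(seed=seed, epochs_attention=6, epochs_detector=6,
                                  epochs_temporal=4),
            )
            firsts.append([log["attention_loss"][0], log["detector_loss"][0],
                           log["temporal_loss"][0]])
            lasts.append([log["attention_loss"][-1], log["detector_loss"][-1],
                          log["temporal_loss"][-1]])
        firsts, lasts = np.array(firsts), np.array(lasts)
        assert np.all(lasts.mean(axis=0) < firsts.mean(axis=0))

    def test_weights_round_trip(self, tmp_path):
        w1, _ = train_model(tiny_dataset(), tiny_train_config(seed=4))
        save_weights(w1, tmp_path / "w.npz")
        w2 = load_weights(tmp_path / "w.npz")
        seq, truth, _ = simulate_sequence(SyntheticConfig(seed=6, n_frames=10))
        p = truth[0].points[2]
        patch, anchor = crop_patch(seq.frames[2], p, ATTENTION_PATCH_SIZE)
        b1 = attention_forward(patch, w1.attention, anchor)
        b2 = attention_forward(patch, w2.attention, anchor)
        assert (b1.x, b1.y, b1.w, b1.h) == pytest.approx((b2.x, b2.y, b2.w, b2.h))
        o1 = detector_forward(seq.frames[2], w1.detector, Box(p[0], p[1], 32, 32))
        o2 = detector_forward(seq.frames[2], w2.detector, Box(p[0], p[1], 32, 32))
        assert o1.cls_scores == o2.cls_scores
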