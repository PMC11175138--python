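"""CNN1D / CNN-LSTM1D architecture contracts, training and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from nystrack.detector import (DetectorConfig, TrainConfig, build_cnn1d,
                               build_cnn_lstm1d, evaluate, predict,
                               save_detector, load_detector, train_detector)
from nystrack.synthkit import NystagmusParams, simulate_trace


def _cnn1d_params_oracle(cfg: DetectorConfig) -> int:
    """Per-layer counting formula, independent of the implementation:
    a kernel-k conv c_in->c_out has k*c_in*c_out + c_out parameters, a
    dense n_in->n_out has n_in*n_out + n_out, batch norm has 2 per
    feature; pooling and GAP are parameter-free."""
    k = cfg.kernel_size
    total = 0
    c_in = 1
    for c_out in cfg.conv_filters:
        total += k * c_in * c_out + c_out
        c_in = c_out
    total += cfg.conv_filters[-1] * cfg.fc_units + cfg.fc_units  # fc1
    total += 2 * cfg.fc_units                                    # batch norm
    total += cfg.fc_units * 1 + 1                                # fc2
    return total


def _cnn_lstm1d_params_oracle(cfg: DetectorConfig) -> int:
    """Same conv stack; the LSTM on c channels with u units packs four
    gates: 4*(c*u + u*u + u)."""
    k = cfg.kernel_size
    total = 0
    c_in = 1
    for c_out in cfg.conv_filters:
        total += k * c_in * c_out + c_out
        c_in = c_out
    u = cfg.lstm_units
    total += 4 * (cfg.conv_filters[-1] * u + u * u + u)
    total += u * cfg.fc_units + cfg.fc_units
    total += cfg.fc_units * 1 + 1
    return total


class TestArchitectures:
    def test_both_detectors_have_fourteen_layers(self):
        cfg = DetectorConfig()
        assert build_cnn1d(cfg).n_layers == 14
        assert build_cnn_lstm1d(cfg).n_layers == 14

    def test_cnn1d_layer_order(self):
        names = build_cnn1d(DetectorConfig()).layer_names
        assert names[0] == "input" and names[-1] == "sigmoid"
        assert names.index("batch_norm") == names.index("fc2") - 1
        assert "global_avg_pool" in names

    def test_cnn_lstm1d_swaps_gap_for_pool_and_lstm(self):
        names = build_cnn_lstm1d(DetectorConfig()).layer_names
        assert "global_avg_pool" not in names
        assert names.count("maxpool3") == 1
        assert names.index("lstm") == names.index("maxpool3") + 1

    @pytest.mark.parametrize("filters,fc,lstm", [
        ((16, 16, 32, 32, 64, 64), 64, 64),
        ((8, 8, 16, 16, 32, 32), 32, 32),
    ])
    def test_param_counts_match_counting_formula(self, filters, fc, lstm):
        cfg = DetectorConfig(conv_filters=filters, fc_units=fc,
                             lstm_units=lstm)
        assert build_cnn1d(cfg).n_params() == _cnn1d_params_oracle(cfg)
        assert build_cnn_lstm1d(cfg).n_params() == \
            _cnn_lstm1d_params_oracle(cfg)

    def test_lstm_variant_has_more_parameters(self):
        cfg = DetectorConfig()
        assert build_cnn_lstm1d(cfg).n_params() > build_cnn1d(cfg).n_params()

    def test_param_count_is_pure_function_of_config(self):
        cfg = DetectorConfig()
        counts = {build_cnn1d(cfg, seed=s).n_params() for s in range(3)}
        assert len(counts) == 1

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(0)
        clips = rng.standard_normal((8, 1000))
        for build in (build_cnn1d, build_cnn_lstm1d):
            scores = predict(build(DetectorConfig(), seed=1), clips)
            assert scores.shape == (8,)
            assert np.all((scores >= 0) & (scores <= 1))
            assert np.all(np.isfinite(scores))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(conv_filters=(8, 8)).validate()
        with pytest.raises(ValueError):
            DetectorConfig(input_len=1001).validate()
        with pytest.raises(ValueError):
            DetectorConfig(architecture="mlp").validate()


class TestPredict:
    def test_identical_clips_identical_scores(self):
        model = build_cnn1d(DetectorConfig(), seed=2)
        clip = np.random.default_rng(1).standard_normal(1000)
        scores = predict(model, np.stack([clip, clip, clip]))
        assert scores[0] == scores[1] == scores[2]

    def test_permuting_clips_permutes_scores(self):
        model = build_cnn1d(DetectorConfig(), seed=2)
        clips = np.random.default_rng(2).standard_normal((6, 1000))
        perm = np.array([3, 0, 5, 1, 4, 2])
        np.testing.assert_allclose(predict(model, clips)[perm],
                                   predict(model, clips[perm]), atol=1e-6)

    def test_wrong_length_rejected(self):
        model = build_cnn1d(DetectorConfig(), seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 999)))


def _toy_clips(n=20, length=200, seed=0):
    """Well-separated classes: clean sawtooth vs low-pass noise."""
    rng = np.random.default_rng(seed)
    clips, labels = [], []
    for i in range(n):
        kind = "nystagmus" if i % 2 == 0 else "normal"
        p = NystagmusParams(noise_sd=0.2, fps=30,
                            beat_frequency=float(rng.uniform(2.5, 4.0)))
        x, _ = simulate_trace(p, length, kind, seed=int(rng.integers(1 << 30)))
        x = (x - np.median(x)) / (x.std() + 1e-6)
        clips.append(x)
        labels.append(int(kind == "nystagmus"))
    return np.stack(clips), np.array(labels)


class TestTraining:
    def test_overfits_well_separated_clips(self):
        clips, labels = _toy_clips()
        cfg = DetectorConfig.test_profile(input_len=200)
        tc = TrainConfig(learning_rate=1e-3, batch_size=10, max_epochs=200,
                         early_stopping_patience=200, seed=0)
        model, _ = train_detector(clips, labels, cfg, tc,
                                  val_clips=clips, val_labels=labels)
        calls = predict(model, clips) > 0.5
        assert np.array_equal(calls.astype(int), labels)  # 100% train acc

    def test_same_seed_identical_history(self):
        clips, labels = _toy_clips(n=12)
        cfg = DetectorConfig.test_profile(input_len=200)
        tc = TrainConfig(learning_rate=1e-3, batch_size=6, max_epochs=3,
                         early_stopping_patience=10, seed=4)
        _, h1 = train_detector(clips, labels, cfg, tc)
        _, h2 = train_detector(clips, labels, cfg, tc)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_best_model_no_worse_than_final_epoch(self):
        clips, labels = _toy_clips(n=12)
        cfg = DetectorConfig.test_profile(input_len=200)
        tc = TrainConfig(learning_rate=1e-3, batch_size=6, max_epochs=8,
                         early_stopping_patience=20, seed=1)
        _, history = train_detector(clips, labels, cfg, tc,
                                    val_clips=clips, val_labels=labels)
        best = history["val_loss"][history["best_epoch"]]
        assert best <= history["val_loss"][-1] + 1e-12
        assert best == min(history["val_loss"])

    def test_single_class_training_rejected(self):
        clips = np.zeros((4, 200))
        with pytest.raises(ValueError):
            train_detector(clips, np.ones(4), DetectorConfig(input_len=200),
                           TrainConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        clips, labels = _toy_clips(n=8)
        cfg = DetectorConfig.test_profile(input_len=200)
        tc = TrainConfig(learning_rate=1e-3, batch_size=4, max_epochs=2,
                         early_stopping_patience=5, seed=0)
        model, _ = train_detector(clips, labels, cfg, tc)
        save_detector(tmp_path / "det.npz", model)
        loaded = load_detector(tmp_path / "det.npz")
        np.testing.assert_allclose(predict(model, clips),
                                   predict(loaded, clips), atol=1e-7)


class TestEvaluate:
    def test_confusion_arithmetic_on_constructed_set(self):
        # TP=94, FN=6, TN=86, FP=14
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        scores = np.r_[np.full(94, 0.9), np.full(6, 0.1),
                       np.full(86, 0.2), np.full(14, 0.8)]
        rep = evaluate(scores, labels, bootstrap_reps=10, seed=0)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (94, 6, 86, 14)
        assert rep.metrics["sensitivity"] == pytest.approx(94.00)
        assert rep.metrics["specificity"] == pytest.approx(86.00)
        assert rep.metrics["precision"] == pytest.approx(87.04, abs=0.005)
        assert rep.metrics["accuracy"] == pytest.approx(90.00)
        assert rep.n == 200

    def test_perfect_separation_auc_one(self):
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        scores = np.r_[np.ones(5), np.zeros(5)]
        assert evaluate(scores, labels, bootstrap_reps=5).auc == 1.0

    def test_uninformative_scores_auc_half(self):
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        scores = np.full(10, 0.5)
        assert evaluate(scores, labels, bootstrap_reps=5).auc == \
            pytest.approx(0.5)

    def test_f1_identity(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        rep = evaluate(scores, labels, bootstrap_reps=50, seed=1)
        m = rep.metrics
        expect = 2 * m["precision"] * m["sensitivity"] / (m["precision"]
                                                          + m["sensitivity"])
        assert m["f1"] == pytest.approx(expect)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_auc_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        rep = evaluate(scores, labels, bootstrap_reps=2, seed=0)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = mannwhitneyu(pos, neg).statistic
        assert rep.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-9)

    def test_one_class_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_bootstrap_spread_is_seeded(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        r1 = evaluate(scores, labels, bootstrap_reps=100, seed=5)
        r2 = evaluate(scores, labels, bootstrap_reps=100, seed=5)
        assert r1.bootstrap_sd == r2.bootstrap_sd
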