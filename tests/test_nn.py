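"""CNN engine: losses, architecture, optimizer, training protocol."""

import math

import numpy as np
import pytest

from ecgcascade.errors import LeakageError, ParameterError, ShapeError
from ecgcascade.nn import (
    Adam,
    ArrayDataset,
    TrainingConfig,
    binary_cross_entropy,
    build_model,
    early_stopping_schedule,
    load_model,
    softmax,
    sparse_categorical_cross_entropy,
    train,
)


class TestLosses:
    @pytest.mark.parametrize(
        "target, pred, expected",
        [
            ([1, 0], [1.0, 0.0], 0.0),
            ([1, 0], [0.5, 0.5], math.log(2)),
            ([1, 0], [0.7, 0.3], -math.log(0.7)),
        ],
    )
    def test_binary_closed_form(self, target, pred, expected):
        loss = binary_cross_entropy(np.array([target]), np.array([pred]))
        assert loss == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize(
        "label, pred, expected",
        [
            (2, [0.1, 0.2, 0.7], -math.log(0.7)),
            (0, [1 / 3, 1 / 3, 1 / 3], math.log(3)),
            (1, [0.0, 1.0, 0.0], 0.0),
        ],
    )
    def test_sparse_categorical_closed_form(self, label, pred, expected):
        loss = sparse_categorical_cross_entropy(np.array([label]), np.array([pred]))
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_losses_match_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            logits = rng.normal(size=(16, 2))
            probs = softmax(logits)
            labels = rng.integers(0, 2, size=16)
            onehot = np.eye(2)[labels]
            loop = np.mean([
                -(y[1] * math.log(max(p[1], 1e-7))
                  + (1 - y[1]) * math.log(max(1 - p[1], 1e-7)))
                for y, p in zip(onehot, probs)
            ])
            assert binary_cross_entropy(onehot, probs) == pytest.approx(loop, abs=1e-6)

            probs3 = softmax(rng.normal(size=(16, 3)))
            labels3 = rng.integers(0, 3, size=16)
            loop3 = np.mean([-math.log(max(p[c], 1e-7))
                             for p, c in zip(probs3, labels3)])
            assert sparse_categorical_cross_entropy(labels3, probs3) == \
                pytest.approx(loop3, abs=1e-6)

    def test_shape_and_label_errors(self):
        with pytest.raises(ShapeError):
            binary_cross_entropy(np.ones((3, 2)), np.ones((4, 2)))
        with pytest.raises(ParameterError):
            sparse_categorical_cross_entropy(np.array([3]), np.ones((1, 3)) / 3)


class TestArchitecture:
    def test_softmax_rows_sum_to_one(self):
        model = build_model(2, width_multiplier=0.125, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 2160, 1))
        probs = model.predict(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_three_class_head(self):
        model = build_model(3, width_multiplier=0.125, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 2160, 1))
        assert model.predict(x).shape == (2, 3)

    def test_full_width_filter_ladder(self):
        model = build_model(2, width_multiplier=1.0, seed=0)
        filters = [d["filters"] for d in model.describe() if d["type"] == "conv1d"]
        assert filters == [16, 16, 32, 32, 32, 32, 256, 256]

    def test_nineteen_layers_before_head(self):
        desc = build_model(3, width_multiplier=1.0, seed=0).describe()
        assert len(desc) == 20  # 19 layers + softmax head
        counts = {t: sum(1 for d in desc[:-1] if d["type"] == t)
                  for t in ("conv1d", "maxpool", "global_maxpool", "dropout", "dense")}
        assert counts == {"conv1d": 8, "maxpool": 3, "global_maxpool": 1,
                          "dropout": 4, "dense": 3}

    def test_invalid_head_rejected(self):
        with pytest.raises(ParameterError):
            build_model(5)

    def test_empty_input_empty_output(self):
        model = build_model(2, width_multiplier=0.125, seed=0)
        assert model.predict(np.zeros((0, 2160, 1))).shape == (0, 2)

    def test_wrong_length_rejected(self):
        model = build_model(2, width_multiplier=0.125, seed=0)
        with pytest.raises(ShapeError):
            model.predict(np.zeros((2, 2000, 1)))

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(3, width_multiplier=0.125, seed=1)
        x = np.random.default_rng(2).normal(size=(2, 2160, 1))
        model.save(tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(model.predict(x), back.predict(x))


class TestOptimization:
    def test_one_small_step_decreases_batch_loss(self):
        rng = np.random.default_rng(3)
        model = build_model(2, width_multiplier=0.125, seed=3)
        x = rng.normal(size=(8, 2160, 1)).astype(np.float32)
        y = np.array([0, 1] * 4)

        def batch_loss():
            return sparse_categorical_cross_entropy(y, model.predict(x))

        before = batch_loss()
        opt = Adam(model.parameters(), learning_rate=1e-4)
        logits = model.forward_logits(x, training=True, rng=rng)
        probs = softmax(logits)
        delta = probs.astype(np.float32)
        delta[np.arange(len(y)), y] -= 1.0
        model.backward(delta / len(y))
        opt.step(model.gradients())
        assert batch_loss() < before

    def test_gradients_match_finite_differences(self):
        # tiny custom stack keeps the check fast and away from ReLU kinks
        from ecgcascade.nn.layers import Conv1D, Dense, GlobalMaxPool1D, MaxPool1D
        from ecgcascade.nn.network import CnnModel

        rng = np.random.default_rng(0)
        layers = [Conv1D(1, 3, 5, rng), MaxPool1D(2, 2), Conv1D(3, 4, 3, rng),
                  GlobalMaxPool1D(), Dense(4, 3, rng, activation=None)]
        model = CnnModel(layers, 3, 40, 1.0)
        x = rng.normal(size=(4, 40, 1))
        y = np.array([0, 1, 2, 1])

        def loss():
            return sparse_categorical_cross_entropy(y, softmax(model.forward_logits(x)))

        probs = softmax(model.forward_logits(x, training=True, rng=rng))
        delta = probs.copy()
        delta[np.arange(4), y] -= 1.0
        model.backward((delta / 4).astype(np.float32))
        grads = [g.copy() for g in model.gradients()]

        rel_errs = []
        for p, g in zip(model.parameters(), grads):
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for i in range(0, flat.size, max(1, flat.size // 4)):
                old = flat[i]
                eps = 1e-3
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                rel_errs.append(abs(num - gflat[i]) / (1.0 + abs(num)))
        assert np.median(rel_errs) < 1e-3


class TestTrainingProtocol:
    @pytest.mark.parametrize(
        "metrics, patience, expected",
        [
            (list(np.linspace(0.5, 0.99, 50)), 10, (50, 50)),  # always improving
            ([0.7] * 50, 10, (11, 1)),  # constant from epoch 1
            ([0.5, 0.9] + [0.6] * 20, 5, (7, 2)),
        ],
    )
    def test_early_stopping_rule(self, metrics, patience, expected):
        assert early_stopping_schedule(metrics, patience) == expected

    def make_dataset(self, subjects, n=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2160, 1)).astype(np.float32)
        y = rng.integers(0, 2, size=n)
        return ArrayDataset(X, y, np.array(list(subjects) * (n // len(subjects))))

    def test_subject_overlap_rejected(self):
        model = build_model(2, width_multiplier=0.125, seed=0)
        with pytest.raises(LeakageError):
            train(model, self.make_dataset("ab"), self.make_dataset("bc"),
                  TrainingConfig(max_epochs=1, patience=1))

    def test_same_seed_reproduces_history(self):
        config = TrainingConfig(max_epochs=2, patience=2, seed=5)
        histories = []
        for _ in range(2):
            model = build_model(2, width_multiplier=0.125, seed=5)
            tm = train(model, self.make_dataset("ab", n=24, seed=1),
                       self.make_dataset("cd", n=8, seed=2), config)
            histories.append(tm.history)
        assert histories[0] == histories[1]

    def test_learns_separable_binary_toy(self):
        # high-SNR N vs PVC cohort with 200 training segments; under the
        # standard early-stopping budget the scaled model fits the training set
        from ecgcascade.pipeline import binary_dataset
        from ecgcascade.preprocess import preprocess_record
        from ecgcascade.synth import CohortConfig, generate_cohort

        config = CohortConfig(
            n_subjects=5, duration_s=45, seed=8,
            prevalence={"N": 0.5, "PVC": 0.5, "LBBB": 0.0, "RBBB": 0.0},
            white_noise_mv=0.01, powerline_amp_mv=0.02, baseline_amp_mv=0.05,
        )
        segments = []
        for record, anns in generate_cohort(config):
            segments.extend(preprocess_record(record, anns))
        train_segs = [s for s in segments if s.subject_id < "S04"][:200]
        val_segs = [s for s in segments if s.subject_id == "S04"]
        model = build_model(2, width_multiplier=0.25, seed=0)
        tm = train(model, binary_dataset(train_segs), binary_dataset(val_segs),
                   TrainingConfig(max_epochs=30, patience=10, seed=0))
        assert max(h["train_acc"] for h in tm.history) >= 0.9
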