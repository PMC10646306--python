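"""Classifier: architecture arithmetic, gradients, training behavior, and
evaluation metrics (top-n, balanced accuracy, group tests)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scenevep import _nn
from scenevep import model as M


def layer_arithmetic_oracle(n_times, k1=64, p1=32, pool2=4, k3=16, p3=8,
                            pool3=8, n_ch=17, filters=16):
    """Independent pad/conv/pool integer arithmetic for the stack."""
    t = n_times + 2 * p1 - k1 + 1       # ConvBlock1
    t = t // pool2                       # ConvBlock2 pool (floor, no pad)
    t = (t + 2 * p3 - k3 + 1) // pool3   # ConvBlock3
    return t, filters * n_ch * t


class TestArchitecture:
    def test_time_lengths_for_standard_input(self):
        spec = M.ArchitectureSpec()
        assert spec.time_lengths() == {"conv1": 501, "block2": 125,
                                       "block3": 15}
        assert spec.flatten_features() == 4080

    @pytest.mark.parametrize("n_times", [100, 250, 500])
    def test_matches_arithmetic_oracle_across_lengths(self, n_times):
        spec = M.ArchitectureSpec(n_times=n_times)
        t_expected, flat_expected = layer_arithmetic_oracle(n_times)
        assert spec.time_lengths()["block3"] == t_expected
        assert spec.flatten_features() == flat_expected
        # the built network agrees with the arithmetic, layer by layer
        net = M.build_model(3, spec=spec)
        assert net.net.out_time(n_times)[13] == t_expected  # after pool 3
        x = np.zeros((1, 17, n_times), np.float32)
        assert net.logits(x).shape == (1, 3)

    def test_probabilities_normalized(self):
        net = M.build_model(13, seed=0)
        x = np.random.default_rng(0).standard_normal((4, 17, 500))
        p = net.predict_proba(x)
        assert p.shape == (4, 13)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6

    def test_input_shape_enforced(self):
        net = M.build_model(4)
        with pytest.raises(ValueError):
            net.logits(np.zeros((2, 17, 400), np.float32))
        with pytest.raises(ValueError):
            M.build_model(1)

    def test_save_load_round_trip(self, tiny_arch, tmp_path):
        net = M.build_model(3, spec=tiny_arch, seed=5)
        x = np.random.default_rng(1).standard_normal((3, 4, 100))
        path = tmp_path / "model.npz"
        net.save(path)
        back = M.EEGNetVariant.load(path)
        assert np.allclose(net.predict_proba(x), back.predict_proba(x))


class TestGradients:
    def test_numerical_gradient_check(self, tiny_arch):
        tiny_arch.dropout = 0.0  # keep the loss deterministic for FD checks
        net = M.build_model(2, spec=tiny_arch, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 4, 100)).astype(np.float32)
        y = np.array([0, 1, 1, 0])

        def loss():
            return _nn.cross_entropy(net.logits(x, training=True), y)[0]

        l0, dl = _nn.cross_entropy(net.logits(x, training=True), y)
        net.net.backward(dl)
        for layer, name, p in net.net.parameters():
            g = layer.grads[name]
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                eps = 1e-2
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = float(g.ravel()[i])
                assert num == pytest.approx(ana, rel=0.08, abs=2e-3), \
                    f"{type(layer).__name__}.{name}[{i}]"


class TestTraining:
    def _samples(self, n, spec, seed, separable=True):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, spec.n_channels, spec.n_times)) * 0.5
        y = rng.integers(0, 2, n)
        if separable:
            t = np.arange(spec.n_times)
            bump = np.exp(-0.5 * ((t - 30) / 5.0) ** 2)
            X[y == 0, 0] += 2 * bump
            X[y == 1, 0] -= 2 * bump
        return [type("S", (), {"data": d.astype(np.float32),
                               "label": int(l)})()
                for d, l in zip(X, y)]

    def test_separable_classes_learned(self, tiny_arch):
        train = self._samples(128, tiny_arch, 0)
        test = self._samples(64, tiny_arch, 1)
        net = M.build_model(2, spec=tiny_arch, seed=0)
        M.train(net, train, M.TrainConfig(n_epochs=30, seed=0, eval_every=0))
        X = np.stack([s.data for s in test])
        y = np.array([s.label for s in test])
        assert (net.predict(X) == y).mean() > 0.9

    def test_permuted_labels_stay_at_chance(self, tiny_arch):
        rng = np.random.default_rng(2)
        train = self._samples(128, tiny_arch, 2)
        labels = np.array([s.label for s in train])
        rng.shuffle(labels)
        for s, l in zip(train, labels):
            s.label = int(l)
        test = self._samples(80, tiny_arch, 3)
        net = M.build_model(2, spec=tiny_arch, seed=0)
        M.train(net, train, M.TrainConfig(n_epochs=15, seed=0, eval_every=0))
        X = np.stack([s.data for s in test])
        y = np.array([s.label for s in test])
        acc = (net.predict(X) == y).mean()
        # the permutation null is wider than binomial(n_test, 1/2): a finite
        # permutation agrees with the true labels at 0.5 +- sqrt(1/4/n_train)
        # and training can amplify that agreement to full strength, so both
        # variance terms enter the band
        band = 1.96 * np.sqrt(0.25 / 80 + 0.25 / 128)
        assert abs(acc - 0.5) < band

    def test_same_seed_same_trace(self, tiny_arch):
        train = self._samples(64, tiny_arch, 4)
        traces = []
        for _ in range(2):
            net = M.build_model(2, spec=tiny_arch, seed=3)
            tr = M.train(net, train,
                         M.TrainConfig(n_epochs=3, seed=3, eval_every=0))
            traces.append(tr.train_loss)
        assert traces[0] == traces[1]

    def test_single_class_rejected(self, tiny_arch):
        train = self._samples(16, tiny_arch, 5)
        for s in train:
            s.label = 0
        net = M.build_model(2, spec=tiny_arch, seed=0)
        with pytest.raises(ValueError):
            M.train(net, train, M.TrainConfig(n_epochs=1))


class TestTopN:
    def test_exhaustive_and_unit_cases(self):
        rng = np.random.default_rng(0)
        probs = rng.random((50, 13))
        probs /= probs.sum(axis=1, keepdims=True)
        y = rng.integers(0, 13, 50)
        assert M.top_n_accuracy(probs, y, 13) == 1.0
        assert M.top_n_accuracy(probs, y, 1) == \
            (probs.argmax(axis=1) == y).mean()
        with pytest.raises(ValueError):
            M.top_n_accuracy(probs, y, 14)

    def test_uniform_scores_give_n_over_k(self):
        rng = np.random.default_rng(1)
        probs = rng.random((10_000, 13))
        y = rng.integers(0, 13, 10_000)
        acc = M.top_n_accuracy(probs, y, 2)
        assert acc == pytest.approx(2 / 13, abs=0.01)

    def test_tie_break_is_stable_by_class_index(self):
        probs = np.array([[0.25, 0.25, 0.25, 0.25]])
        assert M.top_n_accuracy(probs, [1], 2) == 1.0  # classes 0, 1 win ties
        assert M.top_n_accuracy(probs, [3], 2) == 0.0


def brute_force_balanced_accuracy(tp, fn, fp, tn):
    """Mean per-class recall computed from an explicit label expansion."""
    truth = [1] * (tp + fn) + [0] * (tn + fp)
    pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    recalls = []
    for cls in (0, 1):
        idx = [i for i, t in enumerate(truth) if t == cls]
        recalls.append(sum(pred[i] == cls for i in idx) / len(idx))
    return sum(recalls) / 2


class TestBalancedAccuracy:
    @pytest.mark.parametrize("conf,expected", [
        ((10, 0, 10, 0), 0.5),   # always-positive classifier
        ((8, 2, 4, 6), 0.7),
        ((5, 5, 5, 5), 0.5),
    ])
    def test_worked_examples(self, conf, expected):
        assert M.balanced_accuracy(*conf) == pytest.approx(expected)

    def test_empty_class_is_explicit_error(self):
        with pytest.raises(ValueError):
            M.balanced_accuracy(0, 0, 3, 4)
        with pytest.raises(ValueError):
            M.balanced_accuracy(3, 4, 0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 50), st.integers(0, 50),
                     st.integers(0, 50), st.integers(1, 50)))
    def test_matches_brute_force_recall_mean(self, conf):
        tp, fn, fp, tn = conf
        assert M.balanced_accuracy(tp, fn, fp, tn) == pytest.approx(
            brute_force_balanced_accuracy(tp, fn, fp, tn))


class TestEvaluate:
    def _test_samples(self, net, spec, n_per=6, pids=("P00", "P01", "P02")):
        rng = np.random.default_rng(0)
        out = []
        for pid in pids:
            for k in range(n_per):
                out.append(type("S", (), {
                    "data": rng.standard_normal(
                        (spec.n_channels, spec.n_times)).astype(np.float32),
                    "label": int(k % net.n_classes),
                    "participant_id": pid})())
        return out

    def test_chance_levels_are_computed(self, tiny_arch):
        net = M.build_model(13, spec=tiny_arch, seed=0)
        res = M.evaluate(net, self._test_samples(net, tiny_arch, 13),
                         "category")
        assert res.metrics["accuracy"]["chance"] == pytest.approx(1 / 13)
        assert res.metrics["top2_accuracy"]["chance"] == pytest.approx(2 / 13)
        assert res.confusion.sum() == 3 * 13

    def test_binary_uses_balanced_accuracy_with_half_chance(self, tiny_arch):
        net = M.build_model(2, spec=tiny_arch, seed=0)
        res = M.evaluate(net, self._test_samples(net, tiny_arch, 6),
                         "naturalness")
        m = res.metrics["balanced_accuracy"]
        assert m["chance"] == 0.5
        assert "p_fdr" in m
        total = sum(res.confusion.values())
        assert total == 18

    def test_all_correct_gives_unit_metrics(self, tiny_arch):
        net = M.build_model(2, spec=tiny_arch, seed=1)
        samples = self._test_samples(net, tiny_arch, 4)
        for s in samples:  # relabel with the model's own predictions
            s.label = int(net.predict(s.data)[0])
        res = M.evaluate(net, samples, "openness")
        assert (res.per_participant["accuracy"] == 1.0).all()
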