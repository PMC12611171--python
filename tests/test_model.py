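import math

import numpy as np
import pytest

from simpep.model import (
    ModelError,
    NetConfig,
    SiameseSimilarityClassifier,
    SimilarityNet,
    bce_loss,
    load_model,
    save_model,
)
from simpep.synthetic import SynthSpec, gen_embedding_clusters


@pytest.fixture(scope="module")
def tiny_net():
    return SimilarityNet(input_dim=6, encoder_widths=(8, 4), head_width=3,
                         dropout=0.0, rng=np.random.default_rng(0))


def reference_forward(net, va, vb):
    """Independent plain-loop forward pass over the same parameters."""

    def relu(x):
        return [max(0.0, v) for v in x]

    def dense(x, W, b):
        return [sum(x[i] * W[i][j] for i in range(len(x))) + b[j] for j in range(len(b))]

    def encode(v):
        a = list(v)
        for W, b in zip(net.enc_W, net.enc_b):
            a = relu(dense(a, W.tolist(), b.tolist()))
        return a

    la, lb = encode(va), encode(vb)
    d = [abs(x - y) for x, y in zip(la, lb)]
    h = relu(dense(d, net.head_W.tolist(), net.head_b.tolist()))
    z = dense(h, net.out_w.tolist(), net.out_b.tolist())[0]
    return 1.0 / (1.0 + math.exp(-z))


class TestForward:
    def test_identical_inputs_give_constant_score(self, tiny_net):
        rng = np.random.default_rng(1)
        scores = {float(tiny_net.pair_scores(v, v)[0]) for v in rng.standard_normal((5, 6))}
        assert len(scores) == 1  # sigmoid(head(0)) regardless of the input

    def test_swap_symmetry_bit_exact(self, tiny_net):
        rng = np.random.default_rng(2)
        v, w = rng.standard_normal((2, 6))
        assert tiny_net.pair_scores(v, w)[0] == tiny_net.pair_scores(w, v)[0]

    def test_matches_independent_loop_oracle(self, tiny_net):
        rng = np.random.default_rng(3)
        for _ in range(5):
            v, w = rng.standard_normal((2, 6))
            expected = reference_forward(tiny_net, v, w)
            assert tiny_net.pair_scores(v, w)[0] == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_rejected(self, tiny_net):
        with pytest.raises(ModelError):
            tiny_net.pair_scores(np.ones(4), np.ones(4))

    def test_weight_sharing_perturbation_moves_both_channels(self):
        net = SimilarityNet(input_dim=4, encoder_widths=(8, 4), head_width=2,
                            dropout=0.0, rng=np.random.default_rng(7))
        v = np.ones(4)
        w = np.full(4, 2.0)
        la_before, _ = net.encode(v)
        lb_before, _ = net.encode(w)
        assert np.abs(la_before).sum() > 0 and np.abs(lb_before).sum() > 0
        net.enc_W[0] += 0.5
        la_after, _ = net.encode(v)
        lb_after, _ = net.encode(w)
        # a single shared-parameter change shifts both channels' latents
        assert not np.allclose(la_before, la_after)
        assert not np.allclose(lb_before, lb_after)


class TestBCELoss:
    def test_confident_correct_is_near_zero(self):
        assert bce_loss([1.0], [1.0 - 1e-7]) == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_prediction_is_ln2(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(math.log(2.0), rel=1e-9)

    def test_confident_wrong_is_penalized(self):
        assert bce_loss([0.0], [0.9]) == pytest.approx(-math.log(0.1), rel=1e-9)

    def test_endpoint_predictions_stay_finite(self):
        assert np.isfinite(bce_loss([1.0, 0.0], [0.0, 1.0]))

    def test_batch_mean(self):
        single = (bce_loss([1.0], [0.8]) + bce_loss([0.0], [0.3])) / 2.0
        assert bce_loss([1.0, 0.0], [0.8, 0.3]) == pytest.approx(single, rel=1e-12)


class TestNetConfig:
    def test_ascending_encoder_widths_rejected(self):
        with pytest.raises(ModelError):
            NetConfig(encoder_widths=(32, 64))

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ModelError):
            NetConfig(dropout=1.0)


@pytest.fixture(scope="module")
def separable():
    spec = SynthSpec(dim=32, n_pos=40, n_neg=40, delta=6.0, seed=0)
    return gen_embedding_clusters(spec)


class TestTraining:
    def test_separable_clusters_fit_to_high_training_accuracy(self, separable):
        clf = SiameseSimilarityClassifier(random_state=0, max_rounds=3)
        clf.fit(separable.X, separable.y)
        assert clf.history_["accuracy"].iloc[-1] >= 0.95

    def test_single_round_runs_exactly_epochs_per_round(self, separable):
        clf = SiameseSimilarityClassifier(random_state=0, max_rounds=1, epochs_per_round=5)
        clf.fit(separable.X, separable.y)
        assert len(clf.history_) == 5
        assert clf.n_rounds_ == 1

    def test_fit_reproducible_under_random_state(self, separable):
        rhos = []
        for _ in range(2):
            clf = SiameseSimilarityClassifier(random_state=11, max_rounds=1)
            clf.fit(separable.X, separable.y)
            rhos.append(clf.decision_function(separable.X[:5]))
        np.testing.assert_array_equal(rhos[0], rhos[1])

    def test_predict_uses_sorted_classes(self, separable):
        clf = SiameseSimilarityClassifier(random_state=0, max_rounds=1)
        clf.fit(separable.X, separable.y)
        preds = clf.predict(separable.X[:3])
        assert set(preds) <= {0, 1}

    def test_requires_two_classes(self, separable):
        clf = SiameseSimilarityClassifier(random_state=0)
        with pytest.raises(ModelError):
            clf.fit(separable.X, np.zeros(len(separable.y)))

    def test_sklearn_param_round_trip(self):
        clf = SiameseSimilarityClassifier(dropout=0.3, learning_rate=0.01)
        params = clf.get_params()
        clone = SiameseSimilarityClassifier(**params)
        assert clone.get_params() == params


class TestCheckpointing:
    def test_save_load_round_trip_scores(self, tmp_path):
        spec = SynthSpec(dim=8, n_pos=8, n_neg=16, delta=4.0, seed=5)
        data = gen_embedding_clusters(spec)
        clf = SiameseSimilarityClassifier(encoder_widths=(16, 8), head_width=4,
                                          random_state=0, max_rounds=1)
        clf.fit(data.X, data.y)
        save_model(clf, tmp_path / "model")
        restored = load_model(tmp_path / "model")
        np.testing.assert_allclose(
            restored.decision_function(data.X), clf.decision_function(data.X), rtol=1e-12
        )
        assert restored.n_rounds_ == clf.n_rounds_
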