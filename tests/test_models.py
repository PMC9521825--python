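"""Classifier zoo: grid enumeration/search, FNN and CNN training contracts."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from ltrcurator import models
from ltrcurator._nn import Conv2D
from ltrcurator.features import one_hot
from ltrcurator.models import (CnnConfig, FnnConfig, balanced_subsample,
                               enumerate_grid, grid_search, predict,
                               train_cnn, train_fnn)


class TestGridEnumeration:
    @pytest.mark.parametrize("algorithm,count", [
        ("KNN", 100), ("SVC", 2), ("LR", 10), ("LDA", 10),
        ("NB", 10), ("MLP", 10), ("DT", 10), ("RF", 10)])
    def test_candidate_counts(self, algorithm, count):
        assert len(enumerate_grid(algorithm)) == count

    def test_lr_endpoints(self):
        grid = enumerate_grid("LR")
        assert grid[0]["C"] == 0.1 and grid[-1]["C"] == 1.0

    def test_nb_ladder_spans_1e1_to_1e19_by_factor_1e2(self):
        vs = [c["var_smoothing"] for c in enumerate_grid("NB")]
        assert np.isclose(vs[0], 1e-1) and np.isclose(vs[-1], 1e-19)
        assert np.allclose(np.array(vs[1:]) / np.array(vs[:-1]), 1e-2)

    def test_svc_fixed_gamma(self):
        assert all(c["gamma"] == 1e-6 for c in enumerate_grid("SVC"))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid("GBM")


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=160, centers=[[-4, -4], [4, 4]],
                      cluster_std=0.5, random_state=0)
    return (X[:120], y[:120]), (X[120:], y[120:])


@pytest.fixture(scope="module")
def small_onehot(short_library):
    from ltrcurator import sim
    cfg = sim.SimConfig(n_per_class=(30, 30, 0, 0, 0), seed=9)
    ds = sim.generate_dataset(cfg, short_library)
    y = (np.array(ds.labels) != 0).astype(int)
    return one_hot(ds.records), y


class TestGridSearch:
    @pytest.mark.parametrize("algorithm", models.GRID_ALGORITHMS)
    def test_separable_blobs_reach_perfect_f1(self, algorithm, blobs):
        (Xt, yt), (Xv, yv) = blobs
        result = grid_search(algorithm, Xt, yt, Xv, yv, seed=0)
        assert result.best_score == 1.0
        assert len(result.table) == len(enumerate_grid(algorithm))

    def test_tie_resolves_to_smaller_candidate(self, blobs):
        (Xt, yt), (Xv, yv) = blobs
        result = grid_search("DT", Xt, yt, Xv, yv, seed=0)
        # every depth separates the blobs, so the first candidate wins
        assert result.best_params == enumerate_grid("DT")[0]

    def test_best_never_below_first_candidate(self, blobs):
        (Xt, yt), (Xv, yv) = blobs
        result = grid_search("KNN", Xt, yt, Xv, yv, seed=0)
        assert result.best_score >= result.table[0][1]

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            grid_search("KNN", X, np.zeros(20), X, np.zeros(20))


def _toy_binary(n=120, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, d)) + 3.0 * y[:, None]
    return X, y


class TestFnn:
    def test_defaults_follow_training_protocol(self):
        config = FnnConfig()
        assert config.epochs == 200 and config.batch_size == 128
        assert config.dropout == 0.5 and config.batchnorm_momentum == 0.99

    def test_history_has_one_row_per_epoch(self):
        X, y = _toy_binary()
        model = train_fnn(FnnConfig(epochs=5, batch_size=32, seed=1),
                          (X, y), (X, y))
        assert len(model.history) == 5
        assert {"train_loss", "val_loss", "val_metric"} <= set(model.history[0])

    def test_training_reduces_loss_on_memorizable_set(self):
        X, y = _toy_binary(n=100)
        model = train_fnn(FnnConfig(epochs=25, batch_size=32, seed=1),
                          (X, y), (X, y))
        assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]
        assert model.history[-1]["val_metric"] > 0.9

    def test_same_seed_identical_weights(self):
        X, y = _toy_binary()
        m1 = train_fnn(FnnConfig(epochs=3, batch_size=32, seed=5), (X, y))
        m2 = train_fnn(FnnConfig(epochs=3, batch_size=32, seed=5), (X, y))
        for a, b in zip(m1.model.weight_state(), m2.model.weight_state()):
            assert np.array_equal(a, b)

    def test_multiclass_softmax_scores_sum_to_one(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, size=90)
        X = rng.normal(size=(90, 6)) + 2.5 * y[:, None]
        model = train_fnn(FnnConfig(loss="categorical_ce", epochs=5,
                                    batch_size=32, seed=2), (X, y))
        labels, scores = predict(model, X)
        assert np.allclose(scores.sum(axis=1), 1.0)
        assert set(labels) <= {0, 1, 2}

    def test_binary_threshold_semantics(self):
        X, y = _toy_binary()
        model = train_fnn(FnnConfig(epochs=5, batch_size=32, seed=3), (X, y))
        _, scores = predict(model, X)
        assert scores.min() >= 0.0 and scores.max() <= 1.0
        labels, _ = predict(model, X, threshold=0.0)
        assert (labels == 1).all()

    def test_single_class_rejected(self):
        X, _ = _toy_binary()
        with pytest.raises(ValueError):
            train_fnn(FnnConfig(epochs=1), (X, np.zeros(len(X))))


class TestCnn:
    def test_config_matches_architecture(self):
        config = CnnConfig()
        assert config.conv_filters == (64, 32, 32)
        assert config.spatial_dropout == 0.2
        assert config.head.dropout == 0.2

    def test_balanced_subsample_exact(self):
        y = np.array([0] * 300 + [1] * 40)
        idx = balanced_subsample(y, 30, np.random.default_rng(0))
        assert len(idx) == 60
        assert (y[idx] == 0).sum() == 30 and (y[idx] == 1).sum() == 30

    def test_balanced_subsample_insufficient_pool_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsample(np.array([0, 0, 1]), 2,
                               np.random.default_rng(0))

    def test_trains_and_predicts_on_small_elements(self, small_onehot):
        tensor, y = small_onehot
        config = CnnConfig(
            conv_filters=(8, 4, 4),
            head=FnnConfig(hidden_layers=(16,), dropout=0.2,
                           loss="binary_ce", epochs=2, batch_size=16),
            subsample_per_class=20, seed=4)
        model = train_cnn(config, (tensor, y), (tensor, y))
        assert len(model.history) == 2
        convs = [l for l in model.model.layers if isinstance(l, Conv2D)]
        assert [c.W.shape[0] for c in convs] == [8, 4, 4]
        _, scores = predict(model, tensor)
        assert scores.min() >= 0 and scores.max() <= 1

    def test_input_narrower_than_kernel_rejected(self):
        X = np.zeros((10, 1, 5, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            train_cnn(CnnConfig(subsample_per_class=5), (X, y))

    def test_five_label_input_rejected(self):
        X = np.zeros((9, 1, 5, 30))
        y = np.arange(9) % 3
        with pytest.raises(ValueError):
            train_cnn(CnnConfig(subsample_per_class=3), (X, y))


class TestPersistence:
    def test_model_roundtrip_preserves_predictions(self, tmp_path):
        X, y = _toy_binary()
        model = train_fnn(FnnConfig(epochs=3, batch_size=32, seed=6), (X, y))
        path = tmp_path / "model.joblib"
        models.save_model(model, path)
        back = models.load_model(path)
        p1, s1 = predict(model, X)
        p2, s2 = predict(back, X)
        assert np.array_equal(p1, p2) and np.allclose(s1, s2)

    def test_unfitted_network_rejected(self):
        from ltrcurator import _nn
        net = _nn.Network([_nn.Dense(3, 1, np.random.default_rng(0))],
                          _nn.BinaryCrossEntropy(), seed=0)
        model = models.TrainedModel("fnn", net, np.array([0, 1]))
        with pytest.raises(RuntimeError):
            predict(model, np.zeros((2, 3)))
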