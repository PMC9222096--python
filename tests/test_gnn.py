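import numpy as np
import pytest

from calcgraph import gnn
from calcgraph.exceptions import DegenerateLabelError
from calcgraph.graphs import CalcificationGraph, knn_adjacency
from calcgraph.synthetic import (
    benchmark_model_config,
    benchmark_train_config,
    generate_graph_dataset,
)
from conftest import literal_ecc_forward


def _random_graph(rng, n, image_shape=(64, 64), feat_dim=6, label=None):
    coords = rng.uniform(5, 55, size=(n, 2))
    return CalcificationGraph(
        coords=coords,
        adjacency=knn_adjacency(coords, 3),
        image_shape=image_shape,
        base_features=rng.normal(size=(n, feat_dim)),
        label=label,
    )


def _random_layer(rng, d_in, d_out, hidden=8):
    return {
        "w1": rng.normal(size=(3, hidden)),
        "b1": rng.normal(size=hidden),
        "w2": rng.normal(size=(hidden, d_out * d_in)),
        "b2": rng.normal(size=d_out * d_in),
        "bias": rng.normal(size=d_out),
    }


class TestEccForward:
    def test_zero_input_zero_bias_gives_zero(self):
        rng = np.random.default_rng(0)
        g = _random_graph(rng, 6)
        layer = _random_layer(rng, 6, 4)
        layer["bias"] = np.zeros(4)
        out = gnn.ecc_forward(g, layer, np.zeros((6, 6)))
        assert np.allclose(out, 0.0)

    def test_identity_filters_average_neighbors(self):
        # 3-node path graph with constant-identity filter network
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        g = CalcificationGraph(coords=coords, adjacency=adj, image_shape=(32, 32))
        d = 3
        layer = {
            "w1": np.zeros((3, 4)),
            "b1": np.zeros(4),
            "w2": np.zeros((4, d * d)),
            "b2": np.eye(d).reshape(-1),
            "bias": np.zeros(d),
        }
        x = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 4.0]])
        out = gnn.ecc_forward(g, layer, x)
        # node 0 sees {1}; node 1 sees {0, 2}; node 2 sees {1}
        assert np.allclose(out[0], x[1])
        assert np.allclose(out[1], (x[0] + x[2]) / 2)
        assert np.allclose(out[2], x[1])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_per_node_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        g = _random_graph(rng, n, feat_dim=5)
        layer = _random_layer(rng, 5, 4)
        x = rng.normal(size=(n, 5))
        expected = literal_ecc_forward(g.coords, g.adjacency, g.image_shape,
                                       layer, x)
        assert np.max(np.abs(gnn.ecc_forward(g, layer, x) - expected)) <= 1e-6


class TestReadout:
    def test_flatten_exact_concatenation_when_full(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 3))
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        out = gnn.readout(x, mode="flatten", n_max=4, coords=coords)
        order = np.lexsort((coords[:, 0], coords[:, 1]))
        assert np.array_equal(out, x[order].reshape(-1))

    def test_mean_single_node(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(gnn.readout(x, mode="mean"), x[0])

    def test_truncation_drops_lowest_scores(self):
        rng = np.random.default_rng(2)
        n, n_max = 12, 8
        x = rng.normal(size=(n, 2))
        scores = rng.permutation(n).astype(float)
        coords = np.column_stack([np.arange(n), np.zeros(n)]).astype(float)
        out = gnn.readout(x, mode="flatten", n_max=n_max, coords=coords,
                          scores=scores)
        keep = np.sort(np.argsort(-scores)[:n_max])
        assert np.array_equal(out, x[keep].reshape(-1))

    def test_padding_with_zeros(self):
        x = np.ones((2, 3))
        out = gnn.readout(x, mode="flatten", n_max=5,
                          coords=np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert out.shape == (15,)
        assert np.all(out[6:] == 0)


class TestClassify:
    def test_zero_weights_all_half(self):
        out = gnn.classify(np.ones(4), np.zeros((4, 5)), np.zeros(5))
        assert np.allclose(out.probs, 0.5)

    def test_dominant_logit_wins(self):
        w = np.zeros((1, 5))
        b = np.array([10.0, -10.0, -10.0, -10.0, -10.0])
        out = gnn.classify(np.zeros(1), w, b)
        assert out.predicted == 0 and out.probs[0] > 0.999

    def test_matches_affine_sigmoid_oracle(self):
        rng = np.random.default_rng(3)
        x, w, b = rng.normal(size=7), rng.normal(size=(7, 5)), rng.normal(size=5)
        expected = 1.0 / (1.0 + np.exp(-(x @ w + b)))
        assert np.allclose(gnn.classify(x, w, b).probs, expected, atol=1e-9)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(4)
        cfg = gnn.FocalLossConfig(gamma=0.0)
        for _ in range(200):
            p = rng.uniform(0.01, 0.99, size=5)
            y = np.zeros(5)
            y[rng.integers(5)] = 1.0
            ce = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert gnn.focal_loss(p, y, cfg) == pytest.approx(ce, abs=1e-9)

    def test_perfect_prediction_zero_loss(self):
        y = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        p = np.where(y == 1, 1.0, 0.0)
        assert gnn.focal_loss(p, y, gnn.FocalLossConfig(gamma=2.0)) \
            == pytest.approx(0.0, abs=1e-9)

    def test_single_component_half_gamma_two(self):
        # p_t = 0.5, gamma = 2 -> 0.25 * ln 2
        val = gnn.focal_loss(np.array([0.5]), np.array([1.0]),
                             gnn.FocalLossConfig(gamma=2.0))
        assert val == pytest.approx(0.25 * np.log(2), abs=1e-12)

    def test_monotone_decreasing_in_pt(self):
        cfg = gnn.FocalLossConfig(gamma=2.0)
        pts = np.linspace(0.05, 0.95, 40)
        losses = [gnn.focal_loss(np.array([p]), np.array([1.0]), cfg)
                  for p in pts]
        assert np.all(np.diff(losses) < 0)

    def test_gamma_downweights_confident_components(self):
        for p in (0.6, 0.8, 0.95):
            l0 = gnn.focal_loss(np.array([p]), np.array([1.0]),
                                gnn.FocalLossConfig(gamma=0.0))
            l2 = gnn.focal_loss(np.array([p]), np.array([1.0]),
                                gnn.FocalLossConfig(gamma=2.0))
            assert l2 <= l0


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_graph_dataset("balanced", 50, seed=3)


@pytest.fixture(scope="module")
def tiny_model(tiny_dataset):
    from dataclasses import replace

    tc = replace(benchmark_train_config(0), epochs=8)
    return gnn.train(tiny_dataset, benchmark_model_config(), tc)


class TestTraining:
    def test_loss_decreases_and_fits(self, tiny_model, tiny_dataset):
        hist = tiny_model.train_meta["loss_history"]
        assert hist[-1] < hist[0]
        preds = [gnn.predict(tiny_model, g).predicted for g in tiny_dataset]
        acc = np.mean([p == g.label for p, g in zip(preds, tiny_dataset)])
        assert acc >= 0.8  # training accuracy well above chance 0.2

    def test_single_class_rejected(self, tiny_dataset):
        ds = [g for g in tiny_dataset if g.label == 0]
        with pytest.raises(DegenerateLabelError):
            gnn.train(ds, benchmark_model_config(), benchmark_train_config(0))

    def test_contradictory_labels_plateau_without_crash(self):
        rng = np.random.default_rng(6)
        g = _random_graph(rng, 8, feat_dim=8)
        from dataclasses import replace
        import copy

        data = []
        for lab in (0, 1, 0, 1):
            dup = copy.deepcopy(g)
            dup.label = lab
            data.append(dup)
        tc = replace(benchmark_train_config(0), epochs=5, batch_size=4)
        model = gnn.train(data, benchmark_model_config(), tc)
        assert model.train_meta["final_loss"] > 0.1  # unlearnable, no crash

    def test_early_stopping_truncates_history(self, tiny_dataset):
        from dataclasses import replace

        tc = replace(benchmark_train_config(1), epochs=30, lr=0.0,
                     batch_size=64, early_stop_patience=2)
        model = gnn.train(tiny_dataset, benchmark_model_config(), tc)
        # zero learning rate -> loss never improves -> stops after patience
        assert len(model.train_meta["loss_history"]) <= 4

    def test_balanced_sampling_mode_trains(self, tiny_dataset):
        from dataclasses import replace

        tc = replace(benchmark_train_config(2), epochs=3,
                     balanced_sampling=True)
        model = gnn.train(tiny_dataset, benchmark_model_config(), tc)
        hist = model.train_meta["loss_history"]
        assert hist[-1] < hist[0]

    def test_same_seed_identical_weights(self, tiny_dataset):
        from dataclasses import replace
        from calcgraph._nn import flatten

        tc = replace(benchmark_train_config(5), epochs=3)
        m1 = gnn.train(tiny_dataset, benchmark_model_config(), tc)
        m2 = gnn.train(tiny_dataset, benchmark_model_config(), tc)
        f1, _ = flatten(m1.params)
        f2, _ = flatten(m2.params)
        assert np.array_equal(f1, f2)


class TestPredict:
    def test_permutation_invariance_mean_readout(self, tiny_model, tiny_dataset):
        g = tiny_dataset[0]
        rng = np.random.default_rng(7)
        perm = rng.permutation(g.n_nodes)
        g2 = CalcificationGraph(
            coords=g.coords[perm],
            adjacency=g.adjacency[np.ix_(perm, perm)],
            image_shape=g.image_shape,
            base_features=g.base_features[perm],
            label=g.label,
        )
        p1 = gnn.predict(tiny_model, g).probs
        p2 = gnn.predict(tiny_model, g2).probs
        assert np.allclose(p1, p2, atol=1e-9)

    def test_translation_invariance_without_spatial_embedding(self):
        from dataclasses import replace

        rng = np.random.default_rng(8)
        mc = replace(benchmark_model_config(), use_spatial_embedding=False)
        params = gnn.init_params(mc, seed=1)
        model = gnn.GnnModel(params=params, config=mc)
        g = _random_graph(rng, 10, feat_dim=8)
        g2 = CalcificationGraph(
            coords=g.coords + np.array([4.0, -3.0]),
            adjacency=g.adjacency,
            image_shape=g.image_shape,
            base_features=g.base_features,
        )
        assert np.allclose(gnn.predict(model, g).probs,
                           gnn.predict(model, g2).probs, atol=1e-9)

    def test_save_load_bit_identical(self, tiny_model, tiny_dataset, tmp_path):
        path = tmp_path / "model.npz"
        gnn.save_model(tiny_model, path)
        back = gnn.load_model(path)
        for g in tiny_dataset[:5]:
            assert np.array_equal(gnn.predict(tiny_model, g).probs,
                                  gnn.predict(back, g).probs)
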