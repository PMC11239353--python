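import numpy as np
import pytest

from fcdecode import ChebNetDecoder, DecoderConfig, build_decoding_dataset, make_splits
from fcdecode.decoder import NotFittedError, coarsen_adjacency
from fcdecode.graphs import BrainGraph
from fcdecode import nn


def _toy_graphs(rng, n_samples=60, n_nodes=6, f=3, separation=2.0):
    """Two classes whose node features differ by a mean shift."""
    graphs, labels = [], []
    for i in range(n_samples):
        cls = i % 2
        a = np.abs(np.corrcoef(rng.standard_normal((20, n_nodes)), rowvar=False))
        np.fill_diagonal(a, 0.0)
        x = rng.standard_normal((n_nodes, f)) + cls * separation
        graphs.append(BrainGraph(a, node_features=x))
        labels.append("B" if cls else "A")
    return graphs, np.array(labels)


@pytest.fixture(scope="module")
def toy_fit():
    rng = np.random.default_rng(0)
    graphs, labels = _toy_graphs(rng)
    cfg = DecoderConfig(conv_depth=1, cheb_order=2, dropout=0.2, epochs=30,
                        min_epochs=30, batch_size=16, seed=0)
    model = ChebNetDecoder(graphs, labels, config=cfg)
    return model, model.fit(), labels


class TestForward:
    def test_softmax_rows_normalize_on_any_input(self, toy_fit):
        model, res, _ = toy_fit
        probs = res.predict_proba()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs > 0) & (probs < 1))

    def test_hand_rolled_forward_oracle(self):
        """Single sample, depth 1, no dropout: the network output equals an
        independent step-by-step matrix computation."""
        rng = np.random.default_rng(3)
        n, f, k, f_out = 4, 2, 1, 3
        a = np.abs(np.corrcoef(rng.standard_normal((15, n)), rowvar=False))
        np.fill_diagonal(a, 0.0)
        x = rng.standard_normal((n, f))
        g = BrainGraph(a, node_features=x)
        cfg = DecoderConfig(conv_depth=1, cheb_order=k, dropout=0.0,
                            filters=(f_out,), epochs=1, min_epochs=1, seed=0)
        # two identical graphs with opposite labels so fitting is legal
        model = ChebNetDecoder([g, g], ["A", "B"], config=cfg)
        layers = model._build(np.random.default_rng(5), np.random.default_rng(6))
        probs = model._forward(layers, [c[:1] for c in model._cheb], model.x[:1],
                               training=False)[0]

        # independent recomputation with explicit matrix algebra
        conv, bn, _relu, _pool, _drop, _flat, dense = layers
        lt = g.scaled_laplacian
        s0, s1 = x, lt @ x
        h = s0 @ conv.weight[0] + s1 @ conv.weight[1] + conv.bias
        # batch norm in eval mode with running statistics
        h = bn.gamma * (h - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) + bn.beta
        h = np.maximum(h, 0.0)
        pooled = np.maximum(h[0::2], h[1::2])  # node pairs (0,1), (2,3)
        logits = pooled.reshape(-1) @ dense.weight + dense.bias
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(probs, expected, atol=1e-10)

    def test_equal_logits_give_half_half(self):
        assert np.allclose(nn.softmax(np.array([[2.0, 2.0]])), 0.5)


class TestTraining:
    def test_loss_at_initialization_near_ln2(self, toy_fit):
        # untrained network on balanced 2-class data: cross-entropy ~ ln 2
        model, _, labels = toy_fit
        layers = model._build(np.random.default_rng(0), np.random.default_rng(1))
        probs = model._forward(layers, model._cheb, model.x, training=False)
        onehot = np.eye(2)[model.y]
        assert nn.cross_entropy(probs, onehot) == pytest.approx(np.log(2), abs=0.2)

    def test_monotone_learning(self, toy_fit):
        _, res, _ = toy_fit
        assert res.history.train_loss.iloc[-1] < res.history.train_loss.iloc[0]

    def test_separable_classes_learned(self, toy_fit):
        model, res, labels = toy_fit
        assert res.accuracy(np.arange(len(labels))) > 0.9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        graphs, labels = _toy_graphs(rng, n_samples=24)
        cfg = DecoderConfig(conv_depth=1, epochs=5, min_epochs=5, seed=4,
                            batch_size=8)
        r1 = ChebNetDecoder(graphs, labels, config=cfg).fit()
        r2 = ChebNetDecoder(graphs, labels, config=cfg).fit()
        for l1, l2 in zip(r1._layers, r2._layers):
            for p1, p2 in zip(l1.params, l2.params):
                assert np.array_equal(p1, p2)
        assert r1.history.equals(r2.history)

    def test_single_class_rejected(self, rng):
        graphs, labels = _toy_graphs(rng, n_samples=10)
        with pytest.raises(ValueError, match="single class"):
            ChebNetDecoder(graphs, ["A"] * 10)

    def test_unfitted_model_refuses_to_predict(self, rng):
        graphs, labels = _toy_graphs(rng, n_samples=10)
        model = ChebNetDecoder(graphs, labels)
        with pytest.raises(NotFittedError):
            model.predict_proba()


class TestPrediction:
    def test_argmax_and_tie_break_to_lower_index(self, toy_fit):
        model, res, _ = toy_fit
        assert model.classes_[np.argmax(np.array([0.9, 0.1]))] == "A"
        # exact tie resolves to the first (lower-index) class
        assert model.classes_[np.argmax(np.array([0.5, 0.5]))] == "A"

    def test_batch_prediction_shape(self, toy_fit):
        _, res, labels = toy_fit
        idx = np.arange(7)
        assert res.predict(idx).shape == (7,)

    def test_summary_mentions_architecture(self, toy_fit):
        _, res, _ = toy_fit
        text = res.summary()
        assert "Chebyshev" in text and "Adam" in text

    def test_checkpoint_round_trip(self, toy_fit, tmp_path):
        model, res, _ = toy_fit
        before = res.predict_proba(np.arange(10))
        res.save(tmp_path / "ckpt")
        # perturb, then restore
        res._layers[-1].params[0][...] += 1.0
        res.load_weights(tmp_path / "ckpt")
        assert np.array_equal(res.predict_proba(np.arange(10)), before)
        assert (tmp_path / "ckpt.json").exists()

    def test_history_plot_smoke(self, toy_fit):
        import matplotlib
        matplotlib.use("Agg")
        _, res, _ = toy_fit
        ax = res.plot_history()
        assert len(ax.lines) == 2


class TestCoarsening:
    def test_pairwise_merge_sums_weights(self):
        a = np.zeros((4, 4))
        a[0, 2] = a[2, 0] = 1.0
        a[1, 3] = a[3, 1] = 2.0
        c = coarsen_adjacency(a)
        assert c.shape == (2, 2)
        assert c[0, 1] == pytest.approx(3.0)
        assert np.allclose(np.diag(c), 0.0)

    def test_odd_node_kept_alone(self):
        a = np.ones((5, 5)) - np.eye(5)
        c = coarsen_adjacency(a)
        assert c.shape == (3, 3)


class TestChanceLevel:
    def test_permuted_labels_give_chance_accuracy(self, small_cohort):
        """Destroying the state labels leaves held-out accuracy at chance."""
        ds = build_decoding_dataset(small_cohort, "FC")
        rng = np.random.default_rng(0)
        # permute window-state labels across samples
        perm_labels = rng.permutation(ds.state_labels)
        subjects = np.unique(ds.subject_ids)
        plan = make_splits(subjects, "repeated_8020", seed=0, n_repeats=1)[0]
        tr = ds.subject_index(plan.train_subjects)
        te = ds.subject_index(plan.test_subjects)
        cfg = DecoderConfig(epochs=30, min_epochs=30, seed=0)
        model = ChebNetDecoder(ds.graphs, perm_labels, ds.subject_ids, cfg)
        res = model.fit(train_idx=tr)
        acc = float(np.mean(res.predict(te) == perm_labels[te]))
        assert 0.40 <= acc <= 0.60
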