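import numpy as np
import pytest

from dgil6.estimator import DualChannelGraphClassifier
from dgil6.features import fuse_features, one_hot_encode, position_encode
from dgil6.graphs import AdjacencyMatrix, PeptideGraph
from dgil6.io_formats import PeptideRecord
from dgil6.nn import (
    forward,
    forward_batch,
    gat_attention,
    gat_layer_forward,
    gcn_layer_forward,
    global_max_pool,
    init_params,
    pack_graphs,
    predict_label,
    weighted_bce_loss,
)
from oracles import attention_oracle, gat_layer_oracle, gcn_layer_oracle, random_graph


def tiny_params(rng_seed=0, in_dim=6, hidden=8, heads=2):
    return init_params(rng_seed, in_dim=in_dim, hidden=hidden, heads=heads,
                       classifier_hidden=(4, 3, 2))


class TestGatAttention:
    def test_isolated_self_looped_node_attends_to_itself(self, rng):
        params = tiny_params()
        H = rng.normal(size=(3, 6))
        adj = np.eye(3)
        alpha = gat_attention(H, adj, params.gat_layers[0], head=0)
        np.testing.assert_allclose(alpha, np.eye(3))

    def test_identical_neighbours_share_weight(self, rng):
        params = tiny_params()
        H = rng.normal(size=(3, 6))
        H[2] = H[1]  # nodes 1 and 2 identical
        adj = np.ones((3, 3))
        alpha = gat_attention(H, adj, params.gat_layers[0], head=1)
        assert alpha[0, 1] == pytest.approx(alpha[0, 2], abs=1e-12)

    def test_rows_sum_to_one_and_zero_off_support(self, rng):
        params = tiny_params()
        H, adj = random_graph(rng, 5, 6)
        alpha = gat_attention(H, adj, params.gat_layers[0], head=0)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(alpha[adj == 0] == 0.0)

    def test_matches_exhaustive_softmax_oracle(self, rng):
        params = tiny_params(rng_seed=3)
        layer = params.gat_layers[0]
        for _ in range(5):
            H, adj = random_graph(rng, 5, 6)
            for head in range(2):
                expected = attention_oracle(
                    H, adj, layer.weight.data,
                    layer.attn_left.data[head], layer.attn_right.data[head],
                    head, heads=2,
                )
                np.testing.assert_allclose(
                    gat_attention(H, adj, layer, head), expected, atol=1e-10
                )


class TestGatLayer:
    def test_matches_dense_oracle_on_path_graph(self, rng):
        params = tiny_params(rng_seed=1)
        H = rng.normal(size=(4, 6))
        adj = np.eye(4)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        out = gat_layer_forward(H, adj, params.gat_layers[0], heads=2)
        np.testing.assert_allclose(
            out, gat_layer_oracle(H, adj, params.gat_layers[0], heads=2), atol=1e-9
        )

    def test_node_permutation_equivariance(self, rng):
        params = tiny_params(rng_seed=2)
        H, adj = random_graph(rng, 6, 6)
        out = gat_layer_forward(H, adj, params.gat_layers[0], heads=2)
        perm = rng.permutation(6)
        out_p = gat_layer_forward(
            H[perm], adj[np.ix_(perm, perm)], params.gat_layers[0], heads=2
        )
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)


class TestGcnLayer:
    def test_single_node_identity_weight_reduces_to_activation(self):
        params = init_params(0, in_dim=4, hidden=4, heads=2, classifier_hidden=(3, 2, 2))
        params.gcn_layers[0].weight.data = np.eye(4)
        H = np.array([[1.0, -2.0, 0.5, -0.1]])
        out = gcn_layer_forward(H, np.eye(1), params.gcn_layers[0])
        np.testing.assert_allclose(out, np.maximum(H, 0.0))

    def test_identical_fully_connected_nodes_get_identical_rows(self, rng):
        params = tiny_params()
        H = np.tile(rng.normal(size=(1, 6)), (2, 1))
        out = gcn_layer_forward(H, np.ones((2, 2)), params.gcn_layers[0])
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_matches_dense_linear_algebra_oracle(self, rng):
        params = tiny_params(rng_seed=4)
        H, adj = random_graph(rng, 6, 6)
        out = gcn_layer_forward(H, adj, params.gcn_layers[0])
        np.testing.assert_allclose(
            out, gcn_layer_oracle(H, adj, params.gcn_layers[0].weight.data), atol=1e-10
        )


class TestPooling:
    def test_single_node_passthrough(self):
        H = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(global_max_pool(H), H[0])

    def test_columnwise_maximum(self):
        np.testing.assert_array_equal(
            global_max_pool(np.array([[1.0, 5.0], [3.0, 2.0]])), [3.0, 5.0]
        )

    def test_invariant_to_node_shuffle(self, rng):
        H = rng.normal(size=(7, 4))
        np.testing.assert_array_equal(
            global_max_pool(H), global_max_pool(H[rng.permutation(7)])
        )

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            global_max_pool(np.empty((0, 4)))


def _graph_from(sequence, adj, rng):
    features = fuse_features(
        onehot=one_hot_encode(sequence),
        position=position_encode(len(sequence)),
        embedding=rng.normal(size=(len(sequence), 30)),
    )
    return PeptideGraph(
        record=PeptideRecord("g", sequence, 1),
        features=features,
        adjacency=AdjacencyMatrix(adj=adj),
    )


class TestForward:
    def test_deterministic_without_dropout(self, rng):
        graph = _graph_from("ACDEF", np.eye(5), rng)
        params = init_params(0)
        assert forward(graph, params) == forward(graph, params)

    def test_saturating_bias_drives_probability_to_one(self, rng):
        graph = _graph_from("ACDEF", np.eye(5), rng)
        params = init_params(0)
        params.classifier.biases[-1].data[:] = 50.0
        _, prob = forward(graph, params)
        assert prob > 1.0 - 1e-12

    def test_logit_invariant_under_node_permutation(self, rng):
        seq = "ACDEFGH"
        _, adj = random_graph(rng, 7, 1)
        graph = _graph_from(seq, adj, rng)
        params = init_params(1)
        logit, _ = forward(graph, params)
        for _ in range(3):
            perm = rng.permutation(7)
            permuted = PeptideGraph(
                record=PeptideRecord("g", "".join(seq[i] for i in perm), 1),
                features=fuse_features(
                    onehot=graph.features.values[perm, 0:20],
                    position=graph.features.values[perm, 20:40],
                    embedding=graph.features.values[perm, 40:70],
                ),
                adjacency=AdjacencyMatrix(adj=adj[np.ix_(perm, perm)]),
            )
            logit_p, _ = forward(permuted, params)
            assert logit_p == pytest.approx(logit, abs=1e-9)

    def test_padded_batch_equals_single_graph_forward(self, rng):
        graphs = [
            _graph_from("ACDEF", np.eye(5), rng),
            _graph_from("ACDEFGHIKL", np.eye(10), rng),
        ]
        params = init_params(2)
        logits, _ = forward_batch(*pack_graphs(graphs), params)
        for g, batched_logit in zip(graphs, logits.data):
            single_logit, _ = forward(g, params)
            assert single_logit == pytest.approx(batched_logit, abs=1e-10)

    def test_end_to_end_matches_scripted_recomputation(self, rng):
        """A 3-node graph recomputed step by step outside the autodiff path."""
        from oracles import gat_layer_oracle, gcn_layer_oracle

        adj = np.array([[1.0, 1, 0], [1, 1, 1], [0, 1, 1]])
        graph = _graph_from("ACD", adj, rng)
        params = init_params(7)
        H = graph.features.values
        X = H
        for layer in params.gat_layers:
            X = gat_layer_oracle(X, adj, layer, heads=params.heads)
        gat_vec = X.max(axis=0)
        gcn_vec = gcn_layer_oracle(H, adj, params.gcn_layers[0].weight.data).max(axis=0)
        x = np.concatenate([gat_vec, gcn_vec])
        for i, (w, b) in enumerate(zip(params.classifier.weights, params.classifier.biases)):
            x = x @ w.data + b.data
            if i < len(params.classifier.weights) - 1:
                x = np.maximum(x, 0.0)
        logit, prob = forward(graph, params)
        assert logit == pytest.approx(float(x[0]), abs=1e-9)
        assert prob == pytest.approx(1 / (1 + np.exp(-x[0])), abs=1e-12)

    def test_feature_width_mismatch_rejected(self, rng):
        graph = _graph_from("ACDEF", np.eye(5), rng)
        params = init_params(0, in_dim=40)
        with pytest.raises(ValueError, match="width"):
            forward(graph, params)


class TestPredictLabel:
    @pytest.mark.parametrize("prob,expected", [(0.36, 1), (0.34, 0), (0.35, 0)])
    def test_strict_threshold(self, prob, expected):
        assert predict_label(prob, 0.35) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predict_label(1.2)


class TestWeightedBce:
    def test_confident_correct_positive_has_near_zero_loss(self):
        assert weighted_bce_loss(np.array([30.0]), np.array([1])) < 1e-12

    def test_negative_at_even_odds_gives_ln2(self):
        assert weighted_bce_loss(np.array([0.0]), np.array([0])) == pytest.approx(np.log(2))

    def test_positive_at_even_odds_gives_ten_ln2(self):
        assert weighted_bce_loss(
            np.array([0.0]), np.array([1]), pos_weight=10
        ) == pytest.approx(10 * np.log(2))

    def test_non_negative_and_stable_at_extreme_logits(self, rng):
        logits = np.array([-1e4, 1e4, 0.0, -3.0])
        labels = np.array([1, 0, 1, 0])
        loss = weighted_bce_loss(logits, labels)
        assert np.isfinite(loss) and loss >= 0


def test_overfits_tiny_dataset(small_dataset):
    """Trainability: the loss collapses on 16 graphs it can memorise."""
    _, graphs = small_dataset
    subset = graphs[:16]
    est = DualChannelGraphClassifier(
        epochs=200, batch_size=16, dropout=0.0, random_state=0
    )
    est.fit(subset, [g.label for g in subset])
    assert est.loss_history_[-1] < 0.1 * est.loss_history_[0]


def test_disabling_both_channels_rejected(small_dataset):
    _, graphs = small_dataset
    est = DualChannelGraphClassifier(use_gat=False, use_gcn=False, epochs=1)
    with pytest.raises(ValueError, match="channel"):
        est.fit(graphs[:8], [g.label for g in graphs[:8]])
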