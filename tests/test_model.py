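import numpy as np
import pytest

from graphasm.autodiff import Tensor
from graphasm.features import extract_features
from graphasm.graph import AssemblyGraph
from graphasm.model import (
    EdgeScorer,
    ModelConfig,
    TransformerLayer,
    laplacian_pe,
    laplacian_spectrum,
)

from conftest import make_chain, random_graph

SMALL = ModelConfig(d=16, heads=4, layers=2, lappe_k=4, mlp_hidden=(16, 8, 1))


class TestLaplacianPE:
    def test_columns_orthogonal(self):
        rng = np.random.default_rng(5)
        graph = random_graph(20, 50, rng)
        pe = laplacian_pe(graph, 6)
        gram = pe.T @ pe
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-6)

    def test_path_graph_spectrum_closed_form(self):
        graph = make_chain([100] * 4, [40] * 3)
        vals = laplacian_spectrum(graph, normalized=False)
        expected = sorted(2 - 2 * np.cos(np.pi * j / 4) for j in range(4))
        np.testing.assert_allclose(vals, expected, atol=1e-6)

    def test_zero_eigenvalue_per_component(self):
        graph = AssemblyGraph()
        for i in range(6):
            graph.add_node(f"r{i}", "+", 100)
        graph.add_edge(0, 1, 10)
        graph.add_edge(1, 2, 10)
        graph.add_edge(3, 4, 10)  # second component; node 5 isolated = third
        vals = laplacian_spectrum(graph)
        assert int((np.abs(vals) < 1e-9).sum()) == 3

    def test_k_too_large_rejected(self):
        graph = make_chain([100, 100], [40])
        with pytest.raises(ValueError):
            laplacian_pe(graph, 2)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        graph = random_graph(15, 35, rng)
        a = laplacian_pe(graph, 5)
        b = laplacian_pe(graph, 5)
        np.testing.assert_array_equal(a, b)
        for j in range(5):
            assert a[np.argmax(np.abs(a[:, j])), j] > 0


def one_edge_layer():
    """d=1, H=1 layer with identity-like projections and zeroed FFN."""
    cfg = ModelConfig(d=1, heads=1, layers=1, lappe_k=1, mlp_hidden=(1,))
    layer = TransformerLayer(cfg, np.random.default_rng(0))
    for name in ("wq", "wk", "wv", "oh"):
        getattr(layer, name).data = np.array([[1.0]])
    for name in ("bq", "bk", "bv", "boh", "be1", "be2", "b1", "b2"):
        getattr(layer, name).data = np.zeros_like(getattr(layer, name).data)
    layer.we.data = np.array([[0.0]])
    layer.be.data = np.array([1.0])  # edge projection == 1 (neutral gate)
    for name in ("w1", "w2", "we1", "we2"):
        getattr(layer, name).data = np.zeros_like(getattr(layer, name).data)
    return cfg, layer


class TestAttentionLayer:
    def test_single_neighbor_update_is_value_projection(self):
        # one edge a -> b: softmax over b's single in-neighbor is 1, so
        # b's attention update equals V h_a (= h_a with identity weights)
        _, layer = one_edge_layer()
        h = Tensor(np.array([[2.0], [3.0]]))
        e = Tensor(np.array([[0.5]]))
        h_out, _ = layer(h, e, np.array([0]), np.array([1]), training=False)
        scale = 1.0 / np.sqrt(1.0 + layer.norm_h1.eps)  # eval-mode Norm with unit stats
        np.testing.assert_allclose(h_out.data[1], (3.0 + 2.0) * scale**2, atol=1e-4)
        np.testing.assert_allclose(h_out.data[0], 2.0 * scale**2, atol=1e-4)

    def test_no_edges_passes_through_finite(self):
        cfg = SMALL
        layer = TransformerLayer(cfg, np.random.default_rng(1))
        h = Tensor(np.random.default_rng(2).normal(size=(1, cfg.d)))
        e = Tensor(np.zeros((0, cfg.d)))
        h_out, e_out = layer(h, e, np.array([], dtype=np.intp), np.array([], dtype=np.intp), False)
        assert np.all(np.isfinite(h_out.data))
        assert e_out.shape == (0, cfg.d)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        graph = random_graph(12, 30, rng)
        model = EdgeScorer(SMALL, seed=0)
        model.forward(graph, extract_features(graph))
        dst = np.array([e.target for e in graph.edges])
        for layer in model.layers:
            attn = layer.last_attention
            for node in range(graph.num_nodes):
                rows = attn[dst == node]
                if len(rows):
                    np.testing.assert_allclose(rows.sum(axis=0), 1.0, atol=1e-6)

    def test_neutral_edge_gate_gives_uniform_attention(self):
        # identical node features + edge projection == 1 => logits equal
        # within each in-neighborhood => attention is uniform averaging
        rng = np.random.default_rng(4)
        graph = random_graph(10, 25, rng)
        model = EdgeScorer(SMALL, seed=0)
        layer = model.layers[0]
        layer.we.data = np.zeros_like(layer.we.data)
        layer.be.data = np.ones_like(layer.be.data)
        m = graph.num_nodes
        feats = extract_features(graph)
        feats.node_raw[:] = 1.0  # identical raw node features
        model.wpe.data = np.zeros_like(model.wpe.data)  # remove positional signal
        model.forward(graph, feats)
        dst = np.array([e.target for e in graph.edges])
        indeg = np.bincount(dst, minlength=m)
        attn = layer.last_attention
        for eid, node in enumerate(dst):
            np.testing.assert_allclose(attn[eid], 1.0 / indeg[node], atol=1e-9)


class TestEdgeScorer:
    def test_scores_in_open_unit_interval_with_isolated_nodes(self):
        rng = np.random.default_rng(7)
        graph = random_graph(14, 25, rng)
        graph.add_node("isolated", "+", 500)
        feats = extract_features(graph)
        scores = EdgeScorer(SMALL, seed=1).score_edges(graph, feats)
        assert scores.shape == (graph.num_edges,)
        assert np.all(np.isfinite(scores))
        assert np.all((scores > 0) & (scores < 1))

    def test_sigmoid_head_closed_forms(self):
        rng = np.random.default_rng(8)
        graph = random_graph(10, 20, rng)
        feats = extract_features(graph)
        model = EdgeScorer(SMALL, seed=2)
        w, b = model.mlp[-1]
        w.data = np.zeros_like(w.data)
        b.data = np.zeros_like(b.data)
        np.testing.assert_allclose(model.score_edges(graph, feats), 0.5, atol=1e-12)
        b.data = np.full_like(b.data, 5.0)
        np.testing.assert_allclose(
            model.score_edges(graph, feats), 1 / (1 + np.exp(-5.0)), atol=1e-9
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        graph = random_graph(12, 28, rng)
        # precondition: non-degenerate spectrum so eigenvectors are stable
        vals = laplacian_spectrum(graph)
        assert np.min(np.diff(vals[1 : SMALL.lappe_k + 2])) > 1e-6
        feats = extract_features(graph)
        model = EdgeScorer(SMALL, seed=3)
        base = model.score_edges(graph, feats)

        perm = rng.permutation(graph.num_nodes)
        relabeled = AssemblyGraph()
        order = np.argsort(perm)
        for new_id in range(graph.num_nodes):
            node = graph.nodes[order[new_id]]
            relabeled.add_node(node.read_id, node.orientation, node.read_length)
        for edge in graph.edges:  # same edge order, renamed endpoints
            relabeled.add_edge(
                int(perm[edge.source]), int(perm[edge.target]), edge.overlap_length
            )
        permuted = model.score_edges(relabeled, extract_features(relabeled))
        np.testing.assert_allclose(permuted, base, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        graph = random_graph(10, 22, rng)
        feats = extract_features(graph)
        model = EdgeScorer(SMALL, seed=4)
        before = model.score_edges(graph, feats)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = EdgeScorer.load(path)
        assert restored.config == model.config
        np.testing.assert_array_equal(restored.score_edges(graph, feats), before)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d=10, heads=3)
        with pytest.raises(ValueError):
            ModelConfig(clamp=0)
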