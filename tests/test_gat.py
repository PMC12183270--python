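import numpy as np
import pytest

from mag.cohort import PipelineConfig
from mag.connectome import BrainGraph, subject_graph
from mag.gat import (attention_scores, backward, cross_entropy, forward,
                     grid_search, init_params, make_batch, prepare_graph,
                     train_gat)


def small_config(**kw):
    base = dict(n_heads=2, hidden_units=8, n_layers=2, dropout_rate=0.0,
                knn_k=2, leaky_slope=0.2)
    base.update(kw)
    return PipelineConfig(**base)


def random_graph(n=6, seed=0, label=0):
    rng = np.random.default_rng(seed)
    return subject_graph(rng.normal(size=(3 * n, n)), k=2, label=label,
                         subject_id=f"g{seed}")


# ---------------------------------------------------------------------------
# dense oracle: full n×n attention logits with -inf masking


def dense_forward(params, graph: BrainGraph, config: PipelineConfig):
    n = graph.n_nodes
    adj = np.eye(n, dtype=bool)  # self-loops included
    for i, j in graph.edges:
        adj[i, j] = adj[j, i] = True
    x = np.asarray(graph.node_features, dtype=float)

    def leaky(v):
        return np.where(v >= 0, v, config.leaky_slope * v)

    for layer in range(config.n_layers):
        W = params[f"W{layer}"]
        K = config.n_heads
        dh = W.shape[1] // K
        h = (x @ W).reshape(n, K, dh)
        f_src = np.einsum("nkd,kd->nk", h, params[f"a_src{layer}"])
        f_dst = np.einsum("nkd,kd->nk", h, params[f"a_dst{layer}"])
        logits = leaky(f_src[:, None, :] + f_dst[None, :, :])  # (i, j, K)
        logits = np.where(adj[:, :, None], logits, -np.inf)
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        alpha = ez / ez.sum(axis=1, keepdims=True)
        out = np.einsum("ijk,jkd->ikd", alpha, h)
        x = leaky(out.reshape(n, K * dh))
    hg = x.mean(axis=0)
    logits = hg @ params["fc_W"] + params["fc_b"]
    ez = np.exp(logits - logits.max())
    return ez / ez.sum(), alpha


def test_sparse_forward_matches_dense_oracle():
    cfg = small_config(n_layers=3)
    rng = np.random.default_rng(1)
    for seed in range(4):
        g = random_graph(n=6 + seed, seed=seed, label=seed % 2)
        params = init_params(g.n_nodes, cfg, rng)
        probs, _ = forward(params, make_batch([prepare_graph(g)]), cfg)
        dense_probs, _ = dense_forward(params, g, cfg)
        np.testing.assert_allclose(probs[0], dense_probs, atol=1e-5)


def test_attention_rows_sum_to_one_and_match_dense():
    cfg = small_config()
    g = random_graph(n=7, seed=3)
    params = init_params(g.n_nodes, cfg, rng := np.random.default_rng(2))
    ei, ej, alpha = attention_scores(params, 0, g, cfg)
    sums = np.zeros((g.n_nodes, cfg.n_heads))
    np.add.at(sums, ei, alpha)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    _, dense_alpha = dense_forward(params, g, small_config(n_layers=1))
    for (i, j, a) in zip(ei, ej, alpha):
        np.testing.assert_allclose(a, dense_alpha[i, j], atol=1e-6)


def test_uniform_attention_for_identical_features_on_complete_graph():
    n = 5
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    g = BrainGraph(n_nodes=n, node_features=np.ones((n, 3)), edges=edges,
                   weights=np.ones(len(edges)), label=0, subject_id="c")
    cfg = small_config()
    params = init_params(3, cfg, np.random.default_rng(0))
    ei, ej, alpha = attention_scores(params, 0, g, cfg)
    np.testing.assert_allclose(alpha, 1.0 / n, atol=1e-12)


def test_single_node_graph_attention_is_one():
    g = BrainGraph(n_nodes=1, node_features=np.array([[0.3, -0.2]]),
                   edges=np.empty((0, 2), dtype=int), weights=np.empty(0),
                   label=1, subject_id="solo")
    cfg = small_config()
    params = init_params(2, cfg, np.random.default_rng(0))
    _, _, alpha = attention_scores(params, 0, g, cfg)
    np.testing.assert_allclose(alpha, 1.0)
    probs, _ = forward(params, make_batch([prepare_graph(g)]), cfg)
    assert probs.shape == (1, 2)


def test_probabilities_valid_and_permutation_invariant():
    cfg = small_config(n_layers=3)
    g = random_graph(n=8, seed=5)
    params = init_params(8, cfg, np.random.default_rng(4))
    probs, _ = forward(params, make_batch([prepare_graph(g)]), cfg)
    assert np.all(probs > 0) and np.all(probs < 1)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    perm = np.random.default_rng(6).permutation(8)
    inv = np.argsort(perm)
    gp = BrainGraph(n_nodes=8, node_features=g.node_features[perm],
                    edges=np.sort(inv[g.edges], axis=1), weights=g.weights,
                    label=g.label, subject_id="perm")
    probs_p, _ = forward(params, make_batch([prepare_graph(gp)]), cfg)
    np.testing.assert_allclose(probs_p, probs, atol=1e-6)


def test_zero_features_yield_bias_softmax():
    cfg = small_config()
    g = random_graph(n=5, seed=7)
    g.node_features = np.zeros_like(g.node_features)
    params = init_params(5, cfg, np.random.default_rng(8))
    probs, _ = forward(params, make_batch([prepare_graph(g)]), cfg)
    b = params["fc_b"]
    expected = np.exp(b - b.max())
    expected /= expected.sum()
    np.testing.assert_allclose(probs[0], expected, atol=1e-12)


def test_gradients_match_finite_differences():
    cfg = small_config()
    graphs = [random_graph(n=5, seed=s, label=s % 2) for s in range(3)]
    batch = make_batch([prepare_graph(g) for g in graphs])
    rng = np.random.default_rng(9)
    params = init_params(5, cfg, rng)
    probs, caches = forward(params, batch, cfg)
    grads = backward(params, batch, caches, cfg)
    eps = 1e-6
    for key in params:
        flat, gflat = params[key].ravel(), grads[key].ravel()
        for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = cross_entropy(forward(params, batch, cfg)[0], batch.labels)
            flat[idx] = orig - eps
            lm = cross_entropy(forward(params, batch, cfg)[0], batch.labels)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[idx] == pytest.approx(num, abs=1e-6, rel=1e-3)


def test_training_learns_separable_graphs():
    """Class signal planted directly in node features: near-perfect fit."""
    rng = np.random.default_rng(10)
    graphs = []
    for i in range(40):
        label = i % 2
        series = rng.normal(size=(30, 10)) + (1.5 * label) * np.outer(
            np.sin(np.arange(30)), np.ones(10))
        graphs.append(subject_graph(series, k=3, label=label, subject_id=f"t{i}"))
    cfg = small_config(max_epochs=200, patience=200, batch_size=8,
                       hidden_units=16, dropout_rate=0.1)
    model = train_gat(graphs, graphs[:8], cfg, atlas="toy", seed=0)
    batch = make_batch([prepare_graph(g) for g in graphs])
    probs, _ = forward(model.params, batch, cfg)
    train_acc = np.mean(probs.argmax(axis=1) == batch.labels)
    assert train_acc >= 0.95
    assert model.training_log[-1]["train_loss"] < model.training_log[0]["train_loss"]


def test_training_determinism_and_zero_lr():
    graphs = [random_graph(n=6, seed=s, label=s % 2) for s in range(12)]
    cfg = small_config(max_epochs=5, patience=5, dropout_rate=0.3)
    m1 = train_gat(graphs[:8], graphs[8:], cfg, atlas="a", seed=3)
    m2 = train_gat(graphs[:8], graphs[8:], cfg, atlas="a", seed=3)
    assert m1.val_accuracy == m2.val_accuracy
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])

    frozen = train_gat(graphs[:8], graphs[8:],
                       small_config(max_epochs=4, patience=4, learning_rate=0.0),
                       atlas="a", seed=3)
    init = init_params(6, small_config(max_epochs=4, patience=4, learning_rate=0.0),
                       np.random.default_rng())
    losses = [row["train_loss"] for row in frozen.training_log]
    assert np.ptp(losses) < 1e-12  # loss constant across epochs
    with pytest.raises(ValueError, match="empty"):
        train_gat([], [], cfg)
    with pytest.raises(ValueError, match="both classes"):
        train_gat([g for g in graphs if g.label == 0], graphs, cfg)


def test_grid_search_single_cell_and_sabotage():
    graphs = [random_graph(n=6, seed=s, label=s % 2) for s in range(12)]
    cfg = small_config(max_epochs=3, patience=3)
    best, table = grid_search(graphs[:8], graphs[8:], cfg,
                              grid={"learning_rate": [1e-3]})
    assert best.learning_rate == 1e-3 and len(table) == 1
    best2, table2 = grid_search(graphs[:8], graphs[8:], cfg,
                                grid={"learning_rate": [1e-3, 1e3]})
    assert best2.learning_rate == 1e-3  # diverging cell never wins
    assert len(table2) == 2
    with pytest.raises(ValueError, match="non-empty"):
        grid_search(graphs[:8], graphs[8:], cfg, grid={"learning_rate": []})
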