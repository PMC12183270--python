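"""Graph attention network for whole-graph classification, in NumPy.

Architecture: three stacked graph-attention layers with K=4 heads
(concatenated, head width 16 so the layer width is 64), LeakyReLU
nonlinearities, dropout on node features before each layer, global average
pooling over node embeddings, and an affine head with softmax over the two
classes.

Per layer and head, with shared linear map W and attention vector
a = [a_src ∥ a_dst]:

    e_ij   = LeakyReLU(a_srcᵀ W h_i + a_dstᵀ W h_j)       j ∈ N(i) ∪ {i}
    α_ij   = softmax_j(e_ij)
    h_i'   = σ(Σ_j α_ij W h_j)

Self-loops are added inside the layer; edge weights from the KNN graph are
not used by attention (attention is a function of node features only).

Training: minibatch Adam with coupled L2 weight decay on the cross-entropy
loss, early stopping on validation loss with parameter restore from the best
epoch. Forward and backward passes are hand-vectorized over a disjoint union
("batch graph") of the minibatch's graphs; gradients are exact (verified
against finite differences in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._rng import substream
from .cohort import PipelineConfig
from .connectome import BrainGraph

Params = Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# graph preparation


@dataclass
class PreparedGraph:
    """Edge structure with self-loops, ready for vectorized attention."""

    x: np.ndarray  # (n, d) node features
    ei: np.ndarray  # (m,) center node of each attention pair, sorted
    ej: np.ndarray  # (m,) neighbor node
    counts: np.ndarray  # (n,) pairs per center node
    label: int
    n_nodes: int


def prepare_graph(graph: BrainGraph) -> PreparedGraph:
    n = graph.n_nodes
    e = graph.edges
    ei = np.concatenate([e[:, 0], e[:, 1], np.arange(n)])
    ej = np.concatenate([e[:, 1], e[:, 0], np.arange(n)])
    order = np.lexsort((ej, ei))
    ei, ej = ei[order], ej[order]
    counts = np.bincount(ei, minlength=n)
    return PreparedGraph(x=np.asarray(graph.node_features, dtype=float),
                         ei=ei, ej=ej, counts=counts,
                         label=graph.label, n_nodes=n)


@dataclass
class GraphBatch:
    """Disjoint union of several prepared graphs (same feature width)."""

    x: np.ndarray
    ei: np.ndarray
    ej: np.ndarray
    node_starts: np.ndarray  # (m_groups,) reduceat offsets for ei groups
    ei_rep: np.ndarray  # map group -> edges, via np.repeat(counts)
    perm_ej: np.ndarray  # permutation sorting pairs by ej
    ej_starts: np.ndarray  # reduceat offsets over perm_ej groups
    graph_of_node: np.ndarray  # (n_total,)
    graph_starts: np.ndarray  # (B,) node offsets per graph
    n_per_graph: np.ndarray  # (B,)
    labels: np.ndarray  # (B,)


def make_batch(graphs: Sequence[PreparedGraph]) -> GraphBatch:
    xs, eis, ejs, counts, labels, sizes = [], [], [], [], [], []
    offset = 0
    for g in graphs:
        xs.append(g.x)
        eis.append(g.ei + offset)
        ejs.append(g.ej + offset)
        counts.append(g.counts)
        labels.append(g.label)
        sizes.append(g.n_nodes)
        offset += g.n_nodes
    x = np.vstack(xs)
    ei = np.concatenate(eis)
    ej = np.concatenate(ejs)
    counts = np.concatenate(counts)
    node_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    perm_ej = np.lexsort((ei, ej))
    ej_counts = np.bincount(ej, minlength=x.shape[0])
    ej_starts = np.concatenate([[0], np.cumsum(ej_counts)[:-1]])
    n_per_graph = np.asarray(sizes)
    graph_starts = np.concatenate([[0], np.cumsum(n_per_graph)[:-1]])
    graph_of_node = np.repeat(np.arange(len(graphs)), n_per_graph)
    return GraphBatch(x=x, ei=ei, ej=ej, node_starts=node_starts,
                      ei_rep=counts, perm_ej=perm_ej, ej_starts=ej_starts,
                      graph_of_node=graph_of_node, graph_starts=graph_starts,
                      n_per_graph=n_per_graph, labels=np.asarray(labels))


# ---------------------------------------------------------------------------
# parameters


def init_params(in_dim: int, config: PipelineConfig, rng: np.random.Generator) -> Params:
    """Uniform fan-in initialization: U(−1/√fan_in, 1/√fan_in)."""
    if config.hidden_units % config.n_heads:
        raise ValueError("hidden_units must be divisible by n_heads")
    dh = config.hidden_units // config.n_heads
    params: Params = {}
    d = in_dim
    for layer in range(config.n_layers):
        bound_w = 1.0 / math.sqrt(d)
        params[f"W{layer}"] = rng.uniform(-bound_w, bound_w, size=(d, config.n_heads * dh))
        bound_a = 1.0 / math.sqrt(2 * dh)
        params[f"a_src{layer}"] = rng.uniform(-bound_a, bound_a, size=(config.n_heads, dh))
        params[f"a_dst{layer}"] = rng.uniform(-bound_a, bound_a, size=(config.n_heads, dh))
        d = config.hidden_units if config.head_combine == "concat" else dh
    bound_fc = 1.0 / math.sqrt(d)
    params["fc_W"] = rng.uniform(-bound_fc, bound_fc, size=(d, 2))
    params["fc_b"] = rng.uniform(-bound_fc, bound_fc, size=2)
    return params


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def _seg_rep(values: np.ndarray, batch: GraphBatch) -> np.ndarray:
    """Broadcast per-center-node values back to their attention pairs."""
    return np.repeat(values, batch.ei_rep, axis=0)


# ---------------------------------------------------------------------------
# forward / backward


def _layer_forward(params: Params, layer: int, x: np.ndarray, batch: GraphBatch,
                   config: PipelineConfig) -> Tuple[np.ndarray, dict]:
    K = config.n_heads
    W = params[f"W{layer}"]
    a_src = params[f"a_src{layer}"]
    a_dst = params[f"a_dst{layer}"]
    dh = W.shape[1] // K
    h = (x @ W).reshape(-1, K, dh)  # (n, K, dh)
    f_src = np.einsum("nkd,kd->nk", h, a_src)
    f_dst = np.einsum("nkd,kd->nk", h, a_dst)
    z = f_src[batch.ei] + f_dst[batch.ej]  # (m, K) attention logits
    zl = _leaky(z, config.leaky_slope)
    zmax = np.maximum.reduceat(zl, batch.node_starts, axis=0)
    ez = np.exp(zl - _seg_rep(zmax, batch))
    denom = np.add.reduceat(ez, batch.node_starts, axis=0)
    alpha = ez / _seg_rep(denom, batch)  # (m, K)
    msg = alpha[:, :, None] * h[batch.ej]  # (m, K, dh)
    agg = np.add.reduceat(msg, batch.node_starts, axis=0)  # (n, K, dh)
    if config.head_combine == "concat":
        pre = agg.reshape(x.shape[0], K * dh)
    else:
        pre = agg.mean(axis=1)
    out = _leaky(pre, config.leaky_slope)
    cache = dict(x=x, h=h, z=z, alpha=alpha, pre=pre, W=W,
                 a_src=a_src, a_dst=a_dst, dh=dh)
    return out, cache


def _layer_backward(grads: Params, layer: int, dout: np.ndarray, cache: dict,
                    batch: GraphBatch, config: PipelineConfig) -> np.ndarray:
    K = config.n_heads
    dh = cache["dh"]
    h, alpha, z = cache["h"], cache["alpha"], cache["z"]
    n = h.shape[0]
    dpre = dout * _leaky_grad(cache["pre"], config.leaky_slope)
    if config.head_combine == "concat":
        dagg = dpre.reshape(n, K, dh)
    else:
        dagg = np.repeat(dpre[:, None, :], K, axis=1) / K
    dagg_e = dagg[batch.ei]  # (m, K, dh): upstream per pair
    # alpha path
    dalpha = np.einsum("mkd,mkd->mk", dagg_e, h[batch.ej])
    s = alpha * dalpha
    ssum = np.add.reduceat(s, batch.node_starts, axis=0)
    dz = (s - alpha * _seg_rep(ssum, batch)) * _leaky_grad(z, config.leaky_slope)
    # message path into h[ej]
    dmsg = alpha[:, :, None] * dagg_e  # (m, K, dh)
    dh_nodes = np.add.reduceat(dmsg[batch.perm_ej], batch.ej_starts, axis=0)
    # logit paths
    df_src = np.add.reduceat(dz, batch.node_starts, axis=0)  # (n, K)
    df_dst = np.add.reduceat(dz[batch.perm_ej], batch.ej_starts, axis=0)
    dh_nodes = dh_nodes + df_src[:, :, None] * cache["a_src"][None]
    dh_nodes = dh_nodes + df_dst[:, :, None] * cache["a_dst"][None]
    grads[f"a_src{layer}"] = np.einsum("nk,nkd->kd", df_src, h)
    grads[f"a_dst{layer}"] = np.einsum("nk,nkd->kd", df_dst, h)
    dh_flat = dh_nodes.reshape(n, K * dh)
    grads[f"W{layer}"] = cache["x"].T @ dh_flat
    return dh_flat @ cache["W"].T


def forward(params: Params, batch: GraphBatch, config: PipelineConfig,
            train_mode: bool = False, rng: np.random.Generator | None = None,
            ) -> Tuple[np.ndarray, list]:
    """Class probabilities (B, 2) for every graph in the batch.

    ``train_mode`` enables inverted dropout on node features before each
    layer (requires ``rng``); inference is deterministic.
    """
    x = batch.x
    caches = []
    for layer in range(config.n_layers):
        if train_mode and config.dropout_rate > 0:
            mask = (rng.uniform(size=x.shape) >= config.dropout_rate) / (1.0 - config.dropout_rate)
            x = x * mask
        else:
            mask = None
        out, cache = _layer_forward(params, layer, x, batch, config)
        cache["mask"] = mask
        caches.append(cache)
        x = out
    # global average pooling per graph
    sums = np.add.reduceat(x, batch.graph_starts, axis=0)
    hg = sums / batch.n_per_graph[:, None]
    logits = hg @ params["fc_W"] + params["fc_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(logits)
    probs = ez / ez.sum(axis=1, keepdims=True)
    caches.append(dict(hg=hg, probs=probs, x_last=x))
    return probs, caches


def backward(params: Params, batch: GraphBatch, caches: list,
             config: PipelineConfig) -> Params:
    """Gradients of the mean cross-entropy w.r.t. every parameter."""
    head = caches[-1]
    probs, hg = head["probs"], head["hg"]
    B = probs.shape[0]
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), batch.labels] = 1.0
    dlogits = (probs - onehot) / B
    grads: Params = {
        "fc_W": hg.T @ dlogits,
        "fc_b": dlogits.sum(axis=0),
    }
    dhg = dlogits @ params["fc_W"].T
    dx = np.repeat(dhg / batch.n_per_graph[:, None], batch.n_per_graph, axis=0)
    for layer in range(config.n_layers - 1, -1, -1):
        cache = caches[layer]
        dx = _layer_backward(grads, layer, dx, cache, batch, config)
        if cache["mask"] is not None:
            dx = dx * cache["mask"]
    return grads


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


def attention_scores(params: Params, layer: int, graph: BrainGraph | PreparedGraph,
                     config: PipelineConfig, x: np.ndarray | None = None,
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ei, ej, α) for one layer on one graph; rows of α sum to 1 per node/head."""
    pg = graph if isinstance(graph, PreparedGraph) else prepare_graph(graph)
    batch = make_batch([pg])
    feats = pg.x if x is None else x
    _, cache = _layer_forward(params, layer, feats, batch, config)
    return batch.ei, batch.ej, cache["alpha"]


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedAtlasModel:
    atlas: str
    params: Params
    config: PipelineConfig
    val_accuracy: float
    training_log: List[dict] = field(default_factory=list)

    def predict_proba(self, graphs: Sequence[BrainGraph]) -> np.ndarray:
        prepared = [prepare_graph(g) for g in graphs]
        probs, _ = forward(self.params, make_batch(prepared), self.config, train_mode=False)
        return probs


class _Adam:
    def __init__(self, params: Params, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd, self.betas, self.eps = lr, weight_decay, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k in params:
            g = grads[k] + self.wd * params[k]  # coupled L2 weight decay
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def evaluate_graphs(params: Params, prepared: Sequence[PreparedGraph],
                    config: PipelineConfig, chunk: int = 64) -> Tuple[float, float, np.ndarray]:
    """(mean loss, accuracy, probabilities) on a list of prepared graphs."""
    losses, correct, all_probs = [], 0, []
    for start in range(0, len(prepared), chunk):
        part = prepared[start:start + chunk]
        batch = make_batch(part)
        probs, _ = forward(params, batch, config, train_mode=False)
        losses.append(cross_entropy(probs, batch.labels) * len(part))
        correct += int((probs.argmax(axis=1) == batch.labels).sum())
        all_probs.append(probs)
    n = len(prepared)
    return sum(losses) / n, correct / n, np.vstack(all_probs)


def train_gat(train_graphs: Sequence[BrainGraph], val_graphs: Sequence[BrainGraph],
              config: PipelineConfig, atlas: str = "", seed: int | None = None,
              ) -> TrainedAtlasModel:
    """Train one per-atlas model; deterministic given the seed.

    Minibatch Adam on cross-entropy with L2 weight decay; early stopping on
    validation loss with the configured patience; the returned parameters are
    those of the best-validation-loss epoch and ``val_accuracy`` is measured
    there.
    """
    if not train_graphs:
        raise ValueError("empty training set")
    if len({g.label for g in train_graphs}) < 2:
        raise ValueError("training set must contain both classes")
    seed = config.seed if seed is None else seed
    rng_init = substream(seed, "init", atlas)
    rng_drop = substream(seed, "dropout", atlas)
    rng_shuf = substream(seed, "batches", atlas)

    train_p = [prepare_graph(g) for g in train_graphs]
    val_p = [prepare_graph(g) for g in val_graphs]
    in_dim = train_p[0].x.shape[1]
    params = init_params(in_dim, config, rng_init)
    opt = _Adam(params, config.learning_rate, config.weight_decay)

    best = dict(loss=np.inf, acc=0.0, params={k: v.copy() for k, v in params.items()})
    log: List[dict] = []
    since_best = 0
    for epoch in range(config.max_epochs):
        idx = rng_shuf.permutation(len(train_p))
        epoch_loss, seen = 0.0, 0
        diverged = False
        for start in range(0, len(idx), config.batch_size):
            part = [train_p[i] for i in idx[start:start + config.batch_size]]
            batch = make_batch(part)
            probs, caches = forward(params, batch, config, train_mode=True, rng=rng_drop)
            loss = cross_entropy(probs, batch.labels)
            if not np.isfinite(loss):
                diverged = True
                break
            grads = backward(params, batch, caches, config)
            opt.step(params, grads)
            epoch_loss += loss * len(part)
            seen += len(part)
        if diverged or not all(np.all(np.isfinite(v)) for v in params.values()):
            log.append(dict(epoch=epoch, train_loss=float("nan"),
                            val_loss=float("nan"), val_acc=0.0))
            break
        val_loss, val_acc, _ = evaluate_graphs(params, val_p, config) if val_p else (epoch_loss / seen, 0.0, None)
        log.append(dict(epoch=epoch, train_loss=epoch_loss / seen,
                        val_loss=val_loss, val_acc=val_acc))
        if val_loss < best["loss"] - 1e-12:
            best = dict(loss=val_loss, acc=val_acc,
                        params={k: v.copy() for k, v in params.items()})
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    return TrainedAtlasModel(atlas=atlas, params=best["params"], config=config,
                             val_accuracy=best["acc"], training_log=log)


DEFAULT_GRID = {
    "learning_rate": [1e-2, 1e-3, 1e-4, 1e-5],
    "weight_decay": [1e-3, 5e-4, 1e-4, 5e-5],
    "batch_size": [8, 16, 32, 64],
    "dropout_rate": [0.2, 0.3, 0.4, 0.5],
}


def grid_search(train_graphs, val_graphs, config: PipelineConfig,
                grid: Dict[str, list] | None = None, atlas: str = "",
                ) -> Tuple[PipelineConfig, List[dict]]:
    """Exhaustive hyperparameter sweep; best cell by validation accuracy.

    Ties break toward the lower learning rate, then the lower weight decay.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise ValueError("grid must be non-empty")
    keys = list(grid)
    table: List[dict] = []
    best_cfg, best_key = None, None
    from itertools import product
    for combo in product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, combo))
        cfg = config.replace(**cell)
        model = train_gat(train_graphs, val_graphs, cfg, atlas=atlas)
        row = dict(cell)
        row["val_accuracy"] = model.val_accuracy
        table.append(row)
        key = (-model.val_accuracy, cell.get("learning_rate", 0.0),
               cell.get("weight_decay", 0.0))
        if best_key is None or key < best_key:
            best_key, best_cfg = key, cfg
    return best_cfg, table
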