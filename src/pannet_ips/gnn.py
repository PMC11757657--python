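"""Graph neural network scoring of interface cell-graphs.

Each selected patch's cell-graph is classified into IPS1/IPS2/IPS3 by a
message-passing network trained under a distance-weighted loss
("InfiltrationLoss"): the per-patch cross-entropy terms of a batch are
weighted by

    w(d_i) = exp(-lambda * d_i) / sum_j exp(-lambda * d_j),

so patches at the tumor-parenchyma interface (hop distance d = 0) dominate
the objective and the influence of deeper patches decays exponentially.
With lambda = 0 the loss reduces to the unweighted mean cross-entropy. The
weights are normalized within each batch, which decouples lambda from the
learning rate.

The network uses graph-isomorphism-style layers — sum aggregation over
similarity-weighted neighbors followed by a two-layer ReLU node update —
with a mean (configurable) readout and a linear softmax head. Training is
plain Adam with full manual backpropagation in numpy: single-CPU runs with
a fixed seed are bitwise reproducible.

At inference, the patch predictions of a case's three slides are pooled
into one bag and the case IPS is decided by plurality vote (ties broken by
the largest summed class probability across the bag). A Graph-GradCAM-style
node-attention map is available for inspecting which nuclei drive a
prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .cell_graph import CellGraph, FeatureStats, N_FEATURES
from .labels import IPS_CLASSES

__all__ = [
    "GNNConfig",
    "GNNModel",
    "PatchPrediction",
    "CasePrediction",
    "infiltration_loss",
    "train_gnn",
    "predict_patches",
    "predict_case",
    "node_attention_map",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class GNNConfig:
    """Hyperparameters of the cell-graph classifier."""

    n_layers: int = 3
    hidden: int = 32
    readout: str = "mean"  # mean | sum | max
    dropout: float = 0.1
    learning_rate: float = 0.01
    epochs: int = 40
    batch_size: int = 32
    decay_rate: float = 0.5  # lambda of the distance-weighted loss
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one message-passing layer")
        if self.decay_rate < 0:
            raise ValueError("decay rate lambda must be >= 0")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")

    def with_seed(self, seed: int) -> "GNNConfig":
        return replace(self, seed=int(seed))


@dataclass
class PatchPrediction:
    slide_id: str
    coords: Tuple[int, int]
    predicted_ips: str
    probabilities: np.ndarray  # triple over IPS_CLASSES, sums to 1
    hop_distance: int


@dataclass
class CasePrediction:
    case_id: str
    predicted_ips: str
    tally: Dict[str, int]
    n_patches: int


def infiltration_loss(cross_entropies: np.ndarray, hop_distances: np.ndarray,
                      decay_rate: float) -> float:
    """Distance-weighted classification loss of one batch.

    ``loss = sum_i w(d_i) * CE_i`` with ``w(d) = exp(-lambda d)`` normalized
    over the batch. Weights sum to 1 and decrease strictly in d for
    lambda > 0; lambda = 0 gives the plain mean cross-entropy.
    """
    ce = np.asarray(cross_entropies, dtype=float)
    d = np.asarray(hop_distances, dtype=float)
    if decay_rate < 0:
        raise ValueError("decay rate lambda must be >= 0")
    if (d < 0).any():
        raise ValueError("hop distances must be >= 0")
    if ce.shape != d.shape:
        raise ValueError("one hop distance per cross-entropy term required")
    w = _distance_weights(d, decay_rate)
    return float(np.sum(w * ce))


def _distance_weights(d: np.ndarray, decay_rate: float) -> np.ndarray:
    logits = -decay_rate * np.asarray(d, dtype=float)
    logits = logits - logits.max()  # numerical stability
    e = np.exp(logits)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Model


@dataclass
class GNNModel:
    config: GNNConfig
    params: Dict[str, np.ndarray]
    classes: Tuple[str, ...] = IPS_CLASSES
    feature_stats: Optional[FeatureStats] = None
    trained: bool = False


def _init_params(cfg: GNNConfig, rng: np.random.Generator,
                 in_dim: int = N_FEATURES) -> Dict[str, np.ndarray]:
    params: Dict[str, np.ndarray] = {}
    dim = in_dim
    for l in range(cfg.n_layers):
        for name, shape in ((f"W1_{l}", (dim, cfg.hidden)),
                            (f"W2_{l}", (cfg.hidden, cfg.hidden))):
            fan_in = shape[0]
            params[name] = rng.normal(0, np.sqrt(2.0 / fan_in), size=shape)
        params[f"b1_{l}"] = np.zeros(cfg.hidden)
        params[f"b2_{l}"] = np.zeros(cfg.hidden)
        dim = cfg.hidden
    params["Wc"] = rng.normal(0, np.sqrt(2.0 / dim), size=(dim, 3))
    params["bc"] = np.zeros(3)
    return params


def _assemble_batch(graphs: Sequence[CellGraph]):
    """Concatenate graphs into block matrices for vectorized message passing."""
    X = np.vstack([g.features for g in graphs])
    sizes = np.array([g.n_nodes for g in graphs])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_total = int(offsets[-1])
    rows, cols, vals = [], [], []
    for g, off in zip(graphs, offsets[:-1]):
        if g.n_edges:
            i = g.edges[:, 0] + off
            j = g.edges[:, 1] + off
            rows.extend([i, j])
            cols.extend([j, i])
            vals.extend([g.weights, g.weights])
    if rows:
        A = sp.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_total, n_total))
    else:
        A = sp.csr_matrix((n_total, n_total))
    graph_index = np.repeat(np.arange(len(graphs)), sizes)
    return X, A, graph_index, sizes


def _forward(params: Dict[str, np.ndarray], cfg: GNNConfig,
             X: np.ndarray, A: sp.csr_matrix, graph_index: np.ndarray,
             sizes: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
    """Message passing + readout + linear head; returns logits (B, 3)."""
    H = X
    layer_caches = []
    for l in range(cfg.n_layers):
        S = H + A @ H
        Z1 = S @ params[f"W1_{l}"] + params[f"b1_{l}"]
        H1 = np.maximum(Z1, 0.0)
        Z2 = H1 @ params[f"W2_{l}"] + params[f"b2_{l}"]
        H_out = np.maximum(Z2, 0.0)
        if cache is not None:
            layer_caches.append({"S": S, "m1": Z1 > 0, "H1": H1,
                                 "m2": Z2 > 0})
        H = H_out
    B = len(sizes)
    if cfg.readout == "max":
        g = np.full((B, H.shape[1]), -np.inf)
        np.maximum.at(g, graph_index, H)
        argmax = None
        if cache is not None:
            # route gradient to the (first) argmax node per graph/channel
            argmax = np.zeros((B, H.shape[1]), dtype=int)
            for b in range(B):
                nodes = np.nonzero(graph_index == b)[0]
                argmax[b] = nodes[np.argmax(H[nodes], axis=0)]
    else:
        g = np.zeros((B, H.shape[1]))
        np.add.at(g, graph_index, H)
        if cfg.readout == "mean":
            g = g / sizes[:, None]
        argmax = None
    logits = g @ params["Wc"] + params["bc"]
    if cache is not None:
        cache.update({"layers": layer_caches, "H_last": H, "g": g,
                      "argmax": argmax})
    return logits


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _backward(params, cfg: GNNConfig, cache: dict, A: sp.csr_matrix,
              graph_index: np.ndarray, sizes: np.ndarray,
              dlogits: np.ndarray, dropout_mask: Optional[np.ndarray]
              ) -> Dict[str, np.ndarray]:
    grads: Dict[str, np.ndarray] = {}
    g = cache["g_dropped"]
    grads["Wc"] = g.T @ dlogits
    grads["bc"] = dlogits.sum(axis=0)
    dg = dlogits @ params["Wc"].T
    if dropout_mask is not None:
        dg = dg * dropout_mask
    if cfg.readout == "max":
        dH = np.zeros_like(cache["H_last"])
        argmax = cache["argmax"]
        for b in range(len(sizes)):
            for k in range(dH.shape[1]):
                dH[argmax[b, k], k] += dg[b, k]
    else:
        scale = dg / sizes[:, None] if cfg.readout == "mean" else dg
        dH = scale[graph_index]
    for l in reversed(range(cfg.n_layers)):
        c = cache["layers"][l]
        dZ2 = dH * c["m2"]
        grads[f"W2_{l}"] = c["H1"].T @ dZ2
        grads[f"b2_{l}"] = dZ2.sum(axis=0)
        dH1 = dZ2 @ params[f"W2_{l}"].T
        dZ1 = dH1 * c["m1"]
        grads[f"W1_{l}"] = c["S"].T @ dZ1
        grads[f"b1_{l}"] = dZ1.sum(axis=0)
        dS = dZ1 @ params[f"W1_{l}"].T
        dH = dS + A.T @ dS  # A symmetric
    return grads


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_gnn(
    graphs: Sequence[CellGraph],
    labels: Sequence[str],
    config: Optional[GNNConfig] = None,
    feature_stats: Optional[FeatureStats] = None,
) -> Tuple[GNNModel, List[dict]]:
    """Train the cell-graph classifier under the distance-weighted loss.

    ``labels`` carries one IPS label per graph; under the weak-supervision
    scheme the case-level label is assigned to every selected patch of that
    case. Graphs must already carry standardized node features. Returns the
    trained model and a per-epoch training log.
    """
    cfg = config if config is not None else GNNConfig()
    graphs = list(graphs)
    labels = list(labels)
    if not graphs:
        raise ValueError("empty training set")
    if len(graphs) != len(labels):
        raise ValueError("one label per graph required")
    if len(set(labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if not all(g.standardized for g in graphs):
        raise ValueError("graphs must be feature-standardized before training")

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng, in_dim=graphs[0].features.shape[1])
    opt = _Adam(params, cfg.learning_rate)
    y_idx = np.array([IPS_CLASSES.index(lab) for lab in labels])
    d_all = np.array([g.hop_distance for g in graphs], dtype=float)

    log: List[dict] = []
    n = len(graphs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [graphs[i] for i in idx]
            X, A, gi, sizes = _assemble_batch(batch)
            cache: dict = {}
            logits = _forward(params, cfg, X, A, gi, sizes, cache)
            g = cache["g"]
            if cfg.dropout > 0:
                mask = (rng.random(g.shape) >= cfg.dropout) / (1 - cfg.dropout)
            else:
                mask = None
            g_dropped = g * mask if mask is not None else g
            cache["g_dropped"] = g_dropped
            logits = g_dropped @ params["Wc"] + params["bc"]
            p = _softmax(logits)
            y = y_idx[idx]
            ce = -np.log(np.clip(p[np.arange(len(idx)), y], 1e-12, None))
            w = _distance_weights(d_all[idx], cfg.decay_rate)
            loss = float(np.sum(w * ce))
            onehot = np.zeros_like(p)
            onehot[np.arange(len(idx)), y] = 1.0
            dlogits = w[:, None] * (p - onehot)
            grads = _backward(params, cfg, cache, A, gi, sizes, dlogits, mask)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        log.append({"epoch": epoch, "loss": epoch_loss / max(1, n_batches)})

    model = GNNModel(config=cfg, params=params, feature_stats=feature_stats,
                     trained=True)
    return model, log


def predict_patches(model: GNNModel, graphs: Sequence[CellGraph]
                    ) -> List[PatchPrediction]:
    """Deterministic inference: one class-probability triple per graph."""
    if not model.trained:
        raise ValueError("model is not trained")
    graphs = list(graphs)
    if not graphs:
        return []
    X, A, gi, sizes = _assemble_batch(graphs)
    logits = _forward(model.params, model.config, X, A, gi, sizes)
    p = _softmax(logits)
    out = []
    for g, probs in zip(graphs, p):
        k = int(np.argmax(probs))
        out.append(PatchPrediction(
            slide_id=g.slide_id, coords=g.coords,
            predicted_ips=model.classes[k], probabilities=probs,
            hop_distance=g.hop_distance))
    return out


def predict_case(model: GNNModel, bag: Sequence[CellGraph],
                 case_id: str = "") -> CasePrediction:
    """Bag voting: plurality over the patch predictions of a case's slides.

    The bag pools the representative patches of all three slides of the
    case. Ties are broken by the largest summed class probability over the
    bag, then by class order — deterministic and invariant to bag ordering.
    """
    bag = list(bag)
    if not bag:
        raise ValueError("no representative patches in the bag")
    preds = predict_patches(model, bag)
    tally = {c: 0 for c in model.classes}
    prob_sum = np.zeros(len(model.classes))
    for p in preds:
        tally[p.predicted_ips] += 1
        prob_sum += p.probabilities
    best = max(tally.values())
    tied = [c for c in model.classes if tally[c] == best]
    if len(tied) > 1:
        tied.sort(key=lambda c: (-prob_sum[model.classes.index(c)],
                                 model.classes.index(c)))
    return CasePrediction(case_id=case_id, predicted_ips=tied[0],
                          tally=tally, n_patches=len(bag))


def node_attention_map(model: GNNModel, graph: CellGraph,
                       target_class: str) -> np.ndarray:
    """Graph-GradCAM-style node attention for one graph and class.

    The gradient of the target-class logit with respect to the last
    message-passing layer's node activations is channel-averaged into
    weights, combined with the activations per node, rectified at zero,
    and max-normalized into [0, 1].
    """
    if not model.trained:
        raise ValueError("model is not trained")
    cfg = model.config
    X, A, gi, sizes = _assemble_batch([graph])
    cache: dict = {}
    _forward(model.params, cfg, X, A, gi, sizes, cache)
    H = cache["H_last"]  # (n, hidden)
    n = H.shape[0]
    c = model.classes.index(target_class)
    wc = model.params["Wc"][:, c]  # d logit_c / d g
    if cfg.readout == "mean":
        grad = np.tile(wc / n, (n, 1))
    elif cfg.readout == "sum":
        grad = np.tile(wc, (n, 1))
    else:  # max: gradient reaches only the argmax node per channel
        grad = np.zeros_like(H)
        grad[cache["argmax"][0], np.arange(H.shape[1])] = wc
    alpha = grad.mean(axis=0)  # channel weights
    scores = np.maximum(H @ alpha, 0.0)
    top = scores.max()
    return scores / top if top > 0 else scores


# ---------------------------------------------------------------------------
# Checkpointing


def save_model(model: GNNModel, path) -> None:
    """Versioned JSON checkpoint: weights, config, feature statistics."""
    doc = {
        "format": "pannet-ips-gnn/1",
        "config": {k: getattr(model.config, k) for k in (
            "n_layers", "hidden", "readout", "dropout", "learning_rate",
            "epochs", "batch_size", "decay_rate", "seed")},
        "classes": list(model.classes),
        "params": {k: v.tolist() for k, v in model.params.items()},
        "feature_stats": (model.feature_stats.to_dict()
                          if model.feature_stats else None),
        "trained": model.trained,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> GNNModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "pannet-ips-gnn/1":
        raise ValueError("unrecognized checkpoint format")
    stats = doc.get("feature_stats")
    return GNNModel(
        config=GNNConfig(**doc["config"]),
        params={k: np.asarray(v) for k, v in doc["params"].items()},
        classes=tuple(doc["classes"]),
        feature_stats=FeatureStats.from_dict(stats) if stats else None,
        trained=bool(doc.get("trained", False)),
    )
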