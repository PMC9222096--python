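"""Edge-conditioned graph-convolutional classifier.

The model stacks three edge-conditioned convolution (ECC) layers in which a
small feed-forward "filter network" maps each edge label (dx, dy, d) to an
edge-specific weight matrix; node updates average the edge-conditioned linear
maps of the neighbors and add a bias.  A readout (zero-padded flatten or mean
pool) produces a graph representation, and a two-layer fully connected head
with a sigmoid output gives the five per-class probabilities (argmax decides
the class).  Training minimizes multi-label focal loss
``-(1 - p_t)^gamma log(p_t)`` with Adam; gamma=0 recovers plain
cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as _np
import autograd.numpy as anp

from . import _nn
from .exceptions import (
    ConfigurationError,
    DegenerateLabelError,
    ShapeError,
)
from .io import CLASS_NAMES
from .graphs import normalize_coords

EDGE_LABEL_DIM = 3


# ---------------------------------------------------------------------------
# configs


@dataclass
class GnnConfig:
    """Architecture of the graph classifier.

    ``feature_source`` selects where fixed node features come from:
    ``"patches"`` recomputes deep patch features from the jointly trained
    extractor CNN every forward pass (end-to-end mode); ``"precomputed"``
    uses the per-graph ``base_features`` matrix as-is.
    """

    feature_source: str = "patches"
    base_dim: int = 64
    emb_dim: int = 16
    use_spatial_embedding: bool = True
    ecc_dims: tuple = (32, 32, 32)
    filter_hidden: int = 32
    readout: str = "flatten"
    n_max: int = 128
    head_hidden: int = 32
    n_classes: int = 5
    class_names: tuple = CLASS_NAMES
    head_activation: str = "sigmoid"
    self_loops: bool = True  # convolution neighborhoods include the node itself
    patch_size: int = 14
    extractor_tap: int = 6
    coord_normalizer: str = "unit"

    @property
    def node_dim(self):
        return self.base_dim + (self.emb_dim if self.use_spatial_embedding else 0)

    @property
    def rep_dim(self):
        last = self.ecc_dims[-1]
        return self.n_max * last if self.readout == "flatten" else last


@dataclass
class FocalLossConfig:
    """Focusing parameter gamma (>= 0) and optional per-class weights."""

    gamma: float = 2.0
    class_weights: _np.ndarray | None = None

    def __post_init__(self):
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    lr: float = 3e-4
    lr_decay: float = 0.5
    decay_every: int = 30
    epochs: int = 100
    batch_size: int = 32
    balanced_sampling: bool = False  # per-epoch class-balanced resampling
    early_stop_patience: int | None = None  # epochs without loss improvement
    seed: int = 0


@dataclass
class ClassProbabilities:
    """Per-class sigmoid probabilities (not constrained to sum to 1)."""

    probs: _np.ndarray
    class_names: tuple = CLASS_NAMES

    @property
    def predicted(self):
        return int(_np.argmax(self.probs))

    @property
    def predicted_name(self):
        return self.class_names[self.predicted]


# ---------------------------------------------------------------------------
# parameter initialization


def init_params(config, seed):
    rng = _np.random.default_rng(seed)
    params = {}
    if config.feature_source == "patches":
        params["extractor"] = _nn.extractor_init(rng, out_dim=config.base_dim)
    if config.use_spatial_embedding:
        params["emb"] = {"w": _nn.glorot(rng, 2, config.emb_dim),
                         "b": _np.zeros(config.emb_dim)}
    params["ecc"] = []
    din = config.node_dim
    for dout in config.ecc_dims:
        h = config.filter_hidden
        # filter net starts at an identity map (b2 = vec(I)) with small
        # edge-conditioned perturbations from w2: each layer initially acts
        # as neighborhood averaging, so signal and gradients survive the
        # full stack (near-zero filters would collapse it to zero)
        params["ecc"].append({
            "w1": _nn.glorot(rng, EDGE_LABEL_DIM, h),
            "b1": _np.zeros(h),
            "w2": _nn.glorot(rng, h, dout * din) / _np.sqrt(din),
            "b2": _np.eye(dout, din).reshape(-1),
            "bias": _np.zeros(dout),
        })
        din = dout
    params["head"] = {
        "w1": _nn.glorot(rng, config.rep_dim, config.head_hidden),
        "b1": _np.zeros(config.head_hidden),
        "w2": _nn.glorot(rng, config.head_hidden, config.n_classes),
        "b2": _np.zeros(config.n_classes),
    }
    return params


# ---------------------------------------------------------------------------
# public single-graph operations


def edge_filters(layer_params, edge_labels, d_out, d_in):
    """Filter network: edge label (E, 3) -> edge-specific matrices (E, d_out, d_in)."""
    h = anp.tanh(anp.dot(edge_labels, layer_params["w1"]) + layer_params["b1"])
    theta = anp.dot(h, layer_params["w2"]) + layer_params["b2"]
    return anp.reshape(theta, (-1, d_out, d_in))


def ecc_forward(graph, layer_params, x_prev):
    """One edge-conditioned convolution on a single graph.

    Node i receives the mean over incoming edges (j -> i) of the
    edge-conditioned linear map of neighbor j's features, plus the layer
    bias.  Isolated nodes carry a (0, 0, 0)-labeled self-loop so the mean
    stays defined.  No nonlinearity is applied here.
    """
    x_prev = _np.asarray(x_prev, dtype=float)
    if x_prev.shape[0] != graph.n_nodes:
        raise ShapeError("feature rows do not match node count")
    d_out = layer_params["bias"].shape[0]
    d_in = x_prev.shape[1]
    if layer_params["w2"].shape[1] != d_out * d_in:
        raise ShapeError(
            f"layer expects input width {layer_params['w2'].shape[1] // d_out}, "
            f"got {d_in}")
    src, dst = graph.edge_index[:, 0], graph.edge_index[:, 1]
    theta = edge_filters(layer_params, graph.edge_labels, d_out, d_in)
    msg = anp.einsum("eoi,ei->eo", theta, x_prev[src])
    agg = _nn.segment_sum(msg, dst, graph.n_nodes)
    deg = _np.bincount(dst, minlength=graph.n_nodes).astype(float)
    return agg / deg[:, None] + layer_params["bias"]


def readout(node_features, mode="flatten", n_max=128, coords=None, scores=None):
    """Graph-level representation from node features.

    ``flatten``: nodes ordered by (y, x), zero-padded to ``n_max`` rows (when
    more than ``n_max`` nodes exist the highest-detector-score ones are
    kept), then flattened row-major.  ``mean``: column mean.
    """
    x = _np.asarray(node_features, dtype=float)
    if mode == "mean":
        return x.mean(axis=0)
    if mode != "flatten":
        raise ConfigurationError(f"unknown readout mode {mode!r}")
    n, d = x.shape
    idx = _np.arange(n)
    if n > n_max:
        if scores is None:
            scores = _np.zeros(n)
        keep = _np.sort(_np.argsort(-_np.asarray(scores), kind="stable")[:n_max])
        x, idx = x[keep], idx[keep]
        n = n_max
    if coords is not None:
        order = _np.lexsort((_np.asarray(coords)[idx, 0], _np.asarray(coords)[idx, 1]))
        x = x[order]
    out = _np.zeros((n_max, d))
    out[:n] = x
    return out.reshape(-1)


def classify(representation, w_fc, b_fc):
    """Final affine layer + elementwise sigmoid over the five class logits."""
    logits = _np.asarray(representation) @ w_fc + b_fc
    if not _np.all(_np.isfinite(logits)):
        raise ShapeError(f"non-finite logits: {logits}")
    return ClassProbabilities(probs=_np.asarray(_nn.sigmoid(logits)))


def focal_loss(probs, y_onehot, config=None):
    """Focal loss summed over the five sigmoid components.

    ``p_t`` is the probability assigned to the true state of each component
    (p where y=1, 1-p where y=0); each component contributes
    ``-(1 - p_t)^gamma log(p_t)``; logs are clamped for saturated outputs.
    With gamma=0 this is the summed binary cross-entropy.
    """
    config = config or FocalLossConfig()
    p = probs.probs if isinstance(probs, ClassProbabilities) else probs
    p = anp.clip(p, 1e-12, 1.0 - 1e-12)
    y = anp.asarray(y_onehot, dtype=float)
    pt = p * y + (1.0 - p) * (1.0 - y)
    terms = -((1.0 - pt) ** config.gamma) * anp.log(pt)
    if config.class_weights is not None:
        terms = terms * anp.asarray(config.class_weights)
    return anp.sum(terms, axis=-1)


# ---------------------------------------------------------------------------
# batching


def _pack(graphs, config):
    """Concatenate graphs into flat arrays for vectorized forward passes."""
    from .graphs import edge_arrays

    n_graphs = len(graphs)
    offsets = _np.cumsum([0] + [g.n_nodes for g in graphs])
    loop_mode = "all" if config.self_loops else "isolated"
    per_graph = [edge_arrays(g.coords, g.adjacency, g.image_shape,
                             self_loops=loop_mode) for g in graphs]
    src = _np.concatenate([e[:, 0] + o for (e, _), o in zip(per_graph, offsets)])
    dst = _np.concatenate([e[:, 1] + o for (e, _), o in zip(per_graph, offsets)])
    labels = _np.concatenate([l for _, l in per_graph])
    n_nodes = int(offsets[-1])
    deg = _np.bincount(dst, minlength=n_nodes).astype(float)
    pack = {
        "n_graphs": n_graphs,
        "n_nodes": n_nodes,
        "src": src,
        "dst": dst,
        "edge_labels": labels,
        "inv_deg": 1.0 / _np.maximum(deg, 1.0),
        "graph_id": _np.repeat(_np.arange(n_graphs), [g.n_nodes for g in graphs]),
        "counts": _np.array([g.n_nodes for g in graphs], dtype=float),
        "ncoords": _np.concatenate([
            normalize_coords(g.coords, g.image_shape, config.coord_normalizer)
            for g in graphs]),
    }
    if config.feature_source == "patches":
        pack["patches"] = _np.concatenate([g.patches for g in graphs])
    else:
        pack["base"] = _np.concatenate([g.base_features for g in graphs])
    if config.readout == "flatten":
        slots, keep = [], []
        for gi, (g, o) in enumerate(zip(graphs, offsets)):
            idx = _np.arange(g.n_nodes)
            if g.n_nodes > config.n_max:
                idx = _np.sort(_np.argsort(-g.detector_scores, kind="stable")[: config.n_max])
            order = _np.lexsort((g.coords[idx, 0], g.coords[idx, 1]))
            idx = idx[order]
            keep.append(idx + o)
            slots.append(gi * config.n_max + _np.arange(idx.size))
        pack["flat_keep"] = _np.concatenate(keep)
        pack["flat_slot"] = _np.concatenate(slots)
    ys = [g.label for g in graphs]
    if all(y is not None for y in ys):
        onehot = _np.zeros((n_graphs, config.n_classes))
        onehot[_np.arange(n_graphs), _np.asarray(ys, dtype=int)] = 1.0
        pack["y_onehot"] = onehot
    return pack


def _input_features(params, pack, config):
    """Fused base + spatial-embedding node features (layer-0 input)."""
    if config.feature_source == "patches":
        patches = pack["patches"]
        # per-patch standardization: the extractor should see spot shape and
        # contrast, not the local background level (cf. the verifier CNN)
        mean = anp.mean(patches, axis=(1, 2), keepdims=True)
        std = anp.std(patches, axis=(1, 2), keepdims=True)
        base = _nn.extractor_forward(params["extractor"],
                                     (patches - mean) / (std + 1e-6),
                                     tap_layer=config.extractor_tap)
    else:
        base = pack["base"]
    if config.use_spatial_embedding:
        emb = anp.dot(pack["ncoords"], params["emb"]["w"]) + params["emb"]["b"]
        return anp.concatenate([base, emb], axis=1)
    return base


def _ecc_stack(params, pack, config, x, start=0, stop=None):
    """ECC layers ``start``..``stop`` (exclusive) with ReLU after each."""
    stop = len(config.ecc_dims) if stop is None else stop
    dims = (config.node_dim,) + tuple(config.ecc_dims)
    for li in range(start, stop):
        layer, din, dout = params["ecc"][li], dims[li], dims[li + 1]
        theta = edge_filters(layer, pack["edge_labels"], dout, din)
        msg = anp.einsum("eoi,ei->eo", theta, x[pack["src"]])
        agg = _nn.segment_sum(msg, pack["dst"], pack["n_nodes"])
        x = _nn.relu(agg * pack["inv_deg"][:, None] + layer["bias"])
    return x


def _nodes_forward(params, pack, config):
    """Node features through embedding fusion and the full ECC stack."""
    return _ecc_stack(params, pack, config, _input_features(params, pack, config))


def _head_forward(params, x_nodes, pack, config):
    """Readout + two fully connected layers -> class logits (B, n_classes)."""
    d = config.ecc_dims[-1]
    if config.readout == "mean":
        rep = _nn.segment_sum(x_nodes, pack["graph_id"], pack["n_graphs"])
        rep = rep / pack["counts"][:, None]
    else:
        kept = x_nodes[pack["flat_keep"]]
        table = _nn.segment_sum(kept, pack["flat_slot"],
                                pack["n_graphs"] * config.n_max)
        rep = anp.reshape(table, (pack["n_graphs"], config.n_max * d))
    h = _nn.relu(anp.dot(rep, params["head"]["w1"]) + params["head"]["b1"])
    return anp.dot(h, params["head"]["w2"]) + params["head"]["b2"]


def _probs_from_logits(logits, config):
    if config.head_activation == "softmax":
        z = logits - anp.max(logits, axis=-1, keepdims=True)
        e = anp.exp(z)
        return e / anp.sum(e, axis=-1, keepdims=True)
    return _nn.sigmoid(logits)


def forward(params, pack, config):
    return _probs_from_logits(
        _head_forward(params, _nodes_forward(params, pack, config), pack, config),
        config)


# ---------------------------------------------------------------------------
# the trained model


@dataclass
class GnnModel:
    params: dict
    config: GnnConfig
    train_meta: dict = field(default_factory=dict)

    def predict(self, graph):
        return predict(self, graph)


def predict(model, graph):
    """Deterministic forward pass on one graph -> ClassProbabilities."""
    config = model.config
    if config.feature_source == "patches" and graph.patches is None:
        raise ShapeError("model expects raw patches but graph carries none")
    if config.feature_source == "precomputed":
        if graph.base_features is None:
            raise ShapeError("model expects precomputed base features")
        if graph.base_features.shape[1] != config.base_dim:
            raise ShapeError(
                f"graph base features of width {graph.base_features.shape[1]} do not "
                f"match model base_dim {config.base_dim} (config mismatch)")
    pack = _pack([graph], config)
    probs = forward(model.params, pack, config)
    return ClassProbabilities(probs=_np.asarray(probs[0]),
                              class_names=tuple(config.class_names))


def node_activations(model, graph, layer=None):
    """Post-ReLU node activations of ECC layer ``layer`` (1-based, default
    last; 0 selects the fused input features before any convolution) plus
    the closure mapping them to a class logit (for saliency)."""
    config = model.config
    n_layers = len(config.ecc_dims)
    layer = n_layers if layer is None else layer
    if not 0 <= layer <= n_layers:
        raise ConfigurationError(f"layer must be in 0..{n_layers}, got {layer}")
    pack = _pack([graph], config)
    x_tap = _ecc_stack(model.params, pack, config,
                       _input_features(model.params, pack, config),
                       start=0, stop=layer)

    def logit_fn(x_nodes, target_class):
        x_last = _ecc_stack(model.params, pack, config, x_nodes,
                            start=layer, stop=n_layers)
        return _head_forward(model.params, x_last, pack, config)[0, target_class]

    return _np.asarray(x_tap), logit_fn


def train(dataset, model_config=None, train_config=None, loss_config=None,
          verbose=False):
    """Fit the graph classifier by Adam on mean focal loss.

    Jointly optimizes whatever the configuration makes learnable: the patch
    feature extractor (end-to-end mode), the spatial embedding, the ECC
    filter networks and biases, and the head.  Fully deterministic for a
    fixed seed.
    """
    model_config = model_config or GnnConfig()
    train_config = train_config or TrainConfig()
    loss_config = loss_config or FocalLossConfig()
    labels = {g.label for g in dataset}
    if None in labels:
        raise DegenerateLabelError("every training graph needs a label")
    if len(labels) < 2:
        raise DegenerateLabelError(
            f"training needs >= 2 classes, got only {labels}")
    rng = _np.random.default_rng(train_config.seed)
    params = init_params(model_config, seed=train_config.seed)
    n = len(dataset)

    def loss_fn(p, pack):
        probs = forward(p, pack, model_config)
        return anp.mean(focal_loss(probs, pack["y_onehot"], loss_config))

    y_arr = _np.array([g.label for g in dataset])

    def batches(epoch):
        if train_config.balanced_sampling:
            # resample with equal class probabilities (baseline-style
            # imbalance handling, an alternative to focal loss)
            weights = 1.0 / _np.bincount(y_arr)[y_arr]
            order = rng.choice(n, size=n, replace=True, p=weights / weights.sum())
        else:
            order = rng.permutation(n)
        return [
            _pack([dataset[i] for i in order[s : s + train_config.batch_size]],
                  model_config)
            for s in range(0, n, train_config.batch_size)
        ]

    callback = (lambda e, l: print(f"epoch {e:3d}  loss {l:.4f}")) if verbose else None
    params, history = _nn.minimize_adam(
        loss_fn, params, batches,
        epochs=train_config.epochs, lr=train_config.lr,
        lr_decay=train_config.lr_decay, decay_every=train_config.decay_every,
        callback=callback, patience=train_config.early_stop_patience)
    return GnnModel(
        params=params,
        config=model_config,
        train_meta={
            "seed": train_config.seed,
            "train_config": asdict(train_config),
            "loss_config": {"gamma": loss_config.gamma},
            "loss_history": history,
            "final_loss": history[-1],
        },
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model, path):
    """Weights + full config + seed + class-name order in one .npz file."""
    flat, _ = _nn.flatten(model.params)
    meta = {
        "config": {**asdict(model.config),
                   "ecc_dims": list(model.config.ecc_dims),
                   "class_names": list(model.config.class_names)},
        "train_meta": model.train_meta,
    }
    _np.savez(path, flat=flat,
              meta=_np.frombuffer(json.dumps(meta).encode(), dtype=_np.uint8))
    return path


def load_model(path):
    with _np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        cfg = meta["config"]
        cfg["ecc_dims"] = tuple(cfg["ecc_dims"])
        cfg["class_names"] = tuple(cfg["class_names"])
        config = GnnConfig(**cfg)
        template = init_params(config, seed=0)
        _, unflatten = _nn.flatten(template)
        return GnnModel(params=unflatten(data["flat"]), config=config,
                        train_meta=meta["train_meta"])
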