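"""Calcification-graph construction.

Each mammogram with verified calcification candidates becomes one graph:
nodes are candidates, node features are deep patch features concatenated
with a learnable spatial embedding of the (normalized) center coordinates,
and edges connect spatial k-nearest neighbors (Euclidean distance,
symmetrized).  Each directed edge carries the label
``(dx, dy, d)`` — source-minus-destination coordinate offsets and their
Euclidean length, all normalized by the image diagonal — conditioning the
edge-specific filters of the graph convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as _np
from scipy.spatial.distance import cdist

from . import _nn
from .exceptions import NoCalcificationsError, ShapeError

DEFAULT_PATCH_DIM = 64
DEFAULT_EMB_DIM = 16  # 64 + 16 = 80-dim node features by default


# ---------------------------------------------------------------------------
# adjacency and edge labels


def knn_adjacency(coords, k):
    """Symmetrized k-nearest-neighbor adjacency over Euclidean distance.

    ``A[i, j] = 1`` iff j is among the k nearest neighbors of i (self
    excluded), then ``A <- max(A, A.T)``.  Distance ties break toward the
    lower node index.  If fewer than k other nodes exist, all pairs connect.
    """
    coords = _np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n == 0:
        raise ShapeError("need at least one node")
    a = _np.zeros((n, n), dtype=_np.uint8)
    if n == 1:
        return a
    if n - 1 <= k:
        a = _np.ones((n, n), dtype=_np.uint8)
        _np.fill_diagonal(a, 0)
        return a
    d = cdist(coords, coords)
    for i in range(n):
        order = _np.lexsort((_np.arange(n), d[i]))
        order = order[order != i][:k]
        a[i, order] = 1
    a = _np.maximum(a, a.T)
    _np.fill_diagonal(a, 0)
    return a


def compute_edge_labels(coords, adjacency, image_shape):
    """Map each directed edge (j -> i) to its label (dx, dy, d).

    Offsets are source minus destination, ``(x_j - x_i, y_j - y_i)``,
    normalized by the image diagonal; ``d`` is the normalized Euclidean
    distance, identical for both directions.
    """
    coords = _np.asarray(coords, dtype=float)
    h, w = image_shape
    diag = float(_np.hypot(h, w))
    labels = {}
    src, dst = _np.nonzero(_np.asarray(adjacency))
    for j, i in zip(src.tolist(), dst.tolist()):
        delta = (coords[j] - coords[i]) / diag
        labels[(j, i)] = _np.array([delta[0], delta[1], _np.hypot(*delta)])
    return labels


def edge_arrays(coords, adjacency, image_shape, self_loops="isolated"):
    """Dense edge representation: (E, 2) int array of (src, dst) + (E, 3) labels.

    For each undirected adjacency entry both directions are emitted.
    ``self_loops="isolated"`` adds a (0, 0, 0)-labeled self-loop only to
    nodes with no neighbors (single-node graphs), keeping the mean
    aggregation of the graph convolution defined; ``"all"`` adds one to
    every node so each convolution retains the node's own features alongside
    its neighborhood (the convention of the model's stacked layers).
    """
    adjacency = _np.asarray(adjacency)
    n = adjacency.shape[0]
    src, dst = _np.nonzero(adjacency)
    if self_loops == "all":
        loops = _np.arange(n)
        src = _np.concatenate([src, loops])
        dst = _np.concatenate([dst, loops])
    elif self_loops == "isolated":
        deg = adjacency.sum(axis=0)
        isolated = _np.nonzero(deg == 0)[0]
        src = _np.concatenate([src, isolated])
        dst = _np.concatenate([dst, isolated])
    order = _np.lexsort((src, dst))  # group edges by destination
    src, dst = src[order], dst[order]
    coords = _np.asarray(coords, dtype=float)
    diag = float(_np.hypot(*image_shape))
    delta = (coords[src] - coords[dst]) / diag
    labels = _np.column_stack([delta, _np.hypot(delta[:, 0], delta[:, 1])])
    return _np.column_stack([src, dst]).astype(int), labels


# ---------------------------------------------------------------------------
# node features


@dataclass
class FeatureExtractor:
    """Six-layer residual CNN supplying deep patch features (eval mode)."""

    params: dict
    tap_layer: int = 6
    out_dim: int = DEFAULT_PATCH_DIM
    patch_size: int = 14

    @classmethod
    def initialize(cls, seed=0, out_dim=DEFAULT_PATCH_DIM, tap_layer=6):
        rng = _np.random.default_rng(seed)
        return cls(params=_nn.extractor_init(rng, out_dim=out_dim),
                   tap_layer=tap_layer, out_dim=out_dim)


def extract_patch_features(patches, extractor):
    """Row i = pooled feature maps of patch i at the extractor's tap layer."""
    patches = _np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    if patches.shape[1] != extractor.patch_size or patches.shape[2] != extractor.patch_size:
        raise ShapeError(
            f"patches {patches.shape[1:]} do not match extractor input "
            f"{(extractor.patch_size, extractor.patch_size)}")
    return _np.asarray(
        _nn.extractor_forward(extractor.params, patches, tap_layer=extractor.tap_layer))


@dataclass
class SpatialEmbedder:
    """Learnable affine embedding of node coordinates.

    Coordinates are first normalized to [0, 1] by image width/height
    (``normalizer="unit"``) unless raw-pixel mode is selected, then mapped by
    ``s W_emb + b_emb``.
    """

    w_emb: _np.ndarray  # (2, D_emb)
    b_emb: _np.ndarray  # (D_emb,)
    normalizer: str = "unit"

    @classmethod
    def initialize(cls, seed=0, emb_dim=DEFAULT_EMB_DIM, normalizer="unit"):
        rng = _np.random.default_rng(seed)
        return cls(w_emb=_nn.glorot(rng, 2, emb_dim), b_emb=_np.zeros(emb_dim),
                   normalizer=normalizer)


def normalize_coords(coords, image_shape, normalizer="unit"):
    coords = _np.asarray(coords, dtype=float)
    if normalizer == "none":
        return coords
    h, w = image_shape
    return coords / _np.array([w, h], dtype=float)


def embed_coordinates(coords, embedder, image_shape):
    """Affine spatial embedding of (normalized) node coordinates."""
    s = normalize_coords(coords, image_shape, embedder.normalizer)
    return s @ embedder.w_emb + embedder.b_emb


def fuse_node_features(patch_features, spatial_embeddings):
    """Row-wise concatenation, patch block first."""
    patch_features = _np.asarray(patch_features)
    spatial_embeddings = _np.asarray(spatial_embeddings)
    if patch_features.shape[0] != spatial_embeddings.shape[0]:
        raise ShapeError(
            f"row counts differ: {patch_features.shape[0]} patch rows vs "
            f"{spatial_embeddings.shape[0]} embedding rows")
    return _np.concatenate([patch_features, spatial_embeddings], axis=1)


# ---------------------------------------------------------------------------
# the graph container


@dataclass
class CalcificationGraph:
    """One mammogram's calcifications as a graph.

    ``base_features`` are the fixed per-node features (deep patch features,
    or geometric features for coordinate-only datasets); when training end to
    end, raw ``patches`` are carried instead and features are recomputed from
    the current extractor weights.  ``node_features`` caches the fused
    (base + spatial-embedding) matrix when it has been materialized.
    """

    coords: _np.ndarray  # (N, 2) pixel (x, y)
    adjacency: _np.ndarray  # (N, N) uint8, symmetric, zero diagonal
    image_shape: tuple  # (H, W)
    base_features: _np.ndarray | None = None
    patches: _np.ndarray | None = None
    node_features: _np.ndarray | None = None
    detector_scores: _np.ndarray | None = None
    label: int | None = None
    provenance: dict = field(default_factory=dict)
    edge_index: _np.ndarray = field(init=False)
    edge_labels: _np.ndarray = field(init=False)

    def __post_init__(self):
        self.coords = _np.asarray(self.coords, dtype=float)
        self.adjacency = _np.asarray(self.adjacency, dtype=_np.uint8)
        n = self.coords.shape[0]
        if n == 0:
            raise NoCalcificationsError(
                f"graph for image {self.provenance.get('image_id', '?')!r} has no nodes")
        if self.adjacency.shape != (n, n):
            raise ShapeError("adjacency shape does not match node count")
        if _np.any(_np.diag(self.adjacency)):
            raise ShapeError("adjacency has nonzero diagonal")
        if not _np.array_equal(self.adjacency, self.adjacency.T):
            raise ShapeError("adjacency must be symmetric")
        self.edge_index, self.edge_labels = edge_arrays(
            self.coords, self.adjacency, self.image_shape)
        if self.detector_scores is None:
            self.detector_scores = _np.zeros(n)

    @property
    def n_nodes(self):
        return self.coords.shape[0]


def build_graph(candidates, image_shape, extractor=None, embedder=None, k=8,
                label=None, image_id="", keep_patches=True):
    """Assemble a CalcificationGraph from verified candidates.

    With an ``extractor`` and ``embedder`` the fused node-feature matrix is
    materialized immediately (frozen-feature mode); otherwise raw patches are
    carried for end-to-end training.
    """
    if not candidates:
        raise NoCalcificationsError(
            f"image {image_id!r} has no calcification candidates; "
            "it cannot be represented as a graph")
    coords = _np.array([c.center for c in candidates], dtype=float)
    adjacency = knn_adjacency(coords, k)
    patches = _np.stack([_np.asarray(c.patch, dtype=float) for c in candidates])
    scores = _np.array([c.detector_score for c in candidates])
    graph = CalcificationGraph(
        coords=coords,
        adjacency=adjacency,
        image_shape=tuple(image_shape),
        patches=patches if keep_patches else None,
        detector_scores=scores,
        label=label,
        provenance={"image_id": image_id, "k": k,
                    "candidate_order": list(range(len(candidates)))},
    )
    if extractor is not None:
        graph.base_features = extract_patch_features(patches, extractor)
        if embedder is not None:
            graph.node_features = fuse_node_features(
                graph.base_features, embed_coordinates(coords, embedder, image_shape))
    return graph


def save_graph(graph, path):
    """Serialize a graph to an .npz container (exact round trip)."""
    meta = {
        "image_shape": list(graph.image_shape),
        "label": None if graph.label is None else int(graph.label),
        "provenance": graph.provenance,
    }
    arrays = {
        "coords": graph.coords,
        "adjacency": graph.adjacency,
        "detector_scores": graph.detector_scores,
        "meta": _np.frombuffer(json.dumps(meta).encode(), dtype=_np.uint8),
    }
    for name in ("base_features", "patches", "node_features"):
        value = getattr(graph, name)
        if value is not None:
            arrays[name] = value
    _np.savez(path, **arrays)
    return path


def load_graph(path):
    with _np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        return CalcificationGraph(
            coords=data["coords"],
            adjacency=data["adjacency"],
            image_shape=tuple(meta["image_shape"]),
            base_features=data["base_features"] if "base_features" in data else None,
            patches=data["patches"] if "patches" in data else None,
            node_features=data["node_features"] if "node_features" in data else None,
            detector_scores=data["detector_scores"],
            label=meta["label"],
            provenance=meta["provenance"],
        )
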