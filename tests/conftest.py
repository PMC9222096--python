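import numpy as np
import pytest

from calcgraph.detection import DetectionConfig
from calcgraph.synthetic import PatternSpec, generate_phantom


@pytest.fixture(scope="session")
def grouped_phantom():
    """One deterministic grouped-pattern phantom with ground truth."""
    spec = PatternSpec(label="grouped", seed=7)
    image, mask, spots, extras = generate_phantom(spec)
    return image, mask, spots, extras


@pytest.fixture(scope="session")
def default_config():
    return DetectionConfig()


@pytest.fixture(scope="session")
def trained_verifier():
    """Verifier CNN trained once on phantom-derived labeled patches."""
    from calcgraph.detection import VerifierTrainConfig, train_verifier
    from calcgraph.synthetic import verifier_training_patches

    patches, labels = verifier_training_patches(500, n_phantoms=6)
    return train_verifier(patches, labels,
                          VerifierTrainConfig(epochs=25, lr=2e-3, seed=0))


def brute_force_opening(image, footprint):
    """Literal erosion-then-dilation with explicit loops (oracle)."""
    h, w = image.shape
    fh, fw = footprint.shape
    cy, cx = fh // 2, fw // 2
    offs = [(i - cy, j - cx) for i in range(fh) for j in range(fw)
            if footprint[i, j]]
    eroded = np.empty_like(image, dtype=float)
    big = np.inf
    for y in range(h):
        for x in range(w):
            vals = [image[y + dy, x + dx] if 0 <= y + dy < h and 0 <= x + dx < w
                    else big for dy, dx in offs]
            eroded[y, x] = min(vals)
    dilated = np.empty_like(image, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = [eroded[y + dy, x + dx]
                    for dy, dx in offs
                    if 0 <= y + dy < h and 0 <= x + dx < w]
            dilated[y, x] = max(vals)
    return dilated


def brute_force_knn(coords, k):
    """O(N^2) sort-based kNN adjacency oracle with index tie-breaks."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    a = np.zeros((n, n), dtype=np.uint8)
    if n == 1:
        return a
    if n - 1 <= k:
        a[:] = 1
        np.fill_diagonal(a, 0)
        return a
    for i in range(n):
        dists = [(np.hypot(*(coords[j] - coords[i])), j)
                 for j in range(n) if j != i]
        dists.sort()
        for _, j in dists[:k]:
            a[i, j] = 1
    a = np.maximum(a, a.T)
    return a


def literal_ecc_forward(coords, adjacency, image_shape, layer, x_prev):
    """Per-node loop implementing the edge-conditioned convolution update
    X_l(i) = (1/|N(i)|) sum_{j in N(i)} F(L_{j,i}) X_{l-1}(j) + b."""
    n = coords.shape[0]
    diag = np.hypot(*image_shape)
    d_out = layer["bias"].shape[0]
    out = np.zeros((n, d_out))
    for i in range(n):
        neigh = [j for j in range(n) if adjacency[j, i]]
        if not neigh:
            neigh = [i]
        acc = np.zeros(d_out)
        for j in neigh:
            delta = (coords[j] - coords[i]) / diag
            lab = np.array([delta[0], delta[1], np.hypot(*delta)])
            h = np.tanh(lab @ layer["w1"] + layer["b1"])
            theta = (h @ layer["w2"] + layer["b2"]).reshape(d_out, -1)
            acc += theta @ x_prev[j]
        out[i] = acc / len(neigh) + layer["bias"]
    return out
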