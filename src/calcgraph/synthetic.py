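"""Synthetic mammographic phantoms with known calcification ground truth.

The generator emulates the kind of data the classifier is meant for: a
breast-shaped bright region (half-ellipse against a dark background) with
smooth parenchyma-like texture, pixel noise, and small Gaussian bright spots
(2-8 px across, standing in for 0.1-1 mm microcalcifications) arranged
according to one of the five BI-RADS distribution descriptors:

- ``diffuse``    — spots scattered uniformly over the whole breast;
- ``regional``   — spots in a large disc (not conforming to a duct system);
- ``grouped``    — spots in a small cluster;
- ``linear``     — spots along a narrow randomly oriented band;
- ``segmental``  — spots in a wedge with its apex at the nipple point.

Geometric scales are modeled on the BI-RADS descriptor definitions (grouped
= small volume, regional = large volume, segmental = duct-system wedge); the
exact pixel values are configurable.  Every artifact is a pure function of
its spec (including the seed), so datasets replay bit-identically from their
manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as _np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError
from .graphs import CalcificationGraph, knn_adjacency
from .io import CLASS_NAMES, BreastMask, MammogramImage

#: class proportions of the clinical cohort the generator emulates
PAPER_MIX = {
    "diffuse": 0.060,
    "regional": 0.277,
    "grouped": 0.501,
    "linear": 0.020,
    "segmental": 0.142,
}

BALANCED_MIX = {name: 0.2 for name in CLASS_NAMES}

DEFAULT_IMAGE_SHAPE = (256, 192)  # (H, W)

#: per-class spot-count ranges (inclusive)
N_SPOTS = {
    "diffuse": (40, 100),
    "regional": (25, 60),
    "grouped": (6, 14),
    "linear": (6, 15),
    "segmental": (20, 50),
}

#: geometry scales as fractions of the breast's minor semi-axis
GEOMETRY = {
    "grouped": {"radius_frac": (0.10, 0.16)},
    "regional": {"radius_frac": (0.32, 0.45)},
    "linear": {"length_frac": (0.40, 0.65), "width_px": 1.2},
    "segmental": {"half_angle_deg": (8.0, 16.0), "length_frac": (0.55, 0.80)},
    "diffuse": {},
}

GEOMETRIC_FEATURE_DIM = 8


@dataclass
class PatternSpec:
    """Everything needed to generate one phantom deterministically."""

    label: str
    seed: int
    image_shape: tuple = DEFAULT_IMAGE_SHAPE
    n_spots: tuple | None = None  # class default when None
    spot_sigma_range: tuple = (0.7, 1.8)  # Gaussian sigma in px (~3-7 px across)
    spot_amplitude: float = 0.10
    noise_sigma: float = 0.02
    texture_amplitude: float = 0.08
    texture_scale: float = 12.0
    min_separation: float = 5.0
    n_speckles: int = 0  # single-pixel film-noise impulses (verifier negatives)
    n_decoys: int = 0  # extra diffusely scattered spots outside the pattern
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in CLASS_NAMES:
            raise ConfigurationError(f"unknown pattern label {self.label!r}")
        if self.n_spots is None:
            self.n_spots = N_SPOTS[self.label]

    def geometry_params(self):
        return {**GEOMETRY[self.label], **self.geometry}


# ---------------------------------------------------------------------------
# breast geometry


def breast_geometry(image_shape):
    """Half-ellipse breast model: chest wall at x=0, bulge toward +x."""
    h, w = image_shape
    a = 0.78 * w  # semi-axis along x
    b = 0.42 * h  # semi-axis along y
    cy = h / 2.0
    return a, b, cy


def breast_mask(image_shape):
    h, w = image_shape
    a, b, cy = breast_geometry(image_shape)
    ys, xs = _np.mgrid[0:h, 0:w]
    return (xs / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0


def _interior_mask(image_shape, margin=6):
    m = breast_mask(image_shape)
    if margin > 0:
        m = ndimage.binary_erosion(m, iterations=margin)
    return m


def _sample_in_mask(rng, mask, n, min_sep=0.0, center=None, radius=None,
                    max_tries=200):
    """Rejection-sample n points inside ``mask`` (optionally inside a disc),
    keeping pairwise separation >= min_sep on a best-effort basis."""
    ys, xs = _np.nonzero(mask)
    points = []
    for _ in range(n):
        best, best_sep = None, -1.0
        for _ in range(max_tries):
            if center is not None:
                ang = rng.uniform(0, 2 * _np.pi)
                r = radius * _np.sqrt(rng.uniform())
                p = _np.array([center[0] + r * _np.cos(ang),
                               center[1] + r * _np.sin(ang)])
                iy, ix = int(_np.rint(p[1])), int(_np.rint(p[0]))
                if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]
                        and mask[iy, ix]):
                    continue
            else:
                i = rng.integers(ys.size)
                p = _np.array([xs[i] + rng.uniform(-0.5, 0.5),
                               ys[i] + rng.uniform(-0.5, 0.5)])
            sep = (min(_np.hypot(*(p - q)) for q in points)
                   if points else _np.inf)
            if sep > best_sep:
                best, best_sep = p, sep
            if sep >= min_sep:
                break
        if best is not None:
            points.append(best)
    return _np.array(points)


def sample_pattern_coords(label, rng, image_shape=DEFAULT_IMAGE_SHAPE,
                          n_spots=None, geometry=None, min_sep=5.0):
    """Sample spot centers for one descriptor; returns (n, 2) float (x, y)."""
    geometry = {**GEOMETRY[label], **(geometry or {})}
    lo, hi = n_spots if n_spots is not None else N_SPOTS[label]
    n = int(rng.integers(lo, hi + 1))
    a, b, cy = breast_geometry(image_shape)
    r_breast = min(a, b)
    interior = _interior_mask(image_shape)

    if label == "diffuse":
        return _sample_in_mask(rng, interior, n, min_sep=min_sep)

    if label in ("grouped", "regional"):
        rlo, rhi = geometry["radius_frac"]
        radius = rng.uniform(rlo, rhi) * r_breast
        core = _interior_mask(image_shape, margin=int(min(radius, 30)) + 6)
        ys, xs = _np.nonzero(core if core.any() else interior)
        i = rng.integers(ys.size)
        center = (float(xs[i]), float(ys[i]))
        return _sample_in_mask(rng, interior, n, min_sep=min_sep,
                               center=center, radius=radius)

    if label == "linear":
        llo, lhi = geometry["length_frac"]
        length = rng.uniform(llo, lhi) * r_breast
        width = geometry["width_px"]
        ys, xs = _np.nonzero(_interior_mask(image_shape, margin=12))
        for _ in range(200):
            i = rng.integers(ys.size)
            c = _np.array([xs[i], ys[i]], dtype=float)
            theta = rng.uniform(0, _np.pi)
            u = _np.array([_np.cos(theta), _np.sin(theta)])
            ends = [c - 0.5 * length * u, c + 0.5 * length * u]
            ok = all(
                0 <= int(_np.rint(e[1])) < image_shape[0]
                and 0 <= int(_np.rint(e[0])) < image_shape[1]
                and interior[int(_np.rint(e[1])), int(_np.rint(e[0]))]
                for e in ends)
            if ok:
                break
        ts = _np.sort(rng.uniform(-0.5, 0.5, size=n)) * length
        # enforce spacing along the line so spots stay resolvable
        for j in range(1, n):
            ts[j] = max(ts[j], ts[j - 1] + min_sep * 0.8)
        ts -= ts.mean()
        offsets = rng.normal(0, width, size=n)
        normal = _np.array([-u[1], u[0]])
        return c + ts[:, None] * u + offsets[:, None] * normal

    # segmental: wedge with apex at the nipple point opening toward the chest
    alo, ahi = geometry["half_angle_deg"]
    half_angle = _np.deg2rad(rng.uniform(alo, ahi))
    length = rng.uniform(*geometry["length_frac"]) * a
    apex = _np.array([a - 2.0, cy])
    pts = []
    tries = 0
    while len(pts) < n and tries < 200 * n:
        tries += 1
        r = length * _np.sqrt(rng.uniform(0.05, 1.0))
        phi = _np.pi + rng.uniform(-half_angle, half_angle)
        p = apex + r * _np.array([_np.cos(phi), _np.sin(phi)])
        iy, ix = int(_np.rint(p[1])), int(_np.rint(p[0]))
        if not (0 <= iy < image_shape[0] and 0 <= ix < image_shape[1]
                and interior[iy, ix]):
            continue
        if pts and min(_np.hypot(*(p - q)) for q in pts) < min_sep * 0.8:
            continue
        pts.append(p)
    return _np.array(pts) if pts else apex[None] - _np.array([10.0, 0.0])


# ---------------------------------------------------------------------------
# phantom rendering


def _stamp_spot(img, x, y, sigma, amplitude):
    half = int(_np.ceil(4 * sigma)) + 1
    ix, iy = int(_np.rint(x)), int(_np.rint(y))
    y0, y1 = max(0, iy - half), min(img.shape[0], iy + half + 1)
    x0, x1 = max(0, ix - half), min(img.shape[1], ix + half + 1)
    yy, xx = _np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * _np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


def generate_phantom(spec):
    """Render one phantom.

    Returns ``(image, mask, spots, extras)`` where ``spots`` is the list of
    planted pattern calcifications as dicts with exact centers, and
    ``extras`` holds optional decoy spots and film-noise speckles with their
    own ground truth.
    """
    rng = _np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    mask = breast_mask(spec.image_shape)

    img = _np.full((h, w), 0.03)
    tissue = _np.full((h, w), 0.32)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                      spec.texture_scale)
    std = texture[mask].std()
    if std > 0:
        texture *= spec.texture_amplitude / std
    img += mask * (tissue + texture)

    coords = sample_pattern_coords(
        spec.label, rng, spec.image_shape, n_spots=spec.n_spots,
        geometry=spec.geometry, min_sep=spec.min_separation)
    if spec.n_spots == (0, 0):
        coords = _np.empty((0, 2))
    spots = []
    for x, y in coords:
        sigma = rng.uniform(*spec.spot_sigma_range)
        _stamp_spot(img, x, y, sigma, spec.spot_amplitude)
        spots.append({"x": float(x), "y": float(y), "sigma": float(sigma),
                      "amplitude": spec.spot_amplitude})

    extras = {"decoys": [], "speckles": []}
    if spec.n_decoys:
        interior = _interior_mask(spec.image_shape)
        decoy_pts = _sample_in_mask(rng, interior, spec.n_decoys,
                                    min_sep=spec.min_separation)
        for x, y in decoy_pts:
            sigma = rng.uniform(*spec.spot_sigma_range)
            _stamp_spot(img, x, y, sigma, spec.spot_amplitude)
            extras["decoys"].append({"x": float(x), "y": float(y),
                                     "sigma": float(sigma)})
    if spec.n_speckles:
        interior = _interior_mask(spec.image_shape)
        ys, xs = _np.nonzero(interior)
        idx = rng.choice(ys.size, size=spec.n_speckles, replace=False)
        for i in idx:
            img[ys[i], xs[i]] += spec.spot_amplitude * rng.uniform(1.0, 1.6)
            extras["speckles"].append({"x": int(xs[i]), "y": int(ys[i])})

    img += rng.normal(0, spec.noise_sigma, size=(h, w))
    img = _np.clip(img, 0.0, 1.0)
    image = MammogramImage(pixels=img, source_id=f"phantom-{spec.label}-{spec.seed}")
    return image, BreastMask(mask=mask), spots, extras


# ---------------------------------------------------------------------------
# datasets


def largest_remainder_counts(proportions, n):
    """Integer class counts summing to n, by largest-remainder rounding."""
    names = list(proportions)
    raw = _np.array([proportions[c] for c in names], dtype=float)
    if not _np.isclose(raw.sum(), 1.0):
        raise ConfigurationError(f"proportions sum to {raw.sum():.4f}, not 1")
    exact = raw * n
    counts = _np.floor(exact).astype(int)
    rem = exact - counts
    for i in _np.argsort(-rem, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(names, counts.tolist()))


@dataclass
class SyntheticDataset:
    """Phantom images with complete ground truth and a replayable manifest."""

    images: list
    masks: list
    spots: list  # per-image list of planted spot dicts
    extras: list
    labels: list  # integer class indices into CLASS_NAMES
    manifest: dict

    def __len__(self):
        return len(self.images)


def _resolve_mix(class_mix):
    if class_mix == "paper":
        return PAPER_MIX
    if class_mix == "balanced":
        return BALANCED_MIX
    return class_mix


def generate_dataset(class_mix, n_images, seed, **spec_overrides):
    """Stratified phantom dataset; ``class_mix`` is a name->proportion dict or
    one of the presets ``"paper"`` / ``"balanced"``."""
    mix = _resolve_mix(class_mix)
    counts = largest_remainder_counts(mix, n_images)
    rng = _np.random.default_rng(seed)
    specs = []
    for label in CLASS_NAMES:
        for _ in range(counts.get(label, 0)):
            specs.append(PatternSpec(
                label=label, seed=int(rng.integers(0, 2**31 - 1)),
                **spec_overrides))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    manifest = {"seed": seed, "n_images": n_images, "class_mix": dict(mix),
                "specs": [_spec_dict(s) for s in specs]}
    return generate_from_manifest(manifest)


def _spec_dict(spec):
    d = asdict(spec)
    d["image_shape"] = list(d["image_shape"])
    d["n_spots"] = list(d["n_spots"])
    d["spot_sigma_range"] = list(d["spot_sigma_range"])
    return d


def generate_from_manifest(manifest):
    """Replay a dataset bit-identically from its manifest."""
    images, masks, spots, extras, labels = [], [], [], [], []
    for sd in manifest["specs"]:
        sd = dict(sd)
        for key in ("image_shape", "n_spots", "spot_sigma_range"):
            sd[key] = tuple(sd[key])
        spec = PatternSpec(**sd)
        img, mask, sp, ex = generate_phantom(spec)
        images.append(img)
        masks.append(mask)
        spots.append(sp)
        extras.append(ex)
        labels.append(CLASS_NAMES.index(spec.label))
    return SyntheticDataset(images=images, masks=masks, spots=spots,
                            extras=extras, labels=labels, manifest=manifest)


def benchmark_model_config():
    """Classifier architecture for the coordinate-graph benchmark.

    Geometric node features (8) + spatial embedding (16) through three
    16-wide ECC layers, mean-pool readout, 32-wide head.
    """
    from .gnn import GnnConfig

    return GnnConfig(feature_source="precomputed",
                     base_dim=GEOMETRIC_FEATURE_DIM, emb_dim=16,
                     ecc_dims=(16, 16, 16), filter_hidden=32,
                     readout="mean", head_hidden=32)


def benchmark_train_config(seed=0):
    """Training settings for the benchmark: Adam, 25 epochs, lr 5e-3 halved
    every 10 epochs, batches of 32."""
    from .gnn import TrainConfig

    return TrainConfig(lr=5e-3, epochs=25, batch_size=32, decay_every=10,
                       seed=seed)


def pattern_decoy_graph(label, seed, n_decoys=10, k=8,
                        image_shape=DEFAULT_IMAGE_SHAPE, n_spots=None):
    """A pattern graph plus scattered decoy nodes.

    Decoys emulate isolated benign calcifications elsewhere in the breast;
    they occur in every class so sparseness itself carries no class signal.
    Returns ``(graph, in_pattern)`` where ``in_pattern`` flags the nodes of
    the planted pattern.
    """
    rng = _np.random.default_rng(seed)
    pattern = sample_pattern_coords(label, rng, image_shape, n_spots=n_spots)
    interior = _interior_mask(image_shape)
    decoys = _sample_in_mask(rng, interior, n_decoys, min_sep=8.0)
    coords = _np.vstack([pattern, decoys]) if n_decoys else pattern
    in_pattern = _np.zeros(coords.shape[0], dtype=bool)
    in_pattern[: pattern.shape[0]] = True
    graph = CalcificationGraph(
        coords=coords,
        adjacency=knn_adjacency(coords, k),
        image_shape=image_shape,
        base_features=geometric_node_features(coords, image_shape),
        label=CLASS_NAMES.index(label),
        provenance={"image_id": f"synthetic-{label}-decoys-{seed}",
                    "seed": seed, "n_decoys": n_decoys},
    )
    return graph, in_pattern


def grouped_decoy_graph(seed, n_decoys=10, k=8, image_shape=DEFAULT_IMAGE_SHAPE):
    """Grouped cluster plus scattered decoys; see ``pattern_decoy_graph``."""
    return pattern_decoy_graph("grouped", seed, n_decoys=n_decoys, k=k,
                               image_shape=image_shape)


def saliency_study_data(seed, n_per_class=60, n_eval=25, n_decoys=10, k=8):
    """Training + evaluation graphs for the saliency localization study.

    A two-class controlled design: grouped-with-decoy graphs versus diffuse
    graphs drawn with the *same total node count*.  Matching the node count
    removes graph size as a cue, and the scattered decoys match the diffuse
    class's geometry node-for-node, so the planted cluster is the only
    evidence distinguishing the classes — a model that solves the task must
    rely on the cluster, which is exactly what node saliency should then
    highlight.  Evaluation graphs are fresh grouped-with-decoy graphs with
    their cluster masks.
    """
    rng = _np.random.default_rng(seed)
    lo, hi = N_SPOTS["grouped"]
    matched_n = (lo + n_decoys, hi + n_decoys)
    train = []
    for _ in range(n_per_class):
        graph, _ = pattern_decoy_graph("grouped", int(rng.integers(0, 2**31 - 1)),
                                       n_decoys=n_decoys, k=k)
        train.append(graph)
        graph, _ = pattern_decoy_graph("diffuse", int(rng.integers(0, 2**31 - 1)),
                                       n_decoys=0, k=k, n_spots=matched_n)
        train.append(graph)
    evals = [grouped_decoy_graph(int(rng.integers(0, 2**31 - 1)),
                                 n_decoys=n_decoys, k=k)
             for _ in range(n_eval)]
    return train, evals


def verifier_training_patches(seed, n_phantoms=10, config=None, match_tol=3.0):
    """Labeled patch set for the detection verifier.

    Runs the morphological detector on ``n_phantoms`` phantoms (one per
    class, cycling) and labels each candidate patch positive iff its center
    lies within ``match_tol`` px of a planted spot — i.e. positives are
    detector hits on true calcifications and negatives are the detector's
    own false alarms (hard negatives).
    """
    from .detection import DetectionConfig, detect_calcifications

    config = config or DetectionConfig()
    patches, labels = [], []
    for i in range(n_phantoms):
        label = CLASS_NAMES[i % len(CLASS_NAMES)]
        spec = PatternSpec(label=label, seed=seed + i)
        image, mask, spots, _ = generate_phantom(spec)
        gt = _np.array([[s["x"], s["y"]] for s in spots]).reshape(-1, 2)
        for cand in detect_calcifications(image, mask, config):
            d = (_np.linalg.norm(gt - _np.array(cand.center), axis=1).min()
                 if gt.size else _np.inf)
            patches.append(cand.patch)
            labels.append(1.0 if d <= match_tol else 0.0)
    return _np.stack(patches), _np.array(labels)


# ---------------------------------------------------------------------------
# coordinate-graph datasets (skip the imaging stages)


def geometric_node_features(coords, image_shape=DEFAULT_IMAGE_SHAPE):
    """Coordinate-derived node features (8 per node).

    Per node: local density responses ``exp(-d_k / s)`` for the distance to
    the 1st/3rd/8th nearest neighbor (s = 5% of the image diagonal), a
    centroid-proximity response, and a density-profile "gap" response
    ``1 - exp(-(d12/d4 - 1) / 3)`` that fires for nodes inside a tight
    group that is isolated from the rest of the point set (the node-level
    analogue of comparing a two-radius Ripley statistic); per graph
    (replicated): RMS spread about the centroid, planar anisotropy
    ``1 - sqrt(l2/l1)`` of the coordinate covariance, and scaled
    ``log1p(N)``.  Density-style (rather than raw distance) encoding makes
    nodes inside tight structures produce strong activations, which both
    the classifier and gradient-based saliency rely on.
    """
    coords = _np.asarray(coords, dtype=float)
    n = coords.shape[0]
    diag = float(_np.hypot(*image_shape))
    s_local = 0.05 * diag
    s_global = 0.15 * diag
    feats = _np.zeros((n, GEOMETRIC_FEATURE_DIM))
    centroid = coords.mean(axis=0)
    dcent = _np.hypot(*(coords - centroid).T)
    if n > 1:
        d = cdist(coords, coords)
        dsort = _np.sort(d, axis=1)[:, 1:]  # drop self
        for col, kth in enumerate((1, 3, 8)):
            feats[:, col] = _np.exp(-dsort[:, min(kth, n - 1) - 1] / s_local)
        d4 = dsort[:, min(4, n - 1) - 1]
        d12 = dsort[:, min(12, n - 1) - 1]
        gap = d12 / _np.maximum(d4, 1e-9)
        feats[:, 4] = 1.0 - _np.exp(-_np.maximum(gap - 1.0, 0.0) / 3.0)
        cov = _np.cov(coords.T)
        evals = _np.sort(_np.linalg.eigvalsh(cov))
        if evals[1] > 0:
            feats[:, 6] = 1.0 - _np.sqrt(max(evals[0], 0.0) / evals[1])
    feats[:, 3] = _np.exp(-dcent / s_global)
    feats[:, 5] = _np.sqrt(_np.mean(dcent**2)) / diag
    feats[:, 7] = _np.log1p(n) / _np.log(301.0)
    return feats


def generate_graph_dataset(class_mix, n_graphs, feature_mode="geometric",
                           seed=0, k=8, image_shape=DEFAULT_IMAGE_SHAPE):
    """Labeled calcification graphs sampled directly from pattern geometry.

    ``feature_mode="geometric"`` attaches coordinate-derived node features;
    ``"random"`` attaches seeded Gaussian noise (a null dataset carrying no
    class signal in the features).
    """
    if feature_mode not in ("geometric", "random"):
        raise ConfigurationError(f"unknown feature_mode {feature_mode!r}")
    mix = _resolve_mix(class_mix)
    counts = largest_remainder_counts(mix, n_graphs)
    rng = _np.random.default_rng(seed)
    entries = []
    for label in CLASS_NAMES:
        for _ in range(counts.get(label, 0)):
            entries.append((label, int(rng.integers(0, 2**31 - 1))))
    order = rng.permutation(len(entries))
    graphs = []
    for i in order.tolist():
        label, gseed = entries[i]
        grng = _np.random.default_rng(gseed)
        coords = sample_pattern_coords(label, grng, image_shape)
        if feature_mode == "geometric":
            base = geometric_node_features(coords, image_shape)
        else:
            base = grng.standard_normal((coords.shape[0], GEOMETRIC_FEATURE_DIM))
        graphs.append(CalcificationGraph(
            coords=coords,
            adjacency=knn_adjacency(coords, k),
            image_shape=image_shape,
            base_features=base,
            label=CLASS_NAMES.index(label),
            provenance={"image_id": f"synthetic-graph-{label}-{gseed}",
                        "seed": gseed, "feature_mode": feature_mode},
        ))
    return graphs
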