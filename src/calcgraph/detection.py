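"""Calcification candidate detection.

Two stages: (1) white top-hat morphological filtering with a disk structuring
element picks bright structures smaller than the disk out of the uneven
parenchymal background, followed by thresholding and connected-component
analysis; (2) a small patch CNN ("verifier") trained with binary
cross-entropy re-scores each candidate patch and strict filtering at a
probability cutoff removes false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as _np
import autograd.numpy as anp
from scipy import ndimage
from skimage.morphology import disk, white_tophat, black_tophat

from . import _nn
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    DegenerateLabelError,
    ShapeError,
)
from .io import BreastMask, MammogramImage


@dataclass
class DetectionConfig:
    """Detector settings.

    ``threshold_rule`` is one of:

    - ``"robust"``: T = median + k * 1.4826 * MAD of the top-hat response
      inside the breast mask, with ``threshold_value`` = k (default 4.0).
      Tracks the noise floor regardless of how many calcifications are
      present.
    - ``"percentile"``: T = the ``threshold_value``-th percentile of the
      response inside the mask.
    - ``"fixed"``: T = ``threshold_value``.

    ``smooth_sigma`` is the width of the Gaussian matched filter the pipeline
    applies to the top-hat response before thresholding (0 disables it);
    planted spots are themselves roughly Gaussian, so this maximizes their
    contrast against single-pixel noise exceedances.

    ``patch_size`` D is the side of the square patch handed to the verifier;
    with the default D=14 the candidate center sits at window index (7, 7),
    i.e. the window spans offsets -7..+6 around the center.
    """

    se_radius: int = 3
    smooth_sigma: float = 0.5
    threshold_rule: str = "robust"
    threshold_value: float = 3.0
    patch_size: int = 14
    min_blob_area: int = 1
    max_blob_area: int = 200
    verifier_cutoff: float = 0.5

    def __post_init__(self):
        if self.patch_size < 3:
            raise ConfigurationError("patch_size must be >= 3")
        if not 0 < self.verifier_cutoff < 1:
            raise ConfigurationError("verifier_cutoff must be in (0, 1)")
        if self.min_blob_area < 1 or self.min_blob_area >= self.max_blob_area:
            raise ConfigurationError("min_blob_area must be < max_blob_area")
        if self.threshold_rule not in ("robust", "percentile", "fixed"):
            raise ConfigurationError(
                f"unknown threshold_rule {self.threshold_rule!r}")


@dataclass
class CalcificationCandidate:
    """A detected calcification: center, patch, and detection scores."""

    center: tuple  # (x, y) pixel coordinates
    patch: _np.ndarray  # D x D intensities
    detector_score: float
    verifier_prob: float | None = None


def top_hat_transform(image, se_radius, enhance_contrast=False):
    """White top-hat IT = I - opening(I, disk(se_radius)).

    With ``enhance_contrast`` the image is first replaced by
    I + tophat - bottomhat (morphological contrast enhancement) and the
    top-hat of the enhanced image is returned.
    """
    pixels = image.pixels if isinstance(image, MammogramImage) else _np.asarray(image)
    if se_radius < 1:
        raise ConfigurationError("se_radius must be >= 1")
    if 2 * se_radius + 1 > min(pixels.shape):
        raise ConfigurationError(
            f"structuring element (radius {se_radius}) exceeds half the image "
            f"extent {pixels.shape}")
    se = disk(se_radius)
    if enhance_contrast:
        enhanced = (
            pixels.astype(float)
            + white_tophat(pixels, footprint=se)
            - black_tophat(pixels, footprint=se)
        )
        return white_tophat(enhanced, footprint=se)
    return white_tophat(pixels, footprint=se)


def threshold_detect(response, mask, config):
    """Binary detection mask: response >= T inside the breast mask."""
    response = _np.asarray(response)
    mvals = mask.mask if isinstance(mask, BreastMask) else _np.asarray(mask, bool)
    if response.shape != mvals.shape:
        raise ShapeError(
            f"response {response.shape} and mask {mvals.shape} shapes differ")
    inside = response[mvals]
    if inside.size == 0:
        raise DegenerateInputError("breast mask is empty")
    if config.threshold_rule == "fixed":
        t = config.threshold_value
    elif config.threshold_rule == "percentile":
        t = _np.percentile(inside, config.threshold_value)
    else:
        med = _np.median(inside)
        mad = _np.median(_np.abs(inside - med))
        t = med + config.threshold_value * 1.4826 * mad
    return (response >= t) & mvals


def extract_patch(pixels, x, y, size):
    """Size x size window with the center at window index (size//2, size//2).

    Windows reaching past the image border are replicate-padded.
    """
    half = size // 2
    padded = _np.pad(pixels, half, mode="edge")
    y0, x0 = y + half - half, x + half - half  # top-left in padded frame
    return padded[y0 : y0 + size, x0 : x0 + size]


def extract_candidates(detection_mask, image, config, response=None):
    """Connected components of the detection mask -> candidates.

    8-connected components with area inside the configured bounds become
    candidates; the center is the response-weighted centroid rounded to the
    nearest pixel, the detector score the component's peak response, and the
    patch a D x D window of the raw image.  Candidates are sorted by (y, x).
    """
    pixels = image.pixels if isinstance(image, MammogramImage) else _np.asarray(image)
    det = _np.asarray(detection_mask, bool)
    weights = pixels.astype(float) if response is None else _np.asarray(response)
    labels, n = ndimage.label(det, structure=_np.ones((3, 3), dtype=int))
    candidates = []
    for comp in range(1, n + 1):
        ys, xs = _np.nonzero(labels == comp)
        area = ys.size
        if not (config.min_blob_area <= area <= config.max_blob_area):
            continue
        w = weights[ys, xs]
        if w.sum() <= 0:
            w = _np.ones_like(w)
        cx = int(_np.rint(float((xs * w).sum() / w.sum())))
        cy = int(_np.rint(float((ys * w).sum() / w.sum())))
        candidates.append(
            CalcificationCandidate(
                center=(cx, cy),
                patch=extract_patch(pixels, cx, cy, config.patch_size),
                detector_score=float(weights[ys, xs].max()),
            )
        )
    candidates.sort(key=lambda c: (c.center[1], c.center[0]))
    return candidates


# ---------------------------------------------------------------------------
# verifier CNN


@dataclass
class VerifierModel:
    """Patch classifier separating true calcifications from mimics."""

    params: dict
    architecture_tag: str = "conv4-gap"
    patch_size: int = 14
    training_meta: dict = field(default_factory=dict)

    def predict_proba(self, patches):
        """Probability that each D x D patch contains a true calcification."""
        patches = self._prepare(patches)
        logits = _nn.verifier_forward(self.params, _standardize_patches(patches))
        return _np.asarray(_nn.sigmoid(logits))

    def extract_features(self, patches):
        """Pooled last-conv feature maps (the verifier's trunk), usable as
        frozen patch features for graph construction."""
        import autograd.numpy as anp

        patches = self._prepare(patches)
        x = _standardize_patches(patches)[:, None, :, :]
        for i, layer in enumerate(self.params["conv"]):
            x = _nn.relu(_nn.conv2d(x, layer["w"], layer["b"]))
            if i in (1, 3):
                x = _nn.maxpool2(x)
        return _np.asarray(anp.mean(x, axis=(2, 3)))

    def _prepare(self, patches):
        patches = _np.asarray(patches, dtype=float)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[1:] != (self.patch_size, self.patch_size):
            raise ShapeError(
                f"expected patches of size {self.patch_size}, got {patches.shape[1:]}")
        return patches


def _standardize_patches(patches):
    """Per-patch standardization (zero mean, unit variance) for the verifier.

    Removes the local background level so the CNN sees spot shape, not
    absolute exposure.
    """
    mean = patches.mean(axis=(1, 2), keepdims=True)
    std = patches.std(axis=(1, 2), keepdims=True)
    return (patches - mean) / (std + 1e-6)


def binary_cross_entropy(probs, labels):
    """Summed BCE  -sum y log p + (1-y) log(1-p); the verifier's loss."""
    p = anp.clip(probs, 1e-12, 1 - 1e-12)
    return -anp.sum(labels * anp.log(p) + (1 - labels) * anp.log(1 - p))


@dataclass
class VerifierTrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 128
    seed: int = 0


def train_verifier(patches, labels, config=None):
    """Fit the verifier CNN by Adam on mean binary cross-entropy."""
    config = config or VerifierTrainConfig()
    patches = _np.asarray(patches, dtype=float)
    labels = _np.asarray(labels, dtype=float)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ShapeError(f"patches must be (n, D, D), got {patches.shape}")
    if len(set(labels.tolist())) < 2:
        raise DegenerateLabelError("verifier training needs both labels present")
    rng = _np.random.default_rng(config.seed)
    params = _nn.verifier_init(rng)
    n = patches.shape[0]
    std_patches = _standardize_patches(patches)

    def loss_fn(p, batch):
        idx = batch
        logits = _nn.verifier_forward(p, std_patches[idx])
        return binary_cross_entropy(_nn.sigmoid(logits), labels[idx]) / idx.size

    def batches(epoch):
        order = rng.permutation(n)
        return [order[i : i + config.batch_size] for i in range(0, n, config.batch_size)]

    params, history = _nn.minimize_adam(
        loss_fn, params, batches, epochs=config.epochs, lr=config.lr,
        decay_every=max(1, config.epochs // 3))
    return VerifierModel(
        params=params,
        patch_size=patches.shape[1],
        training_meta={
            "epochs": config.epochs,
            "seed": config.seed,
            "final_loss": history[-1],
            "loss_history": history,
        },
    )


def filter_candidates(candidates, model, cutoff):
    """Keep candidates whose verifier probability reaches ``cutoff``.

    Every candidate is annotated with its probability; input order is
    preserved.
    """
    if not candidates:
        return []
    probs = model.predict_proba(_np.stack([c.patch for c in candidates]))
    kept = []
    for cand, p in zip(candidates, probs):
        cand.verifier_prob = float(p)
        if cand.verifier_prob >= cutoff:
            kept.append(cand)
    return kept


def match_detections(true_xy, detected_xy, tol=3.0):
    """Greedy one-to-one matching of detections to ground-truth centers.

    Pairs are matched in order of increasing distance up to ``tol`` pixels.
    Returns ``(n_matched, recall, precision)``.
    """
    true_xy = _np.asarray(true_xy, dtype=float).reshape(-1, 2)
    detected_xy = _np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    if true_xy.shape[0] == 0 or detected_xy.shape[0] == 0:
        return 0, (1.0 if true_xy.shape[0] == 0 else 0.0), \
               (1.0 if detected_xy.shape[0] == 0 else 0.0)
    d = _np.linalg.norm(true_xy[:, None] - detected_xy[None], axis=2)
    pairs = _np.argwhere(d <= tol)
    order = _np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_t, used_d, matched = set(), set(), 0
    for ti, di in pairs[order]:
        if ti not in used_t and di not in used_d:
            used_t.add(int(ti))
            used_d.add(int(di))
            matched += 1
    return matched, matched / true_xy.shape[0], matched / detected_xy.shape[0]


def detect_calcifications(image, mask, config=None, verifier=None, roi=None):
    """Full detection pipeline: top-hat -> threshold -> components -> verifier.

    With an ``roi`` annotation, detection is restricted to the annotated
    region (intersected with the breast mask); otherwise the whole breast is
    searched.
    """
    config = config or DetectionConfig()
    response = top_hat_transform(image, config.se_radius)
    if config.smooth_sigma > 0:
        response = ndimage.gaussian_filter(response, config.smooth_sigma)
    # the breast edge is a step the opening cannot fit, so a high-response
    # rim hugs the boundary; detection is restricted to the eroded interior
    mvals = mask.mask if isinstance(mask, BreastMask) else _np.asarray(mask, bool)
    rim = config.se_radius + int(_np.ceil(2 * config.smooth_sigma)) + 1
    interior = ndimage.binary_erosion(mvals, iterations=rim)
    if roi is not None:
        ys, xs = _np.mgrid[0 : interior.shape[0], 0 : interior.shape[1]]
        if roi.geometry["type"] == "circle":
            cx, cy = roi.geometry["center"]
            inside = ((xs - cx) ** 2 + (ys - cy) ** 2
                      <= roi.geometry["radius"] ** 2)
        else:
            from matplotlib.path import Path as MplPath

            pts = _np.column_stack([xs.ravel(), ys.ravel()])
            inside = MplPath(roi.geometry["vertices"]).contains_points(pts)
            inside = inside.reshape(interior.shape)
        interior = interior & inside
    det = threshold_detect(response, BreastMask(interior), config)
    candidates = extract_candidates(det, image, config, response=response)
    if verifier is not None:
        candidates = filter_candidates(candidates, verifier, config.verifier_cutoff)
    return candidates
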