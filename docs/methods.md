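# Methods

`calcgraph` classifies the spatial distribution of microcalcifications on a
mammogram into the five BI-RADS distribution descriptors — diffuse, regional,
grouped, linear, segmental — by converting each image into a *calcification
graph* and classifying the graph. This note documents the model, the
numerical choices, the synthetic study conditions, and the known limits of
what the synthetic results demonstrate.

## Pipeline

1. **Breast segmentation.** A global Otsu threshold on the native-bit-depth
   histogram separates the breast from the dark background; post-processing
   keeps the largest 8-connected component and fills holes. A 2-px border
   strip is cleared first so film-edge artifacts cannot seed the component.
   Pectoral-muscle removal is out of scope.

2. **Calcification detection.** The white top-hat transform
   `IT = I − opening(I, SE)` with a disk structuring element (default radius
   3 px) removes background structures larger than the disk, leaving bright
   spots. Candidates are pixels with `IT ≥ T` inside the breast, grouped
   into 8-connected components; each component's response-weighted centroid
   becomes a candidate center with a 14×14 patch (center at window index
   (7,7), offsets −7..+6; replicate padding at borders).

   *Numerical choices.* The pipeline applies a Gaussian matched filter
   (σ = 0.5 px) to `IT` before thresholding — the spots are approximately
   Gaussian, so this maximizes their contrast against single-pixel noise.
   Detection is restricted to the breast interior eroded by the SE radius
   plus the filter support, because the breast-edge intensity step produces
   a high-response rim the opening cannot remove. The default threshold is
   the robust noise floor `T = median + k·1.4826·MAD` (default k = 3.0) of
   the filtered response inside the mask. A percentile rule and
   a fixed threshold remain available; a fixed percentile was rejected as
   the default because it fixes the *number* of above-threshold pixels,
   which cannot track spot counts that legitimately range from 5 to 300 per
   image. The default is deliberately permissive (`min_blob_area = 1`):
   proposal recall is ~0.96 and precision ~0.5, and the verifier CNN stage
   restores precision.

3. **Verifier CNN.** A 4-conv-layer network (3×3 kernels, global average
   pool, two dense layers) scores each candidate patch with the probability
   that it contains a true calcification; training minimizes binary
   cross-entropy with Adam. Patches are standardized per patch (zero mean,
   unit variance) inside the model — without this the background level
   dominates and the network does not train. Labels come from ground truth:
   candidates within 3 px of a planted (or annotated) calcification are
   positive, the detector's own false alarms are the hard negatives.
   Candidates with probability below the cutoff (default 0.5) are removed.
   On phantoms this two-stage detector reaches recall ≈ 0.95 and precision
   ≈ 0.95 at spot amplitude 5× the noise σ.

4. **Graph construction.** Verified candidates become nodes. Node features
   are the concatenation of deep patch features (global-average-pooled maps
   of a six-layer residual CNN, default 64 dims, trained jointly with the
   classifier) and a learnable affine embedding of the center coordinates
   (default 16 dims; coordinates are first normalized to [0,1] by image
   width/height for scale invariance — raw-pixel mode is available). The
   default node width is therefore 80. Adjacency is the symmetrized
   k-nearest-neighbor graph (k = 8) under Euclidean distance, ties broken
   toward the lower node index. Each directed edge j→i carries the label
   `(Δx, Δy, d)`: source-minus-destination offsets and their length, all
   normalized by the image diagonal — the spatial-graph convention of
   edge-conditioned convolution.

5. **Classifier.** Three edge-conditioned convolution (ECC) layers: a
   two-layer filter network (tanh hidden layer, width 32) maps each edge
   label to an edge-specific `D_out×D_in` matrix; node i's update is the
   mean of the edge-conditioned linear maps of its neighbors plus a bias,
   followed by ReLU. Readout is either the zero-padded flatten (nodes
   sorted by (y,x), padded/truncated to N_max = 128 rows, truncation keeps
   the highest detector scores) or mean pooling. A two-layer fully
   connected head with elementwise **sigmoid** produces five per-class
   probabilities (not constrained to sum to 1, as in multi-label heads);
   argmax decides the class. A softmax variant exists for ablation.

   *Self-loops.* The stacked layers include a (0,0,0)-labeled self-loop at
   every node, so each update retains the node's own features at weight
   1/(deg+1). Without it each layer discards the node itself and node-level
   evidence cannot survive three rounds of neighborhood averaging; the
   same rule keeps single-node graphs well defined. The public
   `ecc_forward` operation implements the literal neighbors-only update on
   whatever edges a graph carries.

   *Initialization.* The filter network's output bias is initialized to
   vec(I), so every layer starts as plain neighborhood averaging and the
   edge-conditioned part is a small learned perturbation. With zero-centered
   initialization the product of three near-zero filter stacks collapses
   activations to ~1e-9 and training never leaves the majority-class
   solution; the identity start fixes this completely.

6. **Loss and training.** Multi-label focal loss summed over the five
   sigmoid components: `p_t` is the probability assigned to each
   component's true state and each contributes `−(1−p_t)^γ log(p_t)`
   (γ = 2 by default; γ = 0 is exactly summed binary cross-entropy).
   Optional per-class α weights are supported, and a class-balanced
   resampling mode (`TrainConfig.balanced_sampling`) offers the baseline
   alternative to loss reweighting. Training uses Adam
   (default lr 3e-4, 100 epochs, halved every 30 epochs — the benchmark
   configuration below uses faster settings) and is fully deterministic
   given the seed; models serialize to a single `.npz` (weights + config +
   seed + class order) and reload bit-identically.

7. **Saliency.** Node importance for a target class is Grad-CAM adapted to
   graphs: the gradient of the class logit with respect to node
   activations; channel weights are the gradient averaged over nodes (the
   analogue of spatial averaging) and a node scores the ReLU of its
   weighted channel sum, min-max normalized to [0,1]. A per-node
   gradient×activation mode exists. The attributed layer is configurable;
   the **default is the fused input features (layer 0)**, not the last
   convolution: with k = 8 on graphs of a few dozen nodes every node is
   within one or two hops of every other, and controlled experiments showed
   that even one round of neighborhood averaging delocalizes the evidence —
   attribution at deeper layers then scores decoy nodes as highly as the
   true cluster. Overlays color nodes blue→yellow→red over [0,1].

## Synthetic study conditions

The clinical dataset the method was designed for is private, so the
`synthetic` module defines the study conditions: a half-ellipse breast
(chest wall at x = 0, semi-axes 0.78·W and 0.42·H on a 256×192 image) with
smooth parenchyma-like texture (Gaussian field smoothed with σ = 12 px,
amplitude 0.08 — deliberately larger-scale than the spots, as real
parenchymal structure is cm-scale while calcifications are sub-mm), pixel
noise σ = 0.02, and Gaussian spots with σ ∈ [0.7, 1.8] px (≈ 3–7 px across,
standing in for 0.1–1 mm calcifications) at amplitude 0.10 — exactly 5× the
noise σ, the hardest regime the detection performance claims cover. Spot
counts and geometries per descriptor:

| class     | spots  | geometry |
|-----------|--------|----------|
| diffuse   | 40–100 | uniform over the breast interior |
| regional  | 25–60  | disc of radius 0.32–0.45 of the breast minor semi-axis |
| grouped   | 6–14   | disc of radius 0.10–0.16 of the minor semi-axis |
| linear    | 6–15   | band of length 0.40–0.65 of the minor semi-axis, width 1.2 px, random orientation |
| segmental | 20–50  | wedge, apex at the nipple point, half-angle 8–16°, length 0.55–0.80 of the major semi-axis |

Minimum spot separation is 5 px (so neighboring spots stay resolvable at
the detector's scale). The class-imbalance preset mirrors a clinical mix:
50.1% grouped, 27.7% regional, 14.2% segmental, 6.0% diffuse, 2.0% linear,
realized by largest-remainder rounding. Every artifact is a pure function
of its manifest; datasets replay bit-identically.

`generate_graph_dataset` skips imaging and samples node coordinates
directly from the pattern geometry. Its "geometric" node features (8 dims)
are density-style responses — exp(−d/s) of the 1st/3rd/8th-NN distance,
centroid proximity, a two-scale density-profile gap response
`1 − exp(−(d12/d4 − 1)/3)` that fires for nodes in a tight isolated group —
plus three graph-level values (RMS spread, covariance anisotropy, log node
count). Density-style encoding (rather than raw distances) matters twice:
it makes cluster membership a *high*-activation event, which gradient
saliency requires, and it conditions the classifier well. The "random"
feature mode replaces features with seeded Gaussian noise for null
experiments.

## Benchmark configurations

- **Classification benchmark** (500 graphs, paper-mix imbalance): geometric
  features + 16-dim spatial embedding, ECC widths (16,16,16), filter hidden
  32, mean readout, head hidden 32; Adam lr 5e-3 halved every 10 epochs,
  25 epochs, batches of 32. Five-fold case-stratified cross-validation
  reaches ≈ 0.99–1.0 accuracy with minority-class (linear, 2%; diffuse, 6%)
  recall at 1.0 across seeds; both the focal (γ=2) and cross-entropy (γ=0)
  losses solve the benchmark, so the focal-vs-CE minority-recall comparison
  is typically a tie.
- **Saliency study**: a two-class controlled design — grouped graphs with
  10 scattered decoy nodes versus diffuse graphs drawn with the *same total
  node count*. Matching node counts removes graph size as a cue and the
  decoys match the diffuse geometry node-for-node, so the tight cluster is
  the only class evidence; a model that solves the task must rely on it.
  (In an earlier five-class variant the model could classify "grouped" from
  node count and spread alone, making the cluster causally irrelevant — and
  honest saliency correctly refused to highlight it.)
- **Imaging end-to-end study** (tests): 25 balanced phantoms with 8–20
  spots, verifier-filtered graphs, flatten readout, 30 epochs — training
  accuracy ≥ 0.9. Problem sizes throughout are chosen so the whole suite
  runs on one CPU core at desk scale.

## What the synthetic results do and do not show

Passing phantoms shows the machinery is correct and that the model can
recover distribution patterns when they are geometrically well defined, at
the stated SNR, under strong class imbalance. It does not show clinical
performance: real parenchyma has power at all spatial scales (our texture
does not), real calcifications vary in shape and contrast (ours are
Gaussian), vessel and benign calcifications are absent, and the clinical
inter-class boundaries (e.g., grouped vs regional extent) are continuous
and reader-defined rather than sampled from disjoint parameter ranges. The
near-perfect benchmark accuracy reflects those idealized geometry gaps, not
expected accuracy on mammograms.

## Degenerate inputs and edge rules

Constant images are rejected for segmentation (Otsu undefined). Empty
candidate lists cannot become graphs (a diagnostic names the image).
Duplicate node coordinates are allowed (distance 0; kNN ties break toward
the lower index; coincident edges carry the label (0,0,0)). Graphs with a
single node use a self-loop so the convolution's mean is defined. Focal
loss clamps probabilities to [1e-12, 1−1e-12]. Saliency that is constant
across nodes normalizes to all zeros with a warning rather than dividing by
zero.
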