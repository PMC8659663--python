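# Methods

## Problem and pipeline

Adhesion assays for sickle cell disease perfuse clinical whole blood
through protein-functionalized microfluidic channels and image the channel
floor in phase contrast at 10x. The quantity of interest is the number of
adhered sickle red blood cells (sRBCs) per channel, split into two
morphological subtypes that track membrane mechanics:

- **deformable** — partially sickled, rounded/elliptical body that retains
  the biconcave dimple; stretches visibly under flow;
- **non-deformable** — highly sickled, elongated spindle with sharp
  endpoints and no dimple; nearly rigid under flow.

Everything else that shows up in a whole-blood image (white blood cells,
out-of-focus or flowing objects with diffraction halos, platelet clusters,
debris) must be rejected.

`sicklenet` implements this as two networks in tandem:

1. **Phase I — semantic segmentation.** The channel mosaic (canonically
   15,000 x 5,250 pixels) is tiled on a 100 x 35 grid into 3,500 tiles of
   150 x 150, each tile is bicubically resized to the 128 x 128 x 3
   network input (grayscale replicated to three channels) and zero-centered.
   An encoder-decoder network with batch normalization and U-Net-style
   copy-and-concatenate skip connections emits a per-pixel softmax over
   three classes: background (0), adhered sRBC (1), non-functionally
   adhered / other (2).
2. **Phase II — crop classification.** Tile predictions are stitched back
   to a whole-channel mask, the adhered class is binarized, connected
   clusters smaller than 60 pixels are removed as debris, and a 32 x 32
   box centered at each surviving cluster centroid is cut from the
   intensity image. A small CNN with a global-average-pool +
   fully-connected softmax head assigns each crop to deformable sRBC,
   non-deformable sRBC, or non-sRBC; the third class exists purely to
   filter Phase I mistakes out of the counts.

Ensembles are formed by averaging member softmax outputs (probability
averaging, both phases). Counts per channel report
`n_total_srbc = n_deformable + n_nondeformable` with non-sRBC crops
tallied separately as rejected.

## Loss

Phase I trains on `L = L_CE + L_Jac` with

```
L_CE  = -(1/N) Σ_α Σ_i [ p_i(α) log q_i(α) + (1 - p_i(α)) log(1 - q_i(α)) ]
L_Jac = -log J,    J = Σ_αi p q / (2N - Σ_αi p q)
```

where `p` is the one-hot ground truth, `q` the per-pixel softmax and `N`
the number of pixels in the batch (pixels x images — the only reading
under which `J = 1` at a perfect prediction). The binary-style
cross-entropy is implemented exactly in this form, with the
`(1-p)log(1-q)` terms; a configuration switch substitutes categorical
cross-entropy for comparison. Probabilities are clamped to
`[1e-7, 1 - 1e-7]` and `J` is floored at `1e-7` before the logarithm.
Phase II trains on categorical cross-entropy.

Segmentation quality is reported as pixel accuracy, the Jaccard index `J`
evaluated on one-hot encodings with the same index the loss uses, the Dice
coefficient `D = 2J/(1+J)`, and the plain per-class IoU for the adhered
class. Classification quality uses the per-class confusion-count
definitions `Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`,
`Accuracy = (TP+TN)/Total`; undefined ratios are reported as missing
values, never coerced to zero.

## Networks and optimization

No GPU deep-learning stack is assumed: both networks run on a small NHWC
convolution engine (`sicklenet.nn`) with hand-written backward passes
(im2col convolution, batch normalization, 2x2 max pool, nearest-neighbor
upsampling, global average pooling, softmax) verified against central
finite differences in float64. The optimizer is Adam.

Desk-scale defaults, chosen once for 1-CPU tractability:

| parameter | Phase I | Phase II |
| --- | --- | --- |
| architecture | depth-2 encoder-decoder, base 8 filters (8/16/32) | 3 conv stages 8/16/32 + GAP + FC |
| input | 128 x 128 x 3 | 32 x 32 x 3 (native) |
| epochs | 16 | 30 |
| batch size | 8 | 32 |
| Adam lr | 3e-3 | 1e-3 |

The Phase I learning rate matters: at 2e-3 a sizeable fraction of
initialization seeds never learn the rare non-functional class (its logit
stays dominated and the adhered IoU saturates near 0.5-0.65); at 3e-3 the
class separates reliably across most seeds. Wider networks (base 12-16)
achieve the same at higher cost. Because a residual fraction of
initializations still lands in the dead-class basin — diagnosable early
and unambiguously (zero predicted non-functional pixels on validation
tiles after a few epochs, against thousands in healthy runs) — the
training loop carries a deterministic restart safeguard: if after
`collapse_check_epoch` (default 3) epochs the validation predictions
contain no non-functional pixels while the truth does, the run restarts
from a shifted initialization seed, up to `max_restarts` (default 3)
times. The whole procedure remains a pure function of the configured
seed. Minibatch iteration counts include the final
partial batch (ceil), which reproduces the canonical protocol arithmetic:
6,863 crops at minibatch 32 give 215 iterations/epoch and 6,450 over 30
epochs.

Training augmentation follows the two published protocols:

- **balance augmentation** (corpus-level, Phase I): every tile containing
  at least one adhered or non-functional object gains exactly three
  rotated copies (90/180/270 degrees). A tile with adhered pixels counts
  in the adhered category; otherwise in the other category. On the
  canonical corpus (877 adhered tiles, 360 other tiles out of 3,500) this
  yields 2,631 + 1,080 new samples and a 7,211-sample corpus.
- **random augmentation** (per-iteration, training subset only):
  horizontal and vertical reflections each with probability 0.5 plus a
  rotation uniform in [-90, 90] degrees; images bilinear, masks
  nearest-neighbor. Validation data are never augmented.

k-fold cross-validation (`k = 5`, shuffled 80/20) partitions the dataset
into disjoint validation folds whose sizes differ by at most one; for
6,863 crops that is {1,372, 1,373} (the canonical report prints 1,372,
whose 5,488 + 1,372 = 6,860 does not add to 6,863 — near-equal folds are
used here and the discrepancy noted). Single-run training uses the same
shuffled 80/20 split.

## Interpretability

With `f_ijk` the final convolutional feature map and `(w_mk, b_m)` the
GAP+FC head, the class activation map is `c_ij(m) = Σ_k w_mk f_ijk`
(bias excluded), upsampled bilinearly to the crop for overlay; raw values
are preserved for testing, and min-max normalization is applied only at
rendering. Because pooling and the linear head commute, the spatial mean
of the CAM equals `w_m · v` exactly — asserted as an identity in the
tests. Occlusion tests block a rectangle of the crop (block value = crop
mean, i.e. zero in zero-centered units) and report the drop of the target
class probability; on synthetic deformable cells the drop is larger when
the central dimple is blocked than when a background corner is.

## Deformability analysis

Aspect ratio is `AR = minor/major` of the mask's equivalent ellipse: the
eigenvalues λ of the pixel-coordinate covariance give axis lengths 4√λ,
so `AR = sqrt(λ_min/λ_max)`; any consistent axis convention cancels in the
ratio. The per-cell deformability readout is
`pct_change = 100 (AR_noflow - AR_flow) / AR_noflow`, with the relaxed
no-flow state as denominator (recorded in output metadata). The group
difference between subtypes is tested with Welch's unequal-variance t test
(Mann-Whitney U available by configuration); with zero variance in both
groups the p-value is reported as NaN. Masks with fewer than 5 pixels or
collinear pixel sets are rejected.

## Synthetic scenes

The generator (`sicklenet.synthetic`) emulates the image properties the
pipeline actually depends on — not phase-contrast optics. A scene is a
background plane (level ~0.6, per-axis linear luminosity gradients,
additive Gaussian noise, defaults sigma 0.02) plus parametric objects:

- deformable sRBC: anti-aliased filled ellipse (major 13-17 px at 10x
  scale), darker than background by contrast 0.25, with a central dimple
  that recovers `dimple_depth` (0.5-0.8) of the contrast;
- non-deformable sRBC: tapered spindle along the major axis (major
  20-26 px, half-width profile `b (1-t²)^s` with sharpness s = 1.1-1.6),
  sharp endpoints, no dimple;
- WBC: smooth bright-bodied disc with a darker rim;
- out-of-focus object: blurred dark body plus a bright halo ring;
- debris: dark specks of 3-6 px.

Mask label 1 covers adhered-cell footprints, label 2 the rest; footprints
keep a 2-pixel guard band so every adhered cell is exactly one
8-connected component, and colliding placements are relocated (up to 100
redraws from the scene's own generator) or rejected with an error. A seed
fully determines the render. Typical adhered footprints are 80-150 px,
safely above the 60-px debris cut.

What the generator deliberately does **not** model: optical
point-spread/halo physics, cell-to-cell intensity texture, overlapping or
touching cells, motion between captures, staining or illumination drift
beyond linear gradients. Passing tests therefore demonstrate that the
pipeline machinery — tiling, losses, training loop, extraction
arithmetic, ensembling, counting — is correct and learnable on controlled
morphology; they do not certify clinical-image accuracy, which in the full
protocol rests on manually labeled channel data and pretrained backbones.

## Study sizes

The self-contained study that the test suite and `scripts/acceptance.py`
run: 200 synthetic 150 x 150 tiles (160 train / 40 validation) for
Phase I; 560 synthetic crops (448/112) for Phase II; 8 synthetic 300 x 300
channels for end-to-end count agreement (R² about the identity line);
7 + 7 synthetic paired flow/no-flow cells (jittered 20% vs 0% mean AR
change, sd 5%) for the deformability comparison, plus a 200-replicate
power check at those group conditions. These sizes are the package's
desk-scale defaults; the full published protocol (3,500 labeled tiles,
6,863 curated crops, ResNet-50 transfer learning, 19 clinical channels)
requires the clinical corpus and is out of scope here.

## Numerical choices and edge cases

- Intensities are float in [0, 1] internally, 8-bit on disk; masks are
  indexed PNG {0,1,2}.
- Coordinates are row-major, 0-based, origin top-left; boxes half-open.
  Crop centroids round half-up; the 32-px window is `[r-16, r+16)`.
- Label masks are resized nearest-neighbor only; intensity images
  bicubic (order-3, no antialiasing).
- Border crops are reflect-padded (constant fill available).
- Argmax ties break toward the lowest class index.
- Connected components use 8-connectivity by default (4 available).
- Ensemble averaging is the arithmetic mean of probabilities; an ensemble
  of identical members is bit-equivalent to a single member.
- Fixed seeds plus fixed models give bit-identical channel reports.
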