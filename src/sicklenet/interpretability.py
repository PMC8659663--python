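"""Class activation maps and occlusion tests for the crop classifier.

With f_ijk the last convolutional feature map and (w_mk, b_m) the weights
of the global-average-pool + fully-connected softmax head, the class
activation map for class m is c_ij(m) = sum_k w_mk f_ijk — a coarse
spatial heat map of the evidence for that class, upsampled to the crop
size for overlay. Because pooling and the linear head commute, the spatial
mean of the CAM equals the head pre-activation w_m . v (without bias),
which is asserted as an algebraic identity in the tests.

Occlusion tests block a rectangle of the crop and report how much the
target-class probability drops; a large drop marks the blocked region as
evidence the network relied on (the dimple for deformable cells, the sharp
endpoints for non-deformable ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import resize_bicubic
from .classification import CELL_CLASSES, CLASS_INDEX, classify_crops


@dataclass
class CAMHeatmap:
    cam: np.ndarray          # native feature-map resolution (H, W)
    upsampled: np.ndarray    # bilinear rendering at crop resolution
    cell_class: str


@dataclass
class OcclusionResult:
    prob_before: np.ndarray  # length-3 class probabilities
    prob_after: np.ndarray
    target_class: str
    delta: float             # drop of the target-class probability


def global_average_pool(f: np.ndarray) -> np.ndarray:
    """v_k = mean over spatial positions of f_ijk (1/(H*W) normalization)."""
    f = np.asarray(f)
    if f.ndim != 3 or f.shape[0] == 0 or f.shape[1] == 0:
        raise ValueError("expected a non-empty (H, W, K) feature map")
    return f.mean(axis=(0, 1))


def compute_cam(f: np.ndarray, w: np.ndarray, cell_class,
                crop_size: int = 32) -> CAMHeatmap:
    """c_ij(m) = sum_k w_mk f_ijk for class m; bias excluded.

    ``w`` is the (3, K) head weight matrix; ``cell_class`` a class name or
    index. The raw map is kept; the upsampled rendering is bilinear at
    ``crop_size`` (min-max normalization is left to plotting code so raw
    values stay testable).
    """
    f = np.asarray(f, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if f.ndim != 3 or w.ndim != 2 or f.shape[2] != w.shape[1]:
        raise ValueError(f"channel mismatch: f {f.shape}, w {w.shape}")
    m = cell_class if isinstance(cell_class, (int, np.integer)) \
        else CLASS_INDEX[cell_class]
    cam = f @ w[m]
    up = _bilinear_resize(cam, (crop_size, crop_size))
    name = CELL_CLASSES[m]
    return CAMHeatmap(cam=cam, upsampled=up, cell_class=name)


def _bilinear_resize(grid: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize
    return resize(grid, shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def cam_for_crop(model, crop: np.ndarray, cell_class, config=None) -> CAMHeatmap:
    """Convenience wrapper: run the network, pull its feature map and head."""
    from .classification import preprocess_crop

    x = preprocess_crop(crop, config)[None]
    _, feats = model.forward(x, train=False, return_features=True)
    w, _ = model.head_weights
    return compute_cam(feats[0], w, cell_class, crop_size=crop.shape[0])


def occlusion_test(crop: np.ndarray, region: tuple[int, int, int, int],
                   model, target_class, config=None,
                   block_value: float | None = None) -> OcclusionResult:
    """Probability drop for ``target_class`` when ``region`` is blocked.

    ``region`` is (r0, c0, r1, c1), half-open, within crop bounds and
    non-empty. The block value defaults to the crop mean, which maps to a
    zero ("black") block in zero-centered network units.
    """
    crop = np.asarray(crop, dtype=np.float32)
    r0, c0, r1, c1 = region
    h, w = crop.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"empty or out-of-bounds region {region} "
                         f"for crop {crop.shape}")
    m = target_class if isinstance(target_class, (int, np.integer)) \
        else CLASS_INDEX[target_class]
    blocked = crop.copy()
    blocked[r0:r1, c0:c1] = float(crop.mean()) if block_value is None \
        else block_value
    probs = classify_crops(model, np.stack([crop, blocked]), config)
    return OcclusionResult(prob_before=probs[0], prob_after=probs[1],
                           target_class=CELL_CLASSES[m],
                           delta=float(probs[0][m] - probs[1][m]))
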