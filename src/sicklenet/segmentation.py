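"""Phase I: encoder-decoder semantic segmentation of channel tiles.

Pixels are labeled background (0), adhered sRBC (1) or non-functionally
adhered / other (2). Training minimizes L = L_CE + L_Jac where

    L_CE  = -(1/N) sum_a sum_i [p log q + (1 - p) log(1 - q)]
    L_Jac = -log J,   J = (sum_a sum_i p q) / (2N - sum_a sum_i p q)

with p the one-hot ground truth, q the predicted per-pixel softmax and N
the number of pixels in the batch. The binary-style cross-entropy (with its
(1-p)log(1-q) terms) is kept exactly in that form; a switch to categorical
cross-entropy exists for comparison. The Jaccard term directly optimizes
intersection-over-union, which matters because background pixels vastly
outnumber cell pixels in real channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

from .nn import SegNet, Adam

EPS = 1e-7
N_CLASSES = 3


class PixelClass(IntEnum):
    BACKGROUND = 0
    ADHERED_SRBC = 1
    NONFUNCTIONAL_OTHER = 2


@dataclass
class SegModelConfig:
    depth: int = 2
    base_filters: int = 8
    use_batchnorm: bool = True
    use_skip_connections: bool = True
    seed: int = 0
    lr: float = 3e-3
    epochs: int = 16
    batch_size: int = 8
    augment: bool = True
    categorical_ce: bool = False
    # rare-class collapse safeguard: if after this many epochs the
    # validation predictions never contain the non-functional class while
    # the truth does, training restarts from a shifted init seed
    collapse_check_epoch: int = 3
    max_restarts: int = 3


@dataclass
class LossBreakdown:
    l_ce: float
    l_jac: float
    total: float
    n: int


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Integer label grid -> one-hot float array with a trailing class axis."""
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError("labels outside [0, n_classes)")
    return np.eye(n_classes, dtype=np.float32)[mask.astype(int)]


def _flatten_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.shape[-1] != N_CLASSES:
        raise ValueError("last axis must hold the 3 class components")
    return (p.reshape(-1, N_CLASSES).astype(np.float64),
            q.reshape(-1, N_CLASSES).astype(np.float64))


def cross_entropy_loss(p: np.ndarray, q: np.ndarray, eps: float = EPS) -> float:
    """Binary-style cross-entropy averaged over the N pixels of the batch."""
    pf, qf = _flatten_pair(p, q)
    qc = np.clip(qf, eps, 1.0 - eps)
    n = pf.shape[0]
    return float(-(pf * np.log(qc) + (1.0 - pf) * np.log1p(-qc)).sum() / n)


def jaccard_loss(p: np.ndarray, q: np.ndarray, eps: float = EPS,
                 j_floor: float = 1e-7) -> float:
    """Negative log of the soft Jaccard index J = sum(pq) / (2N - sum(pq))."""
    pf, qf = _flatten_pair(p, q)
    n = pf.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    inter = float((pf * np.clip(qf, eps, 1.0 - eps)).sum())
    j = inter / (2.0 * n - inter)
    return float(-np.log(max(j, j_floor)))


def combined_loss(p: np.ndarray, q: np.ndarray) -> LossBreakdown:
    l_ce = cross_entropy_loss(p, q)
    l_jac = jaccard_loss(p, q)
    n = int(np.prod(p.shape[:-1]))
    return LossBreakdown(l_ce=l_ce, l_jac=l_jac, total=l_ce + l_jac, n=n)


def _loss_and_grad(p: np.ndarray, q: np.ndarray,
                   categorical: bool = False) -> tuple[LossBreakdown, np.ndarray]:
    """Loss plus dL/dq for the training loop (same clamping as the losses)."""
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    n = int(np.prod(p.shape[:-1]))
    qc = np.clip(q.astype(np.float64), EPS, 1.0 - EPS)
    pf = p.astype(np.float64)
    if categorical:
        l_ce = float(-(pf * np.log(qc)).sum() / n)
        d_ce = -(pf / qc) / n
    else:
        l_ce = float(-(pf * np.log(qc) + (1 - pf) * np.log1p(-qc)).sum() / n)
        d_ce = (-(pf / qc) + (1 - pf) / (1 - qc)) / n
    inter = float((pf * qc).sum())
    j = max(inter / (2.0 * n - inter), 1e-7)
    l_jac = float(-np.log(j))
    # d(-log J)/d inter = -1/inter - 1/(2N - inter); d inter/dq = p
    d_jac = pf * (-1.0 / max(inter, 1e-12) - 1.0 / (2.0 * n - inter))
    breakdown = LossBreakdown(l_ce=l_ce, l_jac=l_jac, total=l_ce + l_jac, n=n)
    return breakdown, (d_ce + d_jac).astype(np.float32)


@dataclass
class BalanceReport:
    n_selected_adhered: int
    n_selected_other: int
    n_new_adhered: int
    n_new_other: int
    n_total: int


def balance_augment(tiles: list[tuple[np.ndarray, np.ndarray]]
                    ) -> tuple[list[tuple[np.ndarray, np.ndarray]], BalanceReport]:
    """Expand minority-class tiles with 90/180/270-degree rotations.

    A tile containing at least one adhered-sRBC pixel is counted in the
    adhered category; otherwise a tile containing at least one
    non-functional/other pixel counts in the other category. Every selected
    tile contributes exactly three rotated copies (image and mask rotated
    identically); originals are retained.
    """
    out = list(tiles)
    n_adh = n_oth = 0
    for image, mask in tiles:
        if image.shape[0] != image.shape[1]:
            raise ValueError("balance augmentation requires square tiles")
        has_adh = bool((mask == PixelClass.ADHERED_SRBC).any())
        has_oth = bool((mask == PixelClass.NONFUNCTIONAL_OTHER).any())
        if has_adh:
            n_adh += 1
        elif has_oth:
            n_oth += 1
        else:
            continue
        for k in (1, 2, 3):
            out.append((np.rot90(image, k).copy(), np.rot90(mask, k).copy()))
    report = BalanceReport(n_selected_adhered=n_adh, n_selected_other=n_oth,
                           n_new_adhered=3 * n_adh, n_new_other=3 * n_oth,
                           n_total=len(out))
    return out, report


def draw_augment_params(rng: np.random.Generator) -> tuple[bool, bool, float]:
    """(flip_horizontal, flip_vertical, rotation angle in degrees)."""
    return (bool(rng.random() < 0.5), bool(rng.random() < 0.5),
            float(rng.uniform(-90.0, 90.0)))


def random_augment(image: np.ndarray, mask: np.ndarray | None = None,
                   rng: np.random.Generator | None = None,
                   params: tuple[bool, bool, float] | None = None):
    """Random flips (p = 0.5 each) plus a uniform rotation in [-90, 90].

    The image is rotated with bilinear interpolation, the mask with
    nearest-neighbor. Deterministic given the generator state or explicit
    ``params``. Applied to training samples only; validation data stays
    untouched.
    """
    if params is None:
        if rng is None:
            raise ValueError("provide rng or params")
        params = draw_augment_params(rng)
    flip_h, flip_v, angle = params
    img = image
    msk = mask
    if flip_h:
        img = np.flip(img, axis=1)
        msk = np.flip(msk, axis=1) if msk is not None else None
    if flip_v:
        img = np.flip(img, axis=0)
        msk = np.flip(msk, axis=0) if msk is not None else None
    img = _sk_rotate(img.astype(np.float64), angle, order=1, mode="symmetric",
                     preserve_range=True).astype(np.float32)
    if msk is not None:
        msk = _sk_rotate(msk, angle, order=0, mode="symmetric",
                         preserve_range=True).astype(mask.dtype)
        return img, msk
    return img


def prepare_training_data(tiles: list[np.ndarray], masks: list[np.ndarray],
                          input_size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Native tiles + masks -> network inputs and nearest-resized labels."""
    from .channel import preprocess_tile, resize_mask_nearest

    x = np.stack([preprocess_tile(t, out_size=input_size) for t in tiles])
    y = np.stack([resize_mask_nearest(m, (input_size, input_size))
                  for m in masks])
    return x, y


def train_segmenter(x: np.ndarray, y: np.ndarray, config: SegModelConfig,
                    folds: int = 1):
    """Train one segmenter per fold and record loss/metric histories.

    ``x`` is the preprocessed input batch (N, S, S, 3) and ``y`` the integer
    label grid (N, S, S). With ``folds == 1`` a single shuffled 80/20
    train/validation split is used; with ``folds == k`` the k validation
    sets are disjoint and cover the dataset. Returns
    ``(models, histories, splits)``.
    """
    from .classification import kfold_split

    n = len(x)
    if n == 0:
        raise ValueError("empty dataset")
    if folds == 1:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(0.2 * n)))
        splits = [(perm[n_val:], perm[:n_val])]
    else:
        fs = kfold_split(n, k=folds, seed=config.seed)
        splits = list(zip(fs.train_ids, fs.val_ids))

    models, histories = [], []
    for fold_i, (train_ids, val_ids) in enumerate(splits):
        truth_has_other = bool(
            (y[val_ids] == PixelClass.NONFUNCTIONAL_OTHER).any())
        for attempt in range(config.max_restarts + 1):
            model = SegNet(depth=config.depth,
                           base_filters=config.base_filters,
                           use_batchnorm=config.use_batchnorm,
                           use_skip_connections=config.use_skip_connections,
                           seed=config.seed + fold_i + attempt * 1009)
            opt = Adam(model.params, lr=config.lr)
            rng = np.random.default_rng(
                config.seed * 1_000_003 + fold_i + attempt * 7919)
            rows = []
            collapsed = False
            for epoch in range(config.epochs):
                order = rng.permutation(train_ids)
                epoch_loss, n_batches = 0.0, 0
                for start in range(0, len(order), config.batch_size):
                    ids = order[start:start + config.batch_size]
                    xb = x[ids].copy()
                    yb = y[ids].copy()
                    if config.augment:
                        for s in range(len(ids)):
                            xb[s], yb[s] = random_augment(xb[s], yb[s],
                                                          rng=rng)
                    pb = one_hot(yb)
                    q = model.forward(xb, train=True)
                    loss, dq = _loss_and_grad(pb, q, config.categorical_ce)
                    opt.zero_grad()
                    model.backward(dq)
                    opt.step()
                    epoch_loss += loss.total
                    n_batches += 1
                val = evaluate_segmenter(model, x[val_ids], y[val_ids],
                                         config.categorical_ce)
                rows.append(dict(epoch=epoch, attempt=attempt,
                                 train_loss=epoch_loss / n_batches, **val))
                if (epoch == config.collapse_check_epoch and truth_has_other
                        and val["val_pred_other_px"] == 0):
                    collapsed = True  # dead rare class: restart fresh
                    break
            if not collapsed:
                break
        models.append(model)
        histories.append(pd.DataFrame(rows))
    return models, histories, splits


def evaluate_segmenter(model, x: np.ndarray, y: np.ndarray,
                       categorical: bool = False,
                       batch_size: int = 16) -> dict:
    """Validation loss plus pixel accuracy / Jaccard / Dice / class-1 IoU."""
    qs = []
    total_loss = 0.0
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        yb = y[start:start + batch_size]
        q = model.forward(xb, train=False)
        loss, _ = _loss_and_grad(one_hot(yb), q, categorical)
        total_loss += loss.total * len(xb)
        qs.append(q)
    q = np.concatenate(qs)
    pred = q.argmax(axis=-1)
    metrics = seg_metrics(pred, y)
    return dict(val_loss=total_loss / len(x),
                val_pixel_accuracy=metrics.pixel_accuracy,
                val_jaccard=metrics.jaccard, val_dice=metrics.dice,
                val_iou_adhered=per_class_iou(pred, y,
                                              PixelClass.ADHERED_SRBC),
                val_pred_other_px=int(
                    (pred == PixelClass.NONFUNCTIONAL_OTHER).sum()))


def segment_tiles(models, x: np.ndarray) -> np.ndarray:
    """Softmax fields for preprocessed tiles; ensembles average probabilities.

    ``models`` is a single network or a list; the ensemble output is the
    arithmetic mean of the member softmax fields, which stays normalized
    per pixel.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    out = None
    for m in models:
        q = m.forward(x, train=False)
        out = q.astype(np.float64) if out is None else out + q
    return (out / len(models)).astype(np.float32)


@dataclass
class SegMetrics:
    pixel_accuracy: float
    jaccard: float
    dice: float


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixel accuracy, Jaccard index and Dice coefficient of label grids.

    J is evaluated on the one-hot encodings with the same soft-Jaccard
    index used by the loss; the Dice coefficient follows as D = 2J/(1+J).
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = one_hot(truth)
    q = one_hot(pred)
    n = int(np.prod(truth.shape))
    inter = float((p * q).sum())
    j = inter / (2.0 * n - inter)
    return SegMetrics(pixel_accuracy=float((pred == truth).mean()),
                      jaccard=j, dice=2.0 * j / (1.0 + j))


def per_class_iou(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    """Plain intersection-over-union of one class's pixel sets."""
    p = pred == cls
    t = truth == cls
    union = float(np.logical_or(p, t).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum()) / union
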