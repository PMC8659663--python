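"""Phase II: classify 32x32 cell crops into three categories.

Categories: deformable sRBC (partially sickled, keeps the biconcave
dimple), non-deformable sRBC (highly sickled spindle, sharp endpoints, no
dimple) and non-sRBC (everything Phase I should not have passed through —
WBCs, out-of-focus objects, debris). The non-sRBC class exists to filter
the rare Phase I mistakes out of the final counts.

The desk-scale backbone is a small CNN trained from random initialization
at the native 32x32 input with a global-average-pool + fully-connected
softmax head; the pretrained ResNet-50 / Xception backbones of the full
protocol are external artifacts and are accepted in the configuration only
if their weights are supplied. Per-class metrics follow the standard
confusion-count definitions: Precision = TP/(TP+FP), Recall = TP/(TP+FN),
Accuracy = (TP+TN)/Total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channel import resize_bicubic, zero_center
from .nn import Adam, SmallCNN
from .segmentation import draw_augment_params
from skimage.transform import rotate as _sk_rotate

CELL_CLASSES = ("deformable_srbc", "nondeformable_srbc", "non_srbc")
CLASS_INDEX = {name: i for i, name in enumerate(CELL_CLASSES)}


@dataclass
class ClfModelConfig:
    backbone: str = "small_cnn"
    input_size: int = 32
    base_filters: int = 8
    use_batchnorm: bool = True
    seed: int = 0
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    augment: bool = True

    def __post_init__(self) -> None:
        if self.backbone != "small_cnn":
            raise NotImplementedError(
                f"backbone {self.backbone!r} needs externally supplied "
                "pretrained weights; only 'small_cnn' trains from scratch")


@dataclass
class FoldSplit:
    k: int
    train_ids: list[np.ndarray]
    val_ids: list[np.ndarray]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    total: int


def preprocess_crop(crop, config: ClfModelConfig | None = None) -> np.ndarray:
    """32x32 crop -> (input_size, input_size, 3) zero-centered input."""
    config = config or ClfModelConfig()
    pixels = crop.pixels if hasattr(crop, "pixels") else np.asarray(crop)
    if pixels.ndim == 2:
        pixels = np.repeat(pixels[:, :, None], 3, axis=2)
    if pixels.shape[:2] != (32, 32) or pixels.shape[2] != 3:
        raise ValueError(f"expected a 32x32 crop, got {pixels.shape}")
    if config.input_size != 32:
        pixels = np.stack(
            [resize_bicubic(pixels[:, :, c],
                            (config.input_size, config.input_size))
             for c in range(3)], axis=-1)
    return zero_center(pixels)


def kfold_split(n: int, k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle then partition into k near-equal disjoint validation folds.

    Fold sizes differ by at most one; the union of the validation sets is
    the full index range. Deterministic under ``seed``.
    """
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    perm = np.random.default_rng(seed).permutation(n)
    val_ids = [np.sort(chunk) for chunk in np.array_split(perm, k)]
    train_ids = [np.sort(np.setdiff1d(perm, v)) for v in val_ids]
    return FoldSplit(k=k, train_ids=train_ids, val_ids=val_ids)


def labels_to_int(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(int)
    return np.asarray([CLASS_INDEX[str(l)] for l in labels], dtype=int)


def _augment_crop(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flip_h, flip_v, angle = draw_augment_params(rng)
    if flip_h:
        x = np.flip(x, axis=1)
    if flip_v:
        x = np.flip(x, axis=0)
    return _sk_rotate(x.astype(np.float64), angle, order=1, mode="symmetric",
                      preserve_range=True).astype(np.float32)


def iterations_per_epoch(n_samples: int, batch_size: int) -> int:
    """Minibatch count per epoch; a final partial batch counts (ceil)."""
    return int(np.ceil(n_samples / batch_size))


def train_classifier(crops: np.ndarray, labels, config: ClfModelConfig,
                     folds: int = 1):
    """Train one small CNN per fold; returns (models, histories, splits).

    ``crops`` is (N, 32, 32) or (N, 32, 32, 3) raw intensities; ``labels``
    may be class names or integer indices. Random flip/rotation
    augmentation and zero-centering are applied per training sample;
    validation samples are only zero-centered. A class absent from a
    training split triggers a warning and its per-class metrics are
    reported as undefined.
    """
    import warnings

    y = labels_to_int(labels)
    n = len(crops)
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

    x_all = np.stack([preprocess_crop(c, config) for c in crops])
    raw = np.asarray(crops, dtype=np.float32)
    if raw.ndim == 3:
        raw = np.repeat(raw[..., None], 3, axis=-1)

    models, histories = [], []
    for fold_i, (train_ids, val_ids) in enumerate(splits):
        if len(np.unique(y[train_ids])) < len(CELL_CLASSES):
            warnings.warn("a class is absent from the training split; its "
                          "per-class metrics will be undefined", stacklevel=2)
        model = SmallCNN(base_filters=config.base_filters,
                         use_batchnorm=config.use_batchnorm,
                         seed=config.seed + fold_i)
        opt = Adam(model.params, lr=config.lr)
        rng = np.random.default_rng(config.seed * 1_000_003 + fold_i)
        rows = []
        for epoch in range(config.epochs):
            order = rng.permutation(train_ids)
            epoch_loss = n_batches = n_correct = 0
            for start in range(0, len(order), config.batch_size):
                ids = order[start:start + config.batch_size]
                if config.augment:
                    xb = np.stack([zero_center(_augment_crop(raw[i], rng))
                                   for i in ids])
                else:
                    xb = x_all[ids]
                yb = y[ids]
                q = model.forward(xb, train=True)
                qc = np.clip(q.astype(np.float64), 1e-7, 1.0)
                loss = float(-np.log(qc[np.arange(len(yb)), yb]).mean())
                dq = np.zeros_like(q)
                dq[np.arange(len(yb)), yb] = (-1.0 / qc[np.arange(len(yb)), yb]
                                              / len(yb))
                opt.zero_grad()
                model.backward(dq)
                opt.step()
                epoch_loss += loss
                n_batches += 1
                n_correct += int((q.argmax(axis=1) == yb).sum())
            val_q = classify_crops(model, x_all[val_ids], preprocessed=True)
            val_acc = float((val_q.argmax(axis=1) == y[val_ids]).mean())
            rows.append(dict(epoch=epoch, train_loss=epoch_loss / n_batches,
                             train_accuracy=n_correct / len(order),
                             val_accuracy=val_acc))
        models.append(model)
        histories.append(pd.DataFrame(rows))
    return models, histories, splits


def classify_crops(models, crops, config: ClfModelConfig | None = None,
                   preprocessed: bool = False, batch_size: int = 256
                   ) -> np.ndarray:
    """Class probabilities per crop; ensembles average member probabilities.

    ``models`` is one model or a list; any member exposing
    ``predict_proba`` is used through that interface (which allows oracle
    stand-ins), otherwise it is treated as a network. The hard label is the
    argmax; exact ties break toward the lowest class index.
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    if preprocessed:
        x = np.asarray(crops, dtype=np.float32)
    else:
        config = config or ClfModelConfig()
        x = np.stack([preprocess_crop(c, config) for c in crops])
    acc = np.zeros((len(x), len(CELL_CLASSES)), dtype=np.float64)
    for m in models:
        if hasattr(m, "predict_proba"):
            acc += np.asarray(m.predict_proba(x), dtype=np.float64)
        else:
            for start in range(0, len(x), batch_size):
                acc[start:start + batch_size] += m.forward(
                    x[start:start + batch_size], train=False)
    return (acc / len(models)).astype(np.float32)


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax labels; ties resolve to the lowest class index."""
    return probs.argmax(axis=1)


def clf_metrics(predictions, truths
                ) -> tuple[pd.DataFrame, dict[str, ConfusionCounts]]:
    """Per-class precision / recall / accuracy with confusion counts.

    Undefined ratios (zero denominator) are reported as NaN, never coerced
    to 0, so macro averages are not silently inflated.
    """
    pred = labels_to_int(predictions)
    true = labels_to_int(truths)
    if len(pred) != len(true) or len(pred) == 0:
        raise ValueError("predictions and truths must have equal length >= 1")
    total = len(true)
    rows, counts = [], {}
    for i, name in enumerate(CELL_CLASSES):
        tp = int(((pred == i) & (true == i)).sum())
        fp = int(((pred == i) & (true != i)).sum())
        fn = int(((pred != i) & (true == i)).sum())
        tn = total - tp - fp - fn
        counts[name] = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, total=total)
        rows.append(dict(
            cell_class=name,
            precision=tp / (tp + fp) if tp + fp else np.nan,
            recall=tp / (tp + fn) if tp + fn else np.nan,
            accuracy=(tp + tn) / total))
    return pd.DataFrame(rows).set_index("cell_class"), counts
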