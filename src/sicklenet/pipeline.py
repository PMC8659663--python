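"""End-to-end channel analysis and count-agreement evaluation.

Runs the full tandem workflow on a whole channel image — tile, segment,
stitch, extract, classify — and produces per-channel counts of deformable,
non-deformable and rejected non-sRBC objects. Agreement between two count
series (e.g. automated vs manual) is summarized with an R^2 measured about
the identity line y = x (the perfect-agreement line), so R^2 = 1 means the
counts coincide and values can go negative for predictions worse than the
reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import channel as ch
from . import classification as clf
from . import extraction as ex
from . import segmentation as seg


@dataclass
class PipelineConfig:
    grid: ch.GridSpec = field(default_factory=lambda: ch.GridSpec(100, 35))
    network_input_size: int = 128
    min_cluster_size: int = 60
    connectivity: int = 8
    crop_size: int = 32
    clf_config: clf.ClfModelConfig = field(default_factory=clf.ClfModelConfig)
    strict_grid: bool = True


@dataclass
class ChannelCountReport:
    channel_id: str
    n_total_srbc: int
    n_deformable: int
    n_nondeformable: int
    n_non_srbc_rejected: int


@dataclass
class AgreementResult:
    reference: np.ndarray
    predicted: np.ndarray
    r2: float


class PipelineStageError(RuntimeError):
    """Raised with the failing stage's name; partial artifacts survive."""


def run_pipeline(image, seg_models, clf_models, config: PipelineConfig,
                 mask_override: np.ndarray | None = None
                 ) -> tuple[ChannelCountReport, dict]:
    """Tile -> segment -> stitch -> extract -> classify -> count.

    ``image`` is a WholeChannelImage or bare array. ``mask_override``
    substitutes a known-good whole-channel mask for the segmentation stage
    (ground-truth bypass for validation). Deterministic given models and
    config. Returns the count report and an artifact dict (whole-channel
    mask, crops, per-crop probability manifest).
    """
    if not isinstance(image, ch.WholeChannelImage):
        image = ch.WholeChannelImage(pixels=np.asarray(image), source_id="")
    artifacts: dict = {}
    stage = "tile"
    try:
        if mask_override is not None:
            mask = np.asarray(mask_override)
        else:
            tiles = ch.tile_channel(image, config.grid,
                                    strict=config.strict_grid)
            stage = "segment"
            th, tw = tiles[0].pixels.shape[:2]
            x = np.stack([ch.preprocess_tile(t, config.network_input_size)
                          for t in tiles])
            probs = seg.segment_tiles(seg_models, x)
            labels = probs.argmax(axis=-1).astype(np.uint8)
            stage = "stitch"
            native = [ch.resize_mask_nearest(lbl, (th, tw)) for lbl in labels]
            mask = ch.stitch_masks(native, config.grid)
        artifacts["mask"] = mask
        stage = "extract"
        binary = ex.filter_clusters(ex.binarize_mask(mask),
                                    min_size=config.min_cluster_size,
                                    connectivity=config.connectivity)
        crops = ex.extract_crops(image, binary, size=config.crop_size,
                                 connectivity=config.connectivity)
        artifacts["crops"] = crops
        stage = "classify"
        if crops:
            probs = clf.classify_crops(clf_models,
                                       [c.pixels for c in crops],
                                       config.clf_config)
            labels = clf.predict_labels(probs)
        else:
            probs = np.zeros((0, 3), dtype=np.float32)
            labels = np.zeros(0, dtype=int)
        manifest = pd.DataFrame(dict(
            crop_id=np.arange(len(crops)),
            row=[c.centroid[0] for c in crops],
            col=[c.centroid[1] for c in crops],
            p_deformable=probs[:, 0], p_nondeformable=probs[:, 1],
            p_non_srbc=probs[:, 2],
            label=[clf.CELL_CLASSES[l] for l in labels]))
        artifacts["crop_manifest"] = manifest
    except Exception as err:
        raise PipelineStageError(f"stage '{stage}' failed: {err}") from err
    n_def = int((labels == 0).sum())
    n_ndef = int((labels == 1).sum())
    report = ChannelCountReport(
        channel_id=image.source_id,
        n_total_srbc=n_def + n_ndef,
        n_deformable=n_def,
        n_nondeformable=n_ndef,
        n_non_srbc_rejected=int((labels == 2).sum()))
    return report, artifacts


def agreement_r2(reference, predicted) -> AgreementResult:
    """R^2 about the identity line: 1 - SS_res / SS_tot.

    Residuals are measured against y = x; SS_tot is the reference variance
    about its mean. Zero reference variance makes the statistic undefined
    (NaN). Requires >= 2 paired channels.
    """
    r = np.asarray(reference, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if r.shape != p.shape or r.size < 2:
        raise ValueError("need >= 2 paired counts of equal length")
    ss_res = float(((p - r) ** 2).sum())
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return AgreementResult(reference=r, predicted=p, r2=r2)


def repeat_variance(counts) -> pd.DataFrame:
    """Per-channel standard deviation over repeated runs (ddof = 1).

    ``counts`` maps channel id -> sequence of repeated counts (>= 2 each).
    Deterministic pipeline repeats must yield zero variance; stochastic
    repeats report their true spread.
    """
    rows = []
    for channel_id, values in counts.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"channel {channel_id!r}: need >= 2 repeats")
        rows.append(dict(channel_id=channel_id, n_repeats=v.size,
                         mean=float(v.mean()), sd=float(v.std(ddof=1))))
    return pd.DataFrame(rows)
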