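"""Turn a three-class segmentation mask into single-cell 32x32 crops.

The adhered-sRBC channel of the mask is binarized, connected clusters
smaller than a minimum size (default 60 pixels, calibrated to 10x
magnification where one cell covers well over 60 pixels) are deleted as
debris, and a 32x32 box centered at each surviving cluster centroid is cut
from the intensity image. Boxes that straddle the channel border are
reflect-padded so a crop is always exactly 32x32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import PixelClass

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int),
    8: np.ones((3, 3), dtype=int),
}


@dataclass
class Cluster:
    pixels: np.ndarray             # (n, 2) row/col coordinates
    size: int
    centroid: tuple[float, float]  # real-valued (row, col)


@dataclass
class CellCrop:
    pixels: np.ndarray             # always exactly (size, size)
    source_channel: str
    centroid: tuple[float, float]  # in channel coordinates


def binarize_mask(mask: np.ndarray) -> np.ndarray:
    """1 exactly where the label is adhered sRBC, 0 elsewhere. Idempotent."""
    values = np.unique(mask)
    if not np.isin(values, [0, 1, 2]).all():
        raise ValueError(f"unknown label values: {values}")
    return (mask == PixelClass.ADHERED_SRBC).astype(np.uint8)


def find_clusters(binary: np.ndarray, connectivity: int = 8) -> list[Cluster]:
    """Connected clusters of 1-pixels under the configured connectivity."""
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    clusters = []
    for comp in range(1, n + 1):
        rr, cc = np.nonzero(labeled == comp)
        clusters.append(Cluster(pixels=np.stack([rr, cc], axis=1),
                                size=len(rr),
                                centroid=(float(rr.mean()), float(cc.mean()))))
    return clusters


def filter_clusters(binary: np.ndarray, min_size: int = 60,
                    connectivity: int = 8) -> np.ndarray:
    """Delete connected clusters smaller than ``min_size`` pixels.

    Clusters of exactly ``min_size`` pixels are retained. Idempotent, and
    monotone in ``min_size``: raising the threshold never adds clusters.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return binary.astype(np.uint8)
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labeled].astype(np.uint8)


def crop_window(image: np.ndarray, centroid: tuple[float, float],
                size: int = 32) -> np.ndarray:
    """Cut the half-open ``[r-16, r+16) x [c-16, c+16)`` window.

    The centroid is rounded half-up to an integer anchor; windows that
    reach past the border are reflect-padded to keep intensity statistics.
    """
    half = size // 2
    r = int(np.floor(centroid[0] + 0.5))
    c = int(np.floor(centroid[1] + 0.5))
    h, w = image.shape[:2]
    pad_top = max(0, half - r)
    pad_left = max(0, half - c)
    pad_bottom = max(0, r + half - h)
    pad_right = max(0, c + half - w)
    window = image[max(0, r - half):min(h, r + half),
                   max(0, c - half):min(w, c + half)]
    if pad_top or pad_left or pad_bottom or pad_right:
        window = np.pad(window, ((pad_top, pad_bottom), (pad_left, pad_right)),
                        mode="reflect")
    return np.ascontiguousarray(window)


def extract_crops(channel, mask: np.ndarray, size: int = 32,
                  connectivity: int = 8, source_id: str | None = None
                  ) -> list[CellCrop]:
    """One 32x32 crop per surviving cluster, centered at its centroid.

    ``channel`` is a WholeChannelImage or a bare intensity array of the
    same dimensions as the (already filtered) binary mask.
    """
    from .channel import WholeChannelImage

    if isinstance(channel, WholeChannelImage):
        pixels, src = channel.pixels, channel.source_id
    else:
        pixels, src = channel, source_id or ""
    if pixels.shape[:2] != mask.shape:
        raise ValueError(
            f"channel {pixels.shape[:2]} and mask {mask.shape} dimensions differ")
    return [CellCrop(pixels=crop_window(pixels, cl.centroid, size),
                     source_channel=src, centroid=cl.centroid)
            for cl in find_clusters(mask, connectivity)]
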