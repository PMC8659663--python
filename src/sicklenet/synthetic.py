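"""Synthetic phase-contrast-like channel scenes with exact ground truth.

Real adhesion-assay channels are imaged in phase contrast at 10x: adhered
sickle cells appear as dark bodies on a bright, unevenly lit background,
partially sickled ("deformable") cells keep a central dimple of reduced
contrast, highly sickled ("non-deformable") cells are elongated spindles
with sharp endpoints and no dimple, and the non-functionally-adhered class
collects out-of-focus blurred objects with halo rings, smooth round
WBC-like discs, and small debris. This module renders a parametric proxy of
each of those appearances together with the per-pixel three-class label
mask (0 background, 1 adhered sRBC, 2 non-functionally adhered / other), so
every downstream stage can be tested against known truth.

Rendering is fully deterministic given the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

OBJECT_CLASSES = (
    "deformable_srbc",
    "nondeformable_srbc",
    "wbc",
    "out_of_focus",
    "debris",
)
ADHERED_CLASSES = ("deformable_srbc", "nondeformable_srbc")

# default contrast (intensity drop of a cell body against background)
CELL_CONTRAST = 0.25

DEFAULT_CLASS_PROBS = {
    "deformable_srbc": 0.35,
    "nondeformable_srbc": 0.25,
    "wbc": 0.15,
    "out_of_focus": 0.15,
    "debris": 0.10,
}


class SceneOverlapError(RuntimeError):
    """Raised when an adhered cell cannot be placed without overlap."""


@dataclass
class CellSpec:
    """Geometry of one rendered object.

    ``major_axis``/``minor_axis`` are full axis lengths in pixels;
    ``orientation`` is degrees in [-90, 90); ``dimple_depth`` (deformable
    cells only) is the fraction of the cell contrast recovered at the
    center; ``sharpness`` (non-deformable only) controls endpoint taper.
    """

    object_class: str
    centroid: tuple[float, float]
    orientation: float = 0.0
    major_axis: float = 14.0
    minor_axis: float = 11.0
    dimple_depth: float = 0.0
    sharpness: float = 0.0

    def validate(self, height: int | None = None, width: int | None = None) -> None:
        if self.object_class not in OBJECT_CLASSES:
            raise ValueError(f"unknown object class {self.object_class!r}")
        if not (0 < self.minor_axis <= self.major_axis):
            raise ValueError("require 0 < minor_axis <= major_axis")
        if (self.dimple_depth > 0) != (self.object_class == "deformable_srbc"):
            raise ValueError("dimple_depth > 0 iff deformable_srbc")
        if height is not None:
            r, c = self.centroid
            if not (0 <= r < height and 0 <= c < width):
                raise ValueError(f"centroid {self.centroid} outside scene bounds")


@dataclass
class SceneSpec:
    height: int = 256
    width: int = 256
    cells: list[CellSpec] = field(default_factory=list)
    background_level: float = 0.60
    background_gradient: tuple[float, float] = (0.05, 0.08)
    noise_sigma: float = 0.02
    blur_sigma_outoffocus: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for cell in self.cells:
            cell.validate(self.height, self.width)


@dataclass
class RenderedScene:
    image: np.ndarray          # (H, W) float32 intensities in [0, 1]
    mask: np.ndarray           # (H, W) uint8 labels {0, 1, 2}
    objects: pd.DataFrame      # one row per rendered object


def _footprint_and_paint(cell: CellSpec, height: int, width: int,
                         blur_sigma: float) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Rasterize one object in a local window.

    Returns (footprint bool array, intensity delta array, window slices).
    """
    r0, c0 = cell.centroid
    a = cell.major_axis / 2.0
    b = cell.minor_axis / 2.0
    pad = int(np.ceil(max(a, b) + 3 * blur_sigma + 4))
    rlo = max(0, int(np.floor(r0)) - pad)
    rhi = min(height, int(np.ceil(r0)) + pad + 1)
    clo = max(0, int(np.floor(c0)) - pad)
    chi = min(width, int(np.ceil(c0)) + pad + 1)
    rows = np.arange(rlo, rhi)[:, None] - r0
    cols = np.arange(clo, chi)[None, :] - c0
    theta = np.deg2rad(cell.orientation)
    # u along the major axis, v along the minor axis
    u = rows * np.sin(theta) + cols * np.cos(theta)
    v = -rows * np.cos(theta) + cols * np.sin(theta)

    delta = np.zeros(u.shape, dtype=np.float32)
    if cell.object_class == "nondeformable_srbc":
        s = max(cell.sharpness, 1.0)
        t = np.clip(np.abs(u) / a, 0.0, 1.0)
        halfwidth = b * (1.0 - t ** 2) ** s
        alpha = np.clip(halfwidth - np.abs(v), 0.0, 1.0)
        alpha[np.abs(u) >= a] = 0.0
        delta -= CELL_CONTRAST * alpha
        footprint = alpha > 0.5
    else:
        rnorm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        edge = min(a, b)
        alpha = np.clip((1.0 - rnorm) * edge, 0.0, 1.0)
        footprint = alpha > 0.5
        if cell.object_class == "deformable_srbc":
            delta -= CELL_CONTRAST * alpha
            dimple = np.clip((0.45 - rnorm) * edge, 0.0, 1.0)
            delta += cell.dimple_depth * CELL_CONTRAST * dimple
        elif cell.object_class == "wbc":
            # phase-contrast WBCs: smooth bright body with a darker rim
            delta += 0.6 * CELL_CONTRAST * alpha
            rim = np.exp(-((rnorm - 1.0) * edge / 1.2) ** 2)
            delta -= 0.5 * CELL_CONTRAST * rim
        elif cell.object_class == "debris":
            delta -= 1.2 * CELL_CONTRAST * alpha
        elif cell.object_class == "out_of_focus":
            # defocused body plus a bright diffraction halo
            body = -0.8 * CELL_CONTRAST * alpha
            body = ndimage.gaussian_filter(body, blur_sigma)
            ring = np.exp(-((rnorm - 1.3) * edge / 1.8) ** 2)
            delta += (body + 0.6 * CELL_CONTRAST * ring).astype(np.float32)
    return footprint, delta, (slice(rlo, rhi), slice(clo, chi))


def render_scene(spec: SceneSpec, max_relocations: int = 100) -> RenderedScene:
    """Render a scene; adhered footprints that collide are relocated.

    Relocation draws replacement centroids from the scene's own generator,
    so the whole render stays deterministic under the seed. If an adhered
    cell still overlaps after ``max_relocations`` draws a
    :class:`SceneOverlapError` naming the spec is raised.
    """
    spec.validate()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    image = np.full((h, w), spec.background_level, dtype=np.float32)
    gr, gc = spec.background_gradient
    image += gr * (np.arange(h)[:, None] - h / 2) / max(h, 1)
    image += gc * (np.arange(w)[None, :] - w / 2) / max(w, 1)
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, (h, w)).astype(np.float32)

    mask = np.zeros((h, w), dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    rows = []
    for idx, cell in enumerate(spec.cells):
        placed = cell
        for attempt in range(max_relocations + 1):
            fp, delta, window = _footprint_and_paint(
                placed, h, w, spec.blur_sigma_outoffocus)
            # a 2-pixel guard band keeps neighboring footprints from
            # touching, so connected-component counts stay unambiguous
            fp_guard = ndimage.binary_dilation(fp, iterations=2)
            if not (occupied[window] & fp_guard).any():
                break
            margin = placed.major_axis / 2 + 2
            placed = replace(placed, centroid=(
                float(rng.uniform(margin, h - margin)),
                float(rng.uniform(margin, w - margin))))
        else:
            raise SceneOverlapError(
                f"could not place cell #{idx} ({cell.object_class}) without "
                f"overlap after {max_relocations} relocations")
        image[window] += delta
        occupied[window] |= fp_guard
        label = 1 if placed.object_class in ADHERED_CLASSES else 2
        mask[window][fp] = label
        rows.append(dict(object_id=idx, object_class=placed.object_class,
                         row=placed.centroid[0], col=placed.centroid[1],
                         major=placed.major_axis, minor=placed.minor_axis,
                         orientation=placed.orientation,
                         dimple_depth=placed.dimple_depth,
                         sharpness=placed.sharpness,
                         area_px=int(fp.sum())))

    np.clip(image, 0.0, 1.0, out=image)
    columns = ["object_id", "object_class", "row", "col", "major", "minor",
               "orientation", "dimple_depth", "sharpness", "area_px"]
    objects = pd.DataFrame(rows, columns=columns)
    return RenderedScene(image=image, mask=mask, objects=objects)


def dimple_statistic(image: np.ndarray, cell: CellSpec) -> float:
    """Mean intensity of the central disc minus the surrounding annulus.

    Measured in normalized elliptical coordinates of the cell: the center is
    rnorm < 0.35, the annulus 0.55 < rnorm < 0.85. For a rendered deformable
    cell this is close to ``dimple_depth * CELL_CONTRAST``; for spindles it
    is close to zero.
    """
    h, w = image.shape
    a, b = cell.major_axis / 2.0, cell.minor_axis / 2.0
    r0, c0 = cell.centroid
    rows = np.arange(h)[:, None] - r0
    cols = np.arange(w)[None, :] - c0
    theta = np.deg2rad(cell.orientation)
    u = rows * np.sin(theta) + cols * np.cos(theta)
    v = -rows * np.cos(theta) + cols * np.sin(theta)
    rnorm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    center = image[rnorm < 0.35]
    annulus = image[(rnorm > 0.55) & (rnorm < 0.85)]
    return float(center.mean() - annulus.mean())


def sample_cell_spec(rng: np.random.Generator, object_class: str,
                     height: int, width: int) -> CellSpec:
    """Draw one cell with class-typical geometry at 10x magnification."""
    orientation = float(rng.uniform(-90.0, 90.0))
    if object_class == "deformable_srbc":
        major = float(rng.uniform(13.0, 17.0))
        minor = float(rng.uniform(0.75, 0.95)) * major
        extra = dict(dimple_depth=float(rng.uniform(0.5, 0.8)))
    elif object_class == "nondeformable_srbc":
        major = float(rng.uniform(20.0, 26.0))
        minor = float(rng.uniform(6.5, 9.0))
        extra = dict(sharpness=float(rng.uniform(1.1, 1.6)))
    elif object_class == "wbc":
        major = float(rng.uniform(14.0, 18.0))
        minor = major
        extra = {}
    elif object_class == "out_of_focus":
        major = float(rng.uniform(12.0, 18.0))
        minor = float(rng.uniform(0.85, 1.0)) * major
        extra = {}
    else:  # debris
        major = float(rng.uniform(3.0, 6.0))
        minor = float(rng.uniform(0.6, 1.0)) * major
        extra = {}
    margin = major / 2 + 6
    centroid = (float(rng.uniform(margin, height - margin)),
                float(rng.uniform(margin, width - margin)))
    return CellSpec(object_class=object_class, centroid=centroid,
                    orientation=orientation, major_axis=major,
                    minor_axis=minor, **extra)


def sample_scene_spec(rng: np.random.Generator, height: int = 256,
                      width: int = 256, n_cells: tuple[int, int] = (4, 9),
                      class_probs: dict[str, float] | None = None,
                      noise_sigma: float = 0.02) -> SceneSpec:
    """Draw a random scene specification from the configured distribution."""
    probs = dict(DEFAULT_CLASS_PROBS if class_probs is None else class_probs)
    classes = list(probs)
    p = np.asarray([probs[c] for c in classes], dtype=float)
    p /= p.sum()
    n = int(rng.integers(n_cells[0], n_cells[1] + 1))
    cells = [sample_cell_spec(rng, classes[i], height, width)
             for i in rng.choice(len(classes), size=n, p=p)]
    return SceneSpec(height=height, width=width, cells=cells,
                     background_level=float(rng.uniform(0.5, 0.7)),
                     background_gradient=(float(rng.uniform(-0.08, 0.08)),
                                          float(rng.uniform(-0.08, 0.08))),
                     noise_sigma=noise_sigma,
                     seed=int(rng.integers(0, 2 ** 31 - 1)))


def make_dataset(n_scenes: int, spec_distribution: dict | None = None,
                 seed: int = 0, out_dir: str | Path | None = None
                 ) -> tuple[list[RenderedScene], pd.DataFrame]:
    """Render ``n_scenes`` random scenes and build a per-object manifest.

    The manifest has columns scene_id, object_id, class, row, col, major,
    minor, orientation. With ``out_dir`` set, scene/mask PNGs (8-bit and
    indexed respectively) and manifest.csv are written there.
    """
    if n_scenes < 0:
        raise ValueError("n_scenes must be >= 0")
    dist = spec_distribution or {}
    rng = np.random.default_rng(seed)
    scenes: list[RenderedScene] = []
    records = []
    for i in range(n_scenes):
        spec = sample_scene_spec(
            rng,
            height=dist.get("height", 256), width=dist.get("width", 256),
            n_cells=dist.get("n_cells", (4, 9)),
            class_probs=dist.get("class_probs"),
            noise_sigma=dist.get("noise_sigma", 0.02))
        scene = render_scene(spec)
        scenes.append(scene)
        for _, row in scene.objects.iterrows():
            records.append(dict(scene_id=i, object_id=int(row.object_id),
                                **{"class": row.object_class},
                                row=row.row, col=row.col, major=row.major,
                                minor=row.minor, orientation=row.orientation))
    manifest = pd.DataFrame(
        records, columns=["scene_id", "object_id", "class", "row", "col",
                          "major", "minor", "orientation"])
    if out_dir is not None:
        import imageio.v3 as iio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, scene in enumerate(scenes):
            iio.imwrite(out / f"scene_{i:04d}.png",
                        (scene.image * 255).round().astype(np.uint8))
            iio.imwrite(out / f"mask_{i:04d}.png", scene.mask)
        manifest.to_csv(out / "manifest.csv", index=False)
    return scenes, manifest


def crop_ground_truth(scene: RenderedScene, crop_size: int = 32):
    """One labeled crop per adhered cell, centered on the mask centroid.

    Returns a list of ``(CellCrop, label)`` pairs where ``label`` is the
    subtype from the object table. Objects of the non-functional/other
    class (mask label 2) are excluded.
    """
    from .extraction import CellCrop, crop_window

    labeled, n = ndimage.label(scene.mask == 1,
                               structure=np.ones((3, 3), dtype=int))
    adhered = scene.objects[scene.objects.object_class.isin(ADHERED_CLASSES)]
    out = []
    for comp in range(1, n + 1):
        rr, cc = np.nonzero(labeled == comp)
        centroid = (float(rr.mean()), float(cc.mean()))
        d2 = (adhered.row - centroid[0]) ** 2 + (adhered.col - centroid[1]) ** 2
        label = str(adhered.loc[d2.idxmin(), "object_class"])
        crop = CellCrop(pixels=crop_window(scene.image, centroid, crop_size),
                        source_channel="synthetic", centroid=centroid)
        out.append((crop, label))
    return out


def make_crop_dataset(n_crops: int, seed: int = 0,
                      class_probs: dict[str, float] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Build a labeled 32x32 crop corpus for the subtype classifier.

    Crops are cut from rendered scenes at the true object centroids; the
    five scene object classes map onto the three classifier categories
    (wbc / out_of_focus / debris -> ``non_srbc``). Returns
    ``(crops (N, 32, 32) float32, labels (N,) str)``.
    """
    from .extraction import crop_window

    rng = np.random.default_rng(seed)
    crops, labels = [], []
    while len(crops) < n_crops:
        spec = sample_scene_spec(rng, height=192, width=192,
                                 class_probs=class_probs)
        scene = render_scene(spec)
        for _, row in scene.objects.iterrows():
            if len(crops) >= n_crops:
                break
            crops.append(crop_window(scene.image, (row.row, row.col), 32))
            if row.object_class in ADHERED_CLASSES:
                labels.append(row.object_class)
            else:
                labels.append("non_srbc")
    return np.stack(crops), np.asarray(labels)
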