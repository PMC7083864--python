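"""Synthetic fluorescence scenes with exact ground truth.

Scenes emulate GFAP-stained tissue at 20x / 1024x1024 scale: star-shaped
cells (bright isotropic soma plus several thin, curved, tapering
processes), string-like precursor objects (a single smooth curve of
near-constant width, no soma), Poisson photon noise and a small optical
blur.  Ground truth (label map, centroids, per-object class) is kept
noise-free, which makes every pipeline stage testable offline.

The process growth model (random-walk heading jitter, linear width taper)
is a package invention; its parameters live in :class:`SceneConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .segmentation import TrainingSet

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_star",
    "generate_string",
    "render_scene",
    "make_training_pairs",
]


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (512, 512)
    n_stars: int = 10
    n_strings: int = 3
    soma_radius_range: tuple[float, float] = (8.0, 12.0)
    n_processes_range: tuple[int, int] = (4, 7)
    process_length_range: tuple[float, float] = (50.0, 100.0)
    process_width_range: tuple[float, float] = (2.0, 5.0)
    mean_cell_area_target: float = 1500.0
    min_soma_separation: float = 60.0
    string_length_range: tuple[float, float] = (60.0, 120.0)
    string_width_range: tuple[float, float] = (2.0, 3.5)
    #: bright central varicosity of string objects; small enough to add no
    #: orientation peak but bright enough to trigger soma detection
    string_bulge_radius_range: tuple[float, float] = (5.5, 7.5)
    #: per-step heading jitter (radians) of the random-walk growth
    process_curvature: float = 0.03
    string_curvature: float = 0.01
    #: linear taper: tip width as a fraction of the root width
    taper_fraction: float = 0.4
    soma_intensity: float = 1.0
    process_intensity: float = 0.4
    background_intensity: float = 0.02
    photon_peak: float = 120.0
    blur_sigma: float = 1.0
    seed: int = 0
    placement_attempts: int = 1000

    def __post_init__(self) -> None:
        for name in ("soma_radius_range", "n_processes_range",
                     "process_length_range", "process_width_range",
                     "string_length_range", "string_width_range",
                     "string_bulge_radius_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.soma_radius_range[0] <= 0:
            raise ValueError("soma radius must be positive")
        if self.n_processes_range[0] < 3:
            raise ValueError("stars need at least 3 processes")
        if not (self.background_intensity < self.process_intensity
                <= self.soma_intensity):
            raise ValueError(
                "intensities must satisfy background < process <= soma"
            )
        if self.photon_peak <= 0:
            raise ValueError("photon_peak must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray
    #: blurred noise-free intensity in [0, 1] (denoising ground truth)
    clean: np.ndarray
    label_map: np.ndarray
    centroids: list[tuple[float, float]]
    classes: list[str]
    config: SceneConfig = field(repr=False)

    @property
    def n_objects(self) -> int:
        return len(self.centroids)


def _paint_curve(mask: np.ndarray, start: tuple[float, float], heading: float,
                 length: float, width0: float, width1: float,
                 curvature: float, rng: np.random.Generator) -> None:
    """Grow a unit-step random-walk curve, painting tapering disks."""
    r, c = start
    h = heading
    n_steps = max(int(round(length)), 1)
    for step in range(n_steps):
        t = step / n_steps
        w = width0 + (width1 - width0) * t
        # radius floor 0.75 > sqrt(2)/2 guarantees every step paints pixels
        rr, cc = draw_disk((r, c), max(w / 2.0, 0.75), shape=mask.shape)
        mask[rr, cc] = True
        h += rng.normal(0.0, curvature)
        r += np.sin(h)
        c += np.cos(h)
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            break


def generate_star(center: tuple[float, float], config: SceneConfig,
                  rng: np.random.Generator,
                  shape: tuple[int, int] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Render one star: returns (full mask, soma-only mask, centroid).

    The soma is a filled disk; processes grow outward from just inside the
    soma boundary at jittered, evenly spread base angles, so the object is
    a single 8-connected component.
    """
    shape = shape or config.image_size
    soma_r = rng.uniform(*config.soma_radius_range)
    mask = np.zeros(shape, dtype=bool)
    soma = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, soma_r, shape=shape)
    mask[rr, cc] = True
    soma[rr, cc] = True
    k = int(rng.integers(config.n_processes_range[0],
                         config.n_processes_range[1] + 1))
    base = rng.uniform(0.0, 2 * np.pi)
    jitter = (2 * np.pi / k) * 0.3
    for i in range(k):
        ang = base + 2 * np.pi * i / k + rng.uniform(-jitter, jitter)
        start = (center[0] + (soma_r - 1.0) * np.sin(ang),
                 center[1] + (soma_r - 1.0) * np.cos(ang))
        length = rng.uniform(*config.process_length_range)
        w0 = rng.uniform(*config.process_width_range)
        _paint_curve(mask, start, ang, length, w0,
                     w0 * config.taper_fraction, config.process_curvature, rng)
    return mask, soma, (float(center[0]), float(center[1]))


def generate_string(config: SceneConfig, rng: np.random.Generator,
                    center: tuple[float, float] | None = None,
                    shape: tuple[int, int] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Render one string-like object.

    A single smooth near-constant-width curve with a small bright central
    varicosity (returned separately as ``bulge``) but no soma and no arms.
    Returns (mask, bulge mask, centroid).
    """
    shape = shape or config.image_size
    if center is None:
        margin = config.string_length_range[1] / 2 + 5
        center = (rng.uniform(margin, shape[0] - margin),
                  rng.uniform(margin, shape[1] - margin))
    length = rng.uniform(*config.string_length_range)
    width = rng.uniform(*config.string_width_range)
    heading = rng.uniform(0.0, 2 * np.pi)
    mask = np.zeros(shape, dtype=bool)
    # grow both halves from the midpoint so `center` stays the centroid
    _paint_curve(mask, center, heading, length / 2, width, width,
                 config.string_curvature, rng)
    _paint_curve(mask, center, heading + np.pi, length / 2, width, width,
                 config.string_curvature, rng)
    bulge = np.zeros(shape, dtype=bool)
    bulge_r = rng.uniform(*config.string_bulge_radius_range)
    rr, cc = draw_disk(center, bulge_r, shape=shape)
    bulge[rr, cc] = True
    mask |= bulge
    return mask, bulge, (float(center[0]), float(center[1]))


def _place_centers(config: SceneConfig, rng: np.random.Generator,
                   n: int, margin: float) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    rows, cols = config.image_size
    for _ in range(n):
        for _attempt in range(config.placement_attempts):
            cand = (rng.uniform(margin, rows - margin),
                    rng.uniform(margin, cols - margin))
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1])
                   >= config.min_soma_separation for p in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place object {len(centers) + 1}/{n} with "
                f"min_soma_separation={config.min_soma_separation} within "
                f"{config.placement_attempts} attempts"
            )
    return centers


def render_scene(config: SceneConfig) -> SyntheticScene:
    """Compose, blur, Poisson-sample and renormalize a full scene."""
    rng = np.random.default_rng(config.seed)
    # keep somata clear of the border so coarse-scale responses are reliable
    margin = config.soma_radius_range[1] + 15
    centers = _place_centers(config, rng, config.n_stars + config.n_strings,
                             margin)

    label_map = np.zeros(config.image_size, dtype=np.int32)
    intensity = np.full(config.image_size, config.background_intensity)
    centroids: list[tuple[float, float]] = []
    classes: list[str] = []

    for i in range(config.n_stars):
        mask, soma, centroid = generate_star(centers[i], config, rng)
        label_map[mask] = i + 1
        intensity = np.maximum(intensity,
                               np.where(mask, config.process_intensity, 0.0))
        intensity = np.maximum(intensity,
                               np.where(soma, config.soma_intensity, 0.0))
        centroids.append(centroid)
        classes.append("star")

    for i in range(config.n_strings):
        mask, bulge, centroid = generate_string(
            config, rng, center=centers[config.n_stars + i])
        label_map[mask] = config.n_stars + i + 1
        intensity = np.maximum(intensity,
                               np.where(mask, config.process_intensity, 0.0))
        intensity = np.maximum(intensity,
                               np.where(bulge, config.soma_intensity, 0.0))
        centroids.append(centroid)
        classes.append("string")

    clean = ndimage.gaussian_filter(intensity, config.blur_sigma)
    counts = rng.poisson(clean * config.photon_peak).astype(float)
    # back to [0, 1] on the photon scale; over-shooting counts are clipped
    image = np.clip(counts / config.photon_peak, 0.0, 1.0)
    return SyntheticScene(image=image, clean=clean, label_map=label_map,
                          centroids=centroids, classes=classes, config=config)


def make_training_pairs(scene: SyntheticScene, patch_size: int = 128) -> TrainingSet:
    """One (image patch, binary mask) pair per star, centered on the
    ground-truth centroid; the mask keeps only that cell's label."""
    pairs = []
    for label, (centroid, cls) in enumerate(zip(scene.centroids, scene.classes),
                                            start=1):
        if cls != "star":
            continue
        top = int(round(centroid[0])) - patch_size // 2
        left = int(round(centroid[1])) - patch_size // 2
        img = _extract(scene.image, top, left, patch_size)
        mask = _extract((scene.label_map == label).astype(np.uint8),
                        top, left, patch_size)
        pairs.append((img, mask))
    return TrainingSet(patches=pairs)


def _extract(a: np.ndarray, top: int, left: int, size: int) -> np.ndarray:
    out = np.zeros((size, size), dtype=a.dtype)
    r0, r1 = max(top, 0), min(top + size, a.shape[0])
    c0, c1 = max(left, 0), min(left + size, a.shape[1])
    out[r0 - top:r1 - top, c0 - left:c1 - left] = a[r0:r1, c0:c1]
    return out
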