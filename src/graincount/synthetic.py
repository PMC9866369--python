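"""Synthetic dot-annotated scenes of grain-like blobs on textured backgrounds.

Real data for this problem are photographs of dairy-cattle droppings in
which every undigested cereal grain was marked with a dot at its center.
This module generates stand-in imagery with the same supervision
structure: a textured, unevenly lit background carrying a controllable
number of small bright elliptical blobs, each labeled by an exact dot at
its center. Everything is seeded and bit-for-bit reproducible, so the
whole counting pipeline can be exercised and tested without any
external download.

Coordinates are 0-based ``(row, col)`` with row increasing downward;
sub-pixel positions are allowed. CSV files with a ``row,col`` header are
the canonical annotation format; dots burned into images as colored
markers can be imported with :func:`extract_dots_from_marker_image`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from PIL import Image
from scipy import ndimage


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DotAnnotation:
    """An ordered list of (row, col) dots inside a (height, width) frame."""

    points: np.ndarray  # (n, 2) float64, possibly empty
    frame_shape: tuple[int, int]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        h, w = self.frame_shape
        if pts.size and (
            (pts[:, 0] < 0).any()
            or (pts[:, 0] >= h).any()
            or (pts[:, 1] < 0).any()
            or (pts[:, 1] >= w).any()
        ):
            raise ValueError(f"points must lie inside [0, {h}) x [0, {w})")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class AnnotatedImage:
    """Pixel grid in [0, 1] plus its dot annotation."""

    pixels: np.ndarray  # (h, w) or (h, w, 3) float
    annotation: DotAnnotation
    identifier: str = ""

    def __post_init__(self):
        if self.pixels.shape[:2] != tuple(self.annotation.frame_shape):
            raise ValueError(
                f"annotation frame_shape {self.annotation.frame_shape} does not match "
                f"pixel grid {self.pixels.shape[:2]}"
            )

    @property
    def count(self) -> int:
        return len(self.annotation)


def _check_range(name: str, rng_pair, lo_ok=None) -> None:
    lo, hi = rng_pair
    if not (lo <= hi):
        raise ValueError(f"{name}: expected min <= max, got {rng_pair}")
    if lo_ok is not None and lo < lo_ok:
        raise ValueError(f"{name}: lower bound must be >= {lo_ok}, got {lo}")


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the synthetic scene generator.

    Attributes
    ----------
    image_height, image_width:
        Frame size in pixels (default 256 x 256, the working resolution
        of the counting pipeline).
    count_range:
        Inclusive interval the per-image grain count is drawn from.
    grain_axis_range:
        Min/max semi-axes of the elliptical blobs, pixels.
    grain_intensity_range:
        Relative brightness lift of a grain over the background, in [0, 1].
    background_level_range:
        Base gray level interval of the background, in [0, 1].
    illumination_gradient_max:
        Maximum relative linear shading across the frame (0 = flat light).
    noise_sd:
        Standard deviation of additive per-pixel Gaussian noise.
    min_center_margin:
        Minimum distance of any dot from every image border, pixels.
    min_center_separation:
        Minimum pairwise distance between dots (0 = overlap freely).
    seed:
        Master seed; per-scene seeds are derived as ``seed + scene index``.
    """

    image_height: int = 256
    image_width: int = 256
    count_range: tuple[int, int] = (5, 60)
    grain_axis_range: tuple[float, float] = (2.0, 5.0)
    grain_intensity_range: tuple[float, float] = (0.25, 0.6)
    background_level_range: tuple[float, float] = (0.2, 0.5)
    illumination_gradient_max: float = 0.3
    noise_sd: float = 0.02
    min_center_margin: float = 8.0
    min_center_separation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError(
                f"image_height/image_width must be >= 1, got "
                f"{self.image_height}x{self.image_width}"
            )
        _check_range("count_range", self.count_range, lo_ok=0)
        _check_range("grain_axis_range", self.grain_axis_range, lo_ok=0.5)
        _check_range("grain_intensity_range", self.grain_intensity_range, lo_ok=0.0)
        _check_range("background_level_range", self.background_level_range, lo_ok=0.0)
        if self.grain_intensity_range[1] > 1.0:
            raise ValueError("grain_intensity_range: upper bound must be <= 1")
        if self.background_level_range[1] > 1.0:
            raise ValueError("background_level_range: upper bound must be <= 1")
        if self.illumination_gradient_max < 0:
            raise ValueError(
                f"illumination_gradient_max must be >= 0, got {self.illumination_gradient_max}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 <= self.min_center_margin < min(self.image_height, self.image_width) / 2):
            raise ValueError(
                f"min_center_margin must be in [0, {min(self.image_height, self.image_width) / 2}), "
                f"got {self.min_center_margin}"
            )
        if self.min_center_separation < 0:
            raise ValueError(
                f"min_center_separation must be >= 0, got {self.min_center_separation}"
            )


# ---------------------------------------------------------------------------
# scene generation


def _draw_centers(config: SceneConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform centers within margins, optionally with minimum separation."""
    m = config.min_center_margin
    lo = np.array([m, m])
    hi = np.array([config.image_height - 1 - m, config.image_width - 1 - m])
    if config.min_center_separation <= 0:
        return lo + (hi - lo) * rng.random((k, 2))
    centers: list[np.ndarray] = []
    for _ in range(10_000):
        c = lo + (hi - lo) * rng.random(2)
        if all(np.hypot(*(c - p)) >= config.min_center_separation for p in centers):
            centers.append(c)
            if len(centers) == k:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {k} centers with min_center_separation="
        f"{config.min_center_separation} in a "
        f"{config.image_height}x{config.image_width} frame"
    )


def _render_grain(img: np.ndarray, center, a: float, b: float, theta: float, lift: float):
    """Add an anti-aliased filled ellipse; edge softness ~1 px."""
    r0, c0 = center
    rad = int(np.ceil(max(a, b))) + 2
    rlo, rhi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # (1 - d) * min(a, b) approximates the signed distance to the boundary
    alpha = np.clip(0.5 + (1.0 - d) * min(a, b), 0.0, 1.0)
    img[rlo:rhi, clo:chi] += lift * alpha


def generate_scene(config: SceneConfig, scene_seed: int) -> AnnotatedImage:
    """Render one seeded scene: background, illumination, grains, noise.

    The grain count is drawn uniformly from ``config.count_range``; every
    dot sits at the exact (sub-pixel) center of a rendered blob, at least
    ``min_center_margin`` pixels from every border. Identical
    ``(config, scene_seed)`` pairs reproduce the image bit for bit.
    """
    rng = np.random.default_rng(scene_seed)
    h, w = config.image_height, config.image_width

    base = rng.uniform(*config.background_level_range)
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    tmax = np.abs(texture).max()
    img = base * (1.0 + 0.15 * texture / tmax) if tmax > 0 else np.full((h, w), base)

    phi = rng.uniform(0.0, 2.0 * np.pi)
    strength = rng.uniform(0.0, config.illumination_gradient_max)
    rr, cc = np.mgrid[0:h, 0:w]
    proj = (rr * np.cos(phi) + cc * np.sin(phi)) / max(h, w)
    img = img * (1.0 + strength * (proj - proj.mean()))

    k = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
    centers = _draw_centers(config, k, rng) if k else np.empty((0, 2))
    for center in centers:
        a = rng.uniform(*config.grain_axis_range)
        b = rng.uniform(*config.grain_axis_range)
        theta = rng.uniform(0.0, np.pi)
        lift = rng.uniform(*config.grain_intensity_range)
        _render_grain(img, center, a, b, theta, lift)

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    return AnnotatedImage(
        pixels=img,
        annotation=DotAnnotation(points=centers, frame_shape=(h, w)),
        identifier=f"scene_{scene_seed}",
    )


# ---------------------------------------------------------------------------
# annotation and dataset I/O


def write_annotation_csv(annotation: DotAnnotation, path) -> None:
    """Write dots as CSV with header ``row,col`` at 6-decimal precision."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        for r, c in annotation.points:
            writer.writerow([f"{r:.6f}", f"{c:.6f}"])


def read_annotation_csv(path, frame_shape: tuple[int, int]) -> DotAnnotation:
    """Read a ``row,col`` CSV back into a :class:`DotAnnotation`."""
    pts: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is not None and [h.strip() for h in header] != ["row", "col"]:
            raise ValueError(f"{path}: expected header 'row,col', got {header}")
        for row in reader:
            if row:
                pts.append((float(row[0]), float(row[1])))
    return DotAnnotation(points=np.array(pts, dtype=np.float64).reshape(-1, 2),
                         frame_shape=frame_shape)


def save_image_png(pixels: np.ndarray, path) -> None:
    """Save a [0,1] float grid as an 8-bit (grayscale or RGB) PNG."""
    arr = np.clip(np.rint(np.asarray(pixels) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


def load_image_png(path) -> np.ndarray:
    """Load a PNG into a [0,1] float64 grid ((h, w) or (h, w, 3))."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def generate_dataset(config: SceneConfig, n_images: int, out_dir) -> list[dict]:
    """Write ``n_images`` seeded scenes (PNG + CSV each) plus a JSON manifest.

    Scene *i* uses seed ``config.seed + i``, so a dataset is fully
    reproducible from ``(config, n_images)``. Returns the manifest: one
    record ``{identifier, image_path, annotation_path, count}`` per scene.
    """
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    for i in range(n_images):
        scene = generate_scene(config, config.seed + i)
        ident = f"scene_{i:04d}"
        img_path = out / f"{ident}.png"
        ann_path = out / f"{ident}.csv"
        save_image_png(scene.pixels, img_path)
        write_annotation_csv(scene.annotation, ann_path)
        manifest.append(
            {
                "identifier": ident,
                "image_path": img_path.name,
                "annotation_path": ann_path.name,
                "count": scene.count,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest


def load_dataset(manifest_path) -> list[AnnotatedImage]:
    """Load a dataset written by :func:`generate_dataset`.

    ``manifest_path`` may be the manifest file or its directory; image and
    annotation paths in the manifest are resolved relative to it.
    """
    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.json"
    root = mpath.parent
    with open(mpath) as fh:
        manifest = json.load(fh)
    samples: list[AnnotatedImage] = []
    for rec in manifest:
        pixels = load_image_png(root / rec["image_path"])
        ann = read_annotation_csv(root / rec["annotation_path"], pixels.shape[:2])
        samples.append(AnnotatedImage(pixels=pixels, annotation=ann,
                                      identifier=rec["identifier"]))
    return samples


def extract_dots_from_marker_image(
    marker_pixels: np.ndarray,
    marker_color: tuple[int, int, int] = (255, 0, 0),
    tolerance: int = 10,
) -> DotAnnotation:
    """Recover dots from an image where instances are marked with color dots.

    Pixels within ``tolerance`` of ``marker_color`` in every channel are
    grouped into 8-connected components; each component contributes one dot
    at its centroid, in row-major order of component discovery. An image
    with no matching pixels yields an empty annotation.
    """
    arr = np.asarray(marker_pixels)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"marker image must be RGB, got shape {arr.shape}")
    diff = np.abs(arr[:, :, :3].astype(np.int64) - np.asarray(marker_color, dtype=np.int64))
    mask = (diff <= tolerance).all(axis=-1)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return DotAnnotation(points=np.empty((0, 2)), frame_shape=arr.shape[:2])
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    return DotAnnotation(points=np.array(centroids, dtype=np.float64),
                         frame_shape=arr.shape[:2])
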