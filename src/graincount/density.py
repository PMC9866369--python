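"""Gaussian density-map targets and counting by integration.

Each annotated dot is replaced by a truncated isotropic Gaussian kernel;
the superposition of those kernels is the density surface D(x) the
networks regress. Summing (integrating) D over the frame — or over any
window — recovers the (expected) object count there, which is the whole
point of counting by density regression: no detection, no localization.

Two kernel normalizations are supported. ``unit_integral`` scales the
truncated kernel to sum to exactly 1, so one dot contributes one unit of
mass and counts are plain sums; it is the default for training targets.
``unit_peak`` scales the kernel so its central value is exactly 1 —
the form in which such kernels are often written down — and
:func:`count_from_density` then divides by the kernel's discrete mass so
an isolated interior dot still counts as 1.0.

Dots are snapped to the nearest pixel before kernel placement, and
kernels are truncated (not renormalized) at the frame border, so a dot
closer than ``truncation_radius`` to a border loses a little mass; see
``count_from_density`` notes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import DotAnnotation

NORMALIZATIONS = ("unit_integral", "unit_peak")


@dataclass(frozen=True)
class KernelSpec:
    """Isotropic Gaussian kernel: spread, support and normalization.

    ``sigma`` is the Gaussian standard deviation in pixels;
    ``truncation_radius`` the half-width of the square support, so the
    kernel grid is (2r+1) x (2r+1). A radius of at least 3–4 sigma keeps
    the truncated-away mass negligible; radius >= 1 is required.
    """

    sigma: float = 2.0
    truncation_radius: int = 8
    normalization: str = "unit_integral"

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if int(self.truncation_radius) != self.truncation_radius or self.truncation_radius < 1:
            raise ValueError(
                f"truncation_radius must be an integer >= 1, got {self.truncation_radius}"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )


@dataclass(frozen=True)
class DensityMap:
    """Non-negative density surface over a pixel grid.

    ``source_count`` records how many dots built the map (None if the map
    came from a network prediction rather than an annotation).
    """

    values: np.ndarray  # (h, w) float64, >= 0
    kernel: KernelSpec
    source_count: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError(f"density values must be 2-D, got shape {v.shape}")
        if (v < 0).any():
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def gaussian_kernel(spec: KernelSpec) -> np.ndarray:
    """The (2r+1) x (2r+1) truncated Gaussian grid for ``spec``.

    ``unit_integral`` grids sum to exactly 1; ``unit_peak`` grids have a
    central value of exactly 1. Either way the grid is symmetric under
    horizontal/vertical flips and transposition.
    """
    r = int(spec.truncation_radius)
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(ax ** 2) / (2.0 * spec.sigma ** 2))
    g = np.outer(g1, g1)
    if spec.normalization == "unit_integral":
        return g / g.sum()
    return g / g[r, r]  # center of exp(0) = 1 already, kept explicit


def kernel_mass(spec: KernelSpec) -> float:
    """Discrete mass one kernel deposits: 1 for unit_integral, sum(G) for unit_peak."""
    if spec.normalization == "unit_integral":
        return 1.0
    return float(gaussian_kernel(spec).sum())


def build_density_map(annotation: DotAnnotation, kernel: KernelSpec) -> DensityMap:
    """Superpose one kernel per dot (border-truncated) into a density map.

    Dots are rounded to the nearest pixel; an empty annotation yields an
    all-zero map with ``source_count`` 0.
    """
    h, w = annotation.frame_shape
    if h < 1 or w < 1:
        raise ValueError(f"frame_shape must be positive, got {annotation.frame_shape}")
    g = gaussian_kernel(kernel)
    r = int(kernel.truncation_radius)
    values = np.zeros((h, w), dtype=np.float64)
    for row, col in annotation.points:
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"dot ({row}, {col}) lies outside the {h}x{w} frame")
        # floor(x + 0.5): nearest pixel, ties toward +inf
        i, j = int(np.floor(row + 0.5)), int(np.floor(col + 0.5))
        rlo, rhi = max(0, i - r), min(h, i + r + 1)
        clo, chi = max(0, j - r), min(w, j + r + 1)
        values[rlo:rhi, clo:chi] += g[
            rlo - (i - r) : rhi - (i - r), clo - (j - r) : chi - (j - r)
        ]
    return DensityMap(values=values, kernel=kernel, source_count=len(annotation))


def count_from_density(density: DensityMap) -> float:
    """Estimate the object count as the integral of the density surface.

    For ``unit_integral`` kernels this is the plain sum of all entries;
    for ``unit_peak`` the sum is divided by the kernel's discrete mass so
    an isolated interior dot contributes 1.0. Dots whose kernels were
    clipped at the frame border contribute slightly less than 1.
    """
    return float(density.values.sum()) / kernel_mass(density.kernel)


def count_in_region(density: DensityMap, region: tuple[int, int, int, int]) -> float:
    """Mass-corrected density integral over ``region`` = (row_start,
    row_stop, col_start, col_stop), a half-open pixel window.

    Sums over any disjoint tiling of the frame add up to
    :func:`count_from_density` exactly (up to float round-off).
    """
    h, w = density.shape
    r0, r1, c0, c1 = region
    if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
        raise ValueError(f"region {region} out of bounds for {h}x{w} frame")
    return float(density.values[r0:r1, c0:c1].sum()) / kernel_mass(density.kernel)


def save_density_npy(density: DensityMap, path) -> None:
    """Export the surface as a single float32 array in NPY format."""
    np.save(path, density.values.astype(np.float32))


def load_density_npy(path, kernel: KernelSpec) -> DensityMap:
    """Load a surface saved by :func:`save_density_npy`."""
    return DensityMap(values=np.load(path).astype(np.float64), kernel=kernel)


def save_density_heatmap_png(density: DensityMap, path) -> None:
    """Export an 8-bit heat-map PNG (lossy; for visualization only)."""
    from matplotlib import cm

    v = density.values
    vmax = v.max()
    norm = v / vmax if vmax > 0 else v
    rgba = cm.viridis(norm)
    from .synthetic import save_image_png

    save_image_png(rgba[:, :, :3], path)
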