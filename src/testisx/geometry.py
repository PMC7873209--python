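"""3D chromosome-territory geometry from voxel masks.

Oligopaint territory masks are binary voxel grids with (possibly
anisotropic) physical voxel sizes. Volume is voxel counting; surface area
comes from a triangulated 0.5 iso-surface (voxel-face counting would
overestimate area and systematically deflate sphericity). Sphericity

    psi = pi^(1/3) * (6 V)^(2/3) / A

is 1 for a perfect sphere and falls as a shape elongates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes, mesh_surface_area


@dataclass
class VoxelMask:
    """Binary 3D occupancy grid with physical voxel sizes in micrometres."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @classmethod
    def from_coordinates(cls, coords, shape, voxel_size=(1.0, 1.0, 1.0), name=""):
        """Build a mask from an iterable of (z, y, x) voxel indices."""
        grid = np.zeros(shape, dtype=bool)
        for z, y, x in coords:
            grid[int(z), int(y), int(x)] = True
        return cls(grid, voxel_size, name)


def mask_metrics(mask: VoxelMask, smooth_sigma: float = 0.8) -> tuple[float, float]:
    """(volume in um^3, surface area in um^2) of a territory mask.

    Volume counts voxels. Area triangulates the 0.5 iso-surface after a
    light Gaussian smoothing (``smooth_sigma`` in voxels) of the binary
    grid: the raw staircase surface overestimates the area of smooth
    shapes by ~9% regardless of resolution, while the smoothed surface is
    within ~1% for blob-like masks of radius >= 10 voxels. Faceted shapes
    (sharp corners) lose a little area to corner rounding; pass
    ``smooth_sigma=0`` for the raw staircase surface.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    volume = mask.n_voxels * float(np.prod(mask.voxel_size))
    padded = np.pad(mask.grid.astype(np.float32), 2)
    if smooth_sigma > 0:
        smoothed = gaussian_filter(padded, smooth_sigma)
        if smoothed.max() < 0.5:  # mask too thin to survive smoothing
            smoothed = padded
    else:
        smoothed = padded
    verts, faces, _, _ = marching_cubes(smoothed, level=0.5, spacing=mask.voxel_size)
    area = float(mesh_surface_area(verts, faces))
    return volume, area


def sphericity(volume: float, area: float) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A; 1 for a sphere, < 1 otherwise."""
    if volume <= 0 or area <= 0:
        raise ValueError("volume and area must be > 0")
    return float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)


def corrected_volume(
    volume: float, probe_span_mb: float, copy_number: int = 1
) -> float:
    """Territory volume per Mb of probed sequence, optionally per copy.

    The copy-number correction assumes volume scales linearly with copy
    number, an assumption of limited validity; both corrected and
    uncorrected values should be reported side by side.
    """
    if probe_span_mb <= 0:
        raise ValueError("probe span must be > 0 Mb")
    if copy_number < 1:
        raise ValueError("copy number must be >= 1")
    return volume / probe_span_mb / copy_number


def _physical_coords(grid: np.ndarray, voxel_size) -> np.ndarray:
    return np.argwhere(grid) * np.asarray(voxel_size)


def min_edge_distance(a: VoxelMask, b: VoxelMask) -> float:
    """Minimum distance (um) from the boundary of ``a`` to any voxel of ``b``.

    0 when the masks touch or overlap. The minimum over all voxels of ``a``
    is attained on its boundary, so the measure is symmetric in practice.
    """
    if a.grid.shape != b.grid.shape or a.voxel_size != b.voxel_size:
        raise ValueError("masks must share one voxel grid")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise ValueError("empty mask")
    if np.any(a.grid & b.grid):
        return 0.0
    boundary = a.grid & ~binary_erosion(a.grid)
    pts_a = _physical_coords(boundary, a.voxel_size)
    pts_b = _physical_coords(b.grid, b.voxel_size)
    tree = cKDTree(pts_b)
    return float(tree.query(pts_a, k=1)[0].min())


def territory_intensity_ratio(
    signal: np.ndarray,
    total: np.ndarray,
    territory: VoxelMask,
    autosome_refs,
    background: VoxelMask,
) -> float:
    """log2 of a territory's background-subtracted signal share vs autosomes.

    Per mask, the quotient is integrated (signal - mean background signal)
    over integrated (total - mean background total). The returned value is
    log2(territory quotient / mean autosomal quotient); NaN with a warning
    when a denominator is non-positive after background subtraction.
    """
    signal = np.asarray(signal, dtype=float)
    total = np.asarray(total, dtype=float)
    if signal.shape != total.shape or signal.shape != territory.grid.shape:
        raise ValueError("intensity stacks and masks must share one grid")
    if background.n_voxels == 0:
        raise ValueError("background mask is empty")
    bg_sig = signal[background.grid].mean()
    bg_tot = total[background.grid].mean()

    def quotient(mask: VoxelMask) -> float:
        num = float((signal[mask.grid] - bg_sig).sum())
        den = float((total[mask.grid] - bg_tot).sum())
        if den <= 0:
            warnings.warn(
                f"non-positive background-subtracted total in {mask.name or 'mask'}"
            )
            return np.nan
        return num / den

    q_terr = quotient(territory)
    q_autos = [quotient(m) for m in autosome_refs]
    mean_auto = float(np.mean(q_autos))
    if not np.isfinite(q_terr) or not np.isfinite(mean_auto) or mean_auto <= 0:
        return float("nan")
    if q_terr <= 0:
        warnings.warn("non-positive territory quotient; ratio undefined")
        return float("nan")
    return float(np.log2(q_terr / mean_auto))


def ball_mask(
    radius: float, voxel_size=(1.0, 1.0, 1.0), name: str = "ball"
) -> VoxelMask:
    """Digitized ball of the given physical radius, for validation work."""
    vs = np.asarray(voxel_size, dtype=float)
    half = np.ceil(radius / vs).astype(int) + 2
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1) * s for h, s in zip(half, vs)), indexing="ij"
    )
    return VoxelMask(zz**2 + yy**2 + xx**2 <= radius**2, tuple(vs), name)
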