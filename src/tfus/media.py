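"""Heterogeneous acoustic media: water background, binary skull, target ROI.

The skull is represented as a binary mask with uniform bone properties
(single sound speed / density / attenuation), matching the pseudo-CT
thresholding approach where the bone compartment is deliberately binarized.
Everything outside bone is water; soft tissue is not modelled because the
skull dominates the aberration.

Default material constants (literature values at 700 kHz):

===========  ==========  ============  =====================
compartment  c (m/s)     rho (kg/m^3)  alpha (Np/m/MHz)
===========  ==========  ============  =====================
skull        2850        1732          85
water        1482        1000          3.48e-4
===========  ==========  ============  =====================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import SimulationGrid

log = logging.getLogger(__name__)

__all__ = [
    "MaterialProperties",
    "SKULL",
    "WATER",
    "AcousticMedium",
    "TargetROI",
    "make_shell_phantom",
    "make_slab_phantom",
    "load_mask_nifti",
    "save_mask_nifti",
    "align_to_target",
    "intracranial_region",
]


@dataclass(frozen=True)
class MaterialProperties:
    c: float                 # sound speed, m/s
    rho: float               # density, kg/m^3
    alpha_coeff: float       # attenuation, Np/m/MHz (linear in frequency)

    def alpha_at(self, f0_hz: float) -> float:
        """Absorption in Np/m evaluated at the source frequency."""
        return self.alpha_coeff * f0_hz * 1e-6


SKULL = MaterialProperties(c=2850.0, rho=1732.0, alpha_coeff=85.0)
WATER = MaterialProperties(c=1482.0, rho=1000.0, alpha_coeff=3.48e-4)


@dataclass
class AcousticMedium:
    """Per-voxel acoustic property maps on the inner grid."""

    grid: SimulationGrid
    c_map: np.ndarray          # m/s
    rho_map: np.ndarray        # kg/m^3
    alpha_map: np.ndarray      # Np/m at f0
    skull_mask: np.ndarray     # bool
    intracranial_mask: np.ndarray | None = None

    @classmethod
    def from_skull_mask(
        cls,
        grid: SimulationGrid,
        skull_mask: np.ndarray | None,
        f0_hz: float = 700e3,
        skull: MaterialProperties = SKULL,
        water: MaterialProperties = WATER,
    ) -> "AcousticMedium":
        dims = grid.inner_dims
        if skull_mask is None:
            skull_mask = np.zeros(dims, dtype=bool)
        skull_mask = np.asarray(skull_mask).astype(bool)
        if skull_mask.shape != tuple(dims):
            raise ValueError(
                f"skull mask shape {skull_mask.shape} != inner grid {dims}")
        c = np.full(dims, water.c)
        rho = np.full(dims, water.rho)
        alpha = np.full(dims, water.alpha_at(f0_hz))
        c[skull_mask] = skull.c
        rho[skull_mask] = skull.rho
        alpha[skull_mask] = skull.alpha_at(f0_hz)
        return cls(grid=grid, c_map=c, rho_map=rho, alpha_map=alpha,
                   skull_mask=skull_mask)

    def water_only(self) -> "AcousticMedium":
        """Free-field copy of this medium (skull removed)."""
        m = AcousticMedium.from_skull_mask(self.grid, None)
        # keep water absorption identical to this medium's background
        bg = ~self.skull_mask
        if bg.any():
            m.alpha_map[:] = np.min(self.alpha_map[bg])
        return m


@dataclass
class TargetROI:
    """Binary target region used only for post-simulation evaluation."""

    mask: np.ndarray
    grid: SimulationGrid

    @property
    def volume_mm3(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.grid.dx_mm ** 3

    @property
    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        if idx.size == 0:
            raise ValueError("empty ROI")
        return idx.mean(axis=0) * self.grid.dx_mm


def _voxel_centers(grid: SimulationGrid):
    x = np.arange(grid.inner_dims[0]) * grid.dx_mm
    y = np.arange(grid.inner_dims[1]) * grid.dx_mm
    z = np.arange(grid.inner_dims[2]) * grid.dx_mm
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def make_shell_phantom(
    grid: SimulationGrid,
    shell_radius_mm: float,
    thickness_mm: float,
    angular_extent_deg: float = 360.0,
    center_mm=(0.0, 0.0, 0.0),
    axis=(-1.0, 0.0, 0.0),
    allow_clip: bool = False,
) -> np.ndarray:
    """Spherical-shell sector skull phantom (binary mask, center-point test).

    The shell occupies radii ``[r - t/2, r + t/2]`` about ``center_mm``; the
    sector keeps voxels whose direction from the center lies within
    ``angular_extent_deg / 2`` of ``axis`` (default: facing the array, -x).
    With ``allow_clip`` the shell may extend beyond the grid and is clipped
    (used for large-radius calvaria-like caps where only the cap facing the
    array lies inside the domain).
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be >= 0")
    if thickness_mm == 0:
        return np.zeros(grid.inner_dims, dtype=bool)
    r_out = shell_radius_mm + thickness_mm / 2.0
    c = np.asarray(center_mm, dtype=float)
    lo, hi = c - r_out, c + r_out
    ext = np.asarray(grid.inner_extent_mm)
    if not allow_clip and (np.any(lo < -grid.dx_mm / 2)
                           or np.any(hi > ext - grid.dx_mm / 2)):
        raise ValueError("shell phantom exceeds the inner grid")
    X, Y, Z = _voxel_centers(grid)
    dxv, dyv, dzv = X - c[0], Y - c[1], Z - c[2]
    r = np.sqrt(dxv**2 + dyv**2 + dzv**2)
    mask = (r >= shell_radius_mm - thickness_mm / 2.0) & (r <= r_out)
    if angular_extent_deg < 360.0:
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (dxv * ax[0] + dyv * ax[1] + dzv * ax[2]) / r
        half = np.deg2rad(angular_extent_deg / 2.0)
        mask &= cosang >= np.cos(half)
    return mask


def make_slab_phantom(
    grid: SimulationGrid,
    x_start_mm: float,
    thickness_mm: float,
) -> np.ndarray:
    """Flat skull slab normal to the array axis, spanning the lateral extent."""
    if thickness_mm <= 0:
        return np.zeros(grid.inner_dims, dtype=bool)
    x = np.arange(grid.inner_dims[0]) * grid.dx_mm
    in_slab = (x >= x_start_mm) & (x < x_start_mm + thickness_mm)
    mask = np.zeros(grid.inner_dims, dtype=bool)
    mask[in_slab, :, :] = True
    return mask


def load_mask_nifti(path, grid: SimulationGrid) -> np.ndarray:
    """Load a binary mask from NIfTI, nearest-neighbour resampled to the grid.

    Nonzero voxels map to True.  If the input voxel spacing differs from the
    grid spacing the volume is resampled by nearest neighbour (preserves
    binarity); the input affine is recorded in the log.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    log.info("loaded NIfTI %s shape=%s affine=%s", path, data.shape,
             np.round(img.affine, 4).tolist())
    mask = data != 0
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, grid.dx_mm, rtol=1e-3):
        factors = np.asarray(zooms) / grid.dx_mm
        out_shape = tuple(int(round(s * f)) for s, f in
                          zip(mask.shape, factors))
        coords = np.meshgrid(
            *[np.arange(n) / f for n, f in zip(out_shape, factors)],
            indexing="ij")
        mask = ndimage.map_coordinates(
            mask.astype(np.uint8), np.array(coords), order=0,
            mode="constant").astype(bool)
        log.info("resampled NIfTI mask from spacing %s to %.4f mm, "
                 "shape %s", zooms, grid.dx_mm, mask.shape)
    out = np.zeros(grid.inner_dims, dtype=bool)
    take = tuple(slice(0, min(a, b)) for a, b in
                 zip(grid.inner_dims, mask.shape))
    out[take] = mask[take]
    return out


def save_mask_nifti(mask: np.ndarray, grid: SimulationGrid, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine())
    img.header.set_zooms((grid.dx_mm,) * 3)
    nib.save(img, str(path))


def align_to_target(
    skull_mask: np.ndarray,
    roi_mask: np.ndarray,
    target_mm,
    grid: SimulationGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly shift skull + ROI so the ROI centroid lands on ``target_mm``.

    Translation-only (on-lattice, nearest-voxel): the rotation that a
    planning workflow would apply when orienting an array at a head is
    outside the phantom geometry's needs.  Raises if the shift would push
    skull voxels outside the inner grid.
    """
    roi_mask = roi_mask.astype(bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    centroid = np.argwhere(roi_mask).mean(axis=0)
    target_vox = np.asarray(target_mm, dtype=float) / grid.dx_mm
    shift = np.rint(target_vox - centroid).astype(int)
    if np.all(shift == 0):
        return skull_mask.copy(), roi_mask.copy()
    for name, m in (("skull", skull_mask), ("roi", roi_mask)):
        idx = np.argwhere(m)
        if idx.size:
            lo = idx.min(axis=0) + shift
            hi = idx.max(axis=0) + shift
            if np.any(lo < 0) or np.any(hi >= np.asarray(grid.inner_dims)):
                raise ValueError(
                    f"alignment shift {shift.tolist()} pushes {name} mask "
                    "outside the inner grid")
    out = []
    for m in (skull_mask, roi_mask):
        shifted = np.zeros_like(m, dtype=bool)
        src = tuple(slice(max(0, -s), m.shape[i] - max(0, s))
                    for i, s in enumerate(shift))
        dst = tuple(slice(max(0, s), m.shape[i] - max(0, -s))
                    for i, s in enumerate(shift))
        shifted[dst] = m[src]
        out.append(shifted)
    return out[0], out[1]


def intracranial_region(
    skull_mask: np.ndarray,
    target_voxel,
    fallback_axial_plane: int | None = None,
) -> np.ndarray:
    """Connected non-skull region containing the target (6-connected).

    This is the "intracranial" compartment against which pressure is
    normalized and the focus extracted: the water component on the far side
    of the skull from the array.  If the skull mask is empty, falls back to
    the water half-space beyond ``fallback_axial_plane`` (axial voxel index).
    For open skull sectors pass ``fallback_axial_plane`` as well: the flood
    fill is then restricted to voxels at or beyond that plane so it cannot
    leak around the sector rim into the array-side water.
    """
    skull_mask = skull_mask.astype(bool)
    tv = tuple(int(i) for i in target_voxel)
    if skull_mask[tv]:
        raise ValueError(f"target voxel {tv} lies inside the skull mask")
    water = ~skull_mask
    if not skull_mask.any():
        if fallback_axial_plane is None:
            raise ValueError(
                "no skull present: supply fallback_axial_plane to define "
                "the intracranial half-space")
        region = np.zeros_like(water)
        region[fallback_axial_plane:, :, :] = True
        return region & water
    domain = water.copy()
    if fallback_axial_plane is not None:
        domain[:fallback_axial_plane, :, :] = False
        if not domain[tv]:
            raise ValueError("target voxel lies before the axial plane")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(domain, structure=structure)
    lab = labels[tv]
    if lab == 0:
        raise ValueError("target voxel not in any water component")
    return labels == lab
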