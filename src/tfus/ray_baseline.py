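"""Straight-ray time-of-flight baseline ("ray (simplified)").

A deliberately simple geometric stand-in for ray-tracing planning tools:
each element's correction is derived from the straight segment from the
element center to the target, with no Snell refraction.  The skull path
length along the segment converts to an arrival-time difference relative
to an all-water path, and an element is activated only when its incidence
angle at the skull entry is below a threshold (default 30 deg, near the
water->bone longitudinal critical angle asin(1482/2850) ~ 31.3 deg, beyond
which most energy reflects).  Full-wave phase reversal is expected to beat
this baseline wherever diffraction and scattering matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .array_model import TransducerArray
from .grid import SimulationGrid
from .media import SKULL, WATER

__all__ = [
    "RayResult",
    "trace_ray",
    "ray_phase_delay",
    "activation_criterion",
    "ray_delays",
]


@dataclass
class RayResult:
    """Per-element straight-ray quantities (lengths mm, angles deg)."""

    path_length_water: np.ndarray
    path_length_skull: np.ndarray
    tof_free: np.ndarray        # s
    tof_skull: np.ndarray       # s
    dphi_ray: np.ndarray        # radians, same sign convention as DelaySet
    incidence_angle: np.ndarray  # degrees (nan if no skull crossing)
    active: np.ndarray          # 0/1

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "element_index": np.arange(len(self.active)),
            "l_water_mm": self.path_length_water,
            "l_skull_mm": self.path_length_skull,
            "dphi_rad": self.dphi_ray,
            "incidence_deg": self.incidence_angle,
            "active": self.active.astype(int),
        }).to_csv(path, index=False)


def trace_ray(
    element_center_mm,
    target_mm,
    skull_mask: np.ndarray,
    grid: SimulationGrid,
    step_frac: float = 0.25,
):
    """Sample the element->target segment; return path lengths + entry angle.

    The segment is sampled every ``step_frac * dx``; the skull path length
    is the in-skull sample fraction times the segment length.  The entry
    normal comes from the gradient of a 1-voxel-smoothed skull mask at the
    first in-skull sample.  Returns ``(l_water_mm, l_skull_mm,
    incidence_deg)``; the angle is NaN when the ray misses the skull.
    """
    a = np.asarray(element_center_mm, dtype=float)
    b = np.asarray(target_mm, dtype=float)
    seg = b - a
    length = float(np.linalg.norm(seg))
    if length == 0:
        return 0.0, 0.0, float("nan")
    direction = seg / length
    n_samp = max(2, int(np.ceil(length / (step_frac * grid.dx_mm))) + 1)
    ts = np.linspace(0.0, 1.0, n_samp)
    pts = a[None, :] + ts[:, None] * seg[None, :]
    vox = np.rint(pts / grid.dx_mm).astype(int)
    dims = np.asarray(grid.inner_dims)
    inside = np.all((vox >= 0) & (vox < dims), axis=1)
    in_skull = np.zeros(n_samp, dtype=bool)
    iv = vox[inside]
    in_skull[inside] = skull_mask[iv[:, 0], iv[:, 1], iv[:, 2]]
    frac = in_skull.mean()
    l_skull = frac * length
    l_water = length - l_skull
    if not in_skull.any():
        return l_water, 0.0, float("nan")
    entry = pts[np.argmax(in_skull)]   # first in-skull sample
    smooth = ndimage.gaussian_filter(skull_mask.astype(float), sigma=1.0)
    gx, gy, gz = ndimage.sobel(smooth, 0), ndimage.sobel(smooth, 1), \
        ndimage.sobel(smooth, 2)
    ev = np.clip(np.rint(entry / grid.dx_mm).astype(int), 0, dims - 1)
    normal = np.array([gx[tuple(ev)], gy[tuple(ev)], gz[tuple(ev)]])
    nn = np.linalg.norm(normal)
    if nn == 0:
        return l_water, l_skull, float("nan")
    cosang = abs(float(direction @ (normal / nn)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return l_water, l_skull, angle


def ray_phase_delay(
    path_water_mm: float,
    path_skull_mm: float,
    c_water: float = WATER.c,
    c_skull: float = SKULL.c,
    f0: float = 700e3,
) -> float:
    """Time-of-flight phase delay of the skull path vs an all-water path.

    ``dt_ray = l_skull (1/c_skull - 1/c_water)`` (negative: bone is
    faster); ``dphi = 2 pi f0 dt_ray``, the same sign convention as the
    full-wave delay estimate, so it feeds the same correction machinery.
    """
    if path_water_mm < 0 or path_skull_mm < 0:
        raise ValueError("path lengths must be >= 0")
    total = (path_water_mm + path_skull_mm) * 1e-3
    tof_skull = (path_water_mm * 1e-3) / c_water + \
        (path_skull_mm * 1e-3) / c_skull
    dt_ray = tof_skull - total / c_water
    return 2.0 * np.pi * f0 * dt_ray


def activation_criterion(incidence_angle_deg: float,
                         threshold_deg: float = 30.0) -> int:
    """1 if the element's skull incidence angle admits transmission.

    NaN angles (no skull on the ray) activate the element.
    """
    if np.isnan(incidence_angle_deg):
        return 1
    return int(incidence_angle_deg <= threshold_deg)


def ray_delays(
    array: TransducerArray,
    skull_mask: np.ndarray,
    target_mm,
    grid: SimulationGrid,
    f0: float = 700e3,
    c_water: float = WATER.c,
    c_skull: float = SKULL.c,
    activation_threshold_deg: float = 30.0,
) -> RayResult:
    """Straight-ray delays + activation for every element of the array."""
    n = array.n_elements
    lw = np.zeros(n)
    ls = np.zeros(n)
    ang = np.zeros(n)
    for i in range(n):
        lw[i], ls[i], ang[i] = trace_ray(
            array.element_centers[i], target_mm, skull_mask, grid)
    tof_free = (lw + ls) * 1e-3 / c_water
    tof_skull = lw * 1e-3 / c_water + ls * 1e-3 / c_skull
    dphi = 2.0 * np.pi * f0 * (tof_skull - tof_free)
    active = np.array([activation_criterion(a, activation_threshold_deg)
                       for a in ang])
    return RayResult(path_length_water=lw, path_length_skull=ls,
                     tof_free=tof_free, tof_skull=tof_skull, dphi_ray=dphi,
                     incidence_angle=ang, active=active)
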