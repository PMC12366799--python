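"""Random spherical-cap phased array: geometry, rasterization, CW drive.

The array is a 128-element (default) random layout of 4 mm disc elements on
a spherical cap of radius equal to the focal depth (35 mm), so every element
is equidistant from the geometric focus and an unsteered (zero-phase) drive
focuses there by construction.  Randomized element placement suppresses the
periodic grating lobes a regular lattice would produce.  The physical
transducer's element coordinates are proprietary, so layouts are generated
by seeded rejection sampling (and can be imported from CSV if measured
coordinates are available).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import SimulationGrid

__all__ = [
    "TransducerArray",
    "SourceSignal",
    "CWSourceTerm",
    "wrap_phase",
    "generate_random_array",
    "geometric_steering_phases",
    "rasterize_elements",
    "make_cw_source",
    "save_array_csv",
    "load_array_csv",
]


def wrap_phase(phi):
    """Wrap phase(s) to the half-open interval (-pi, pi]."""
    w = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class TransducerArray:
    """Disc elements on a spherical cap focused at ``focus_mm``."""

    element_centers: np.ndarray      # (n, 3) mm
    element_normals: np.ndarray      # (n, 3) unit vectors toward the focus
    focus_mm: np.ndarray             # (3,) geometric focus, mm
    element_diameter: float = 4.0    # mm
    focal_depth: float = 35.0        # mm (cap radius)
    aperture_diameter: float = 64.0  # mm
    geometry_seed: int | None = None

    @property
    def n_elements(self) -> int:
        return self.element_centers.shape[0]

    def distances_to(self, target_mm) -> np.ndarray:
        d = self.element_centers - np.asarray(target_mm, dtype=float)
        return np.linalg.norm(d, axis=1)


@dataclass(frozen=True)
class SourceSignal:
    """Continuous-wave drive: s_i(t) = amplitude * sin(2 pi f0 t + phase_i)."""

    f0: float = 700e3            # Hz
    amplitude_pa: float = 1e6    # Pa, per element (Samp)
    phases: np.ndarray | float = 0.0   # radians, per element or scalar
    t_end: float = 50e-6         # s

    def phases_for(self, n_elements: int) -> np.ndarray:
        ph = np.broadcast_to(np.atleast_1d(
            np.asarray(self.phases, dtype=float)), (n_elements,))
        return wrap_phase(ph)

    def with_phases(self, phases) -> "SourceSignal":
        return replace(self, phases=np.asarray(phases, dtype=float))


def generate_random_array(
    n: int = 128,
    aperture_diameter: float = 64.0,
    focal_depth: float = 35.0,
    element_diameter: float = 4.0,
    seed: int = 0,
    focus_mm=(35.0, 0.0, 0.0),
    max_attempts: int | None = None,
) -> TransducerArray:
    """Seeded rejection sampling of non-overlapping discs on the cap.

    Candidate centers are drawn uniformly on the spherical cap (uniform in
    cos(theta) and azimuth); a candidate is rejected when its center lies
    closer than ``element_diameter`` to an accepted one.  Deterministic per
    seed (PCG64).  The cap opens toward -x: the apex sits at
    ``focus - focal_depth * x_hat``.
    """
    if n < 1:
        raise ValueError("need at least one element")
    R = float(focal_depth)
    half_ap = aperture_diameter / 2.0
    if half_ap > R:
        raise ValueError("aperture radius cannot exceed the focal depth")
    cos_tmax = np.sqrt(1.0 - (half_ap / R) ** 2)
    cap_area = 2.0 * np.pi * R**2 * (1.0 - cos_tmax)
    elem_area = np.pi * (element_diameter / 2.0) ** 2
    if n * elem_area >= cap_area:
        raise ValueError(
            f"cannot pack {n} discs of area {elem_area:.2f} mm^2 on a cap "
            f"of area {cap_area:.2f} mm^2")
    focus = np.asarray(focus_mm, dtype=float)
    rng = np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(200_000, 20_000 * n)
    centers = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"failed to place {n} elements after {max_attempts} "
                f"attempts ({len(centers)} placed): cap too small for "
                "this element count/diameter")
        ct = rng.uniform(cos_tmax, 1.0)
        st = np.sqrt(1.0 - ct * ct)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        d = np.array([-ct, st * np.cos(phi), st * np.sin(phi)])
        cand = focus + R * d
        if centers:
            dist = np.linalg.norm(np.asarray(centers) - cand, axis=1)
            if np.min(dist) < element_diameter:
                continue
        centers.append(cand)
    centers = np.asarray(centers)
    normals = (focus - centers) / R
    return TransducerArray(
        element_centers=centers, element_normals=normals, focus_mm=focus,
        element_diameter=element_diameter, focal_depth=focal_depth,
        aperture_diameter=aperture_diameter, geometry_seed=seed)


def geometric_steering_phases(
    array: TransducerArray, target_mm, c: float = 1482.0,
    f0: float = 700e3,
) -> np.ndarray:
    """Phases steering the beam to ``target_mm`` in a homogeneous medium.

    phase_i = 2 pi f0 (d_max - d_i) / c, wrapped to (-pi, pi]: the farthest
    element fires first (phase 0), nearer elements are advanced so all
    arrivals coincide.  At the geometric focus all d_i are equal and every
    phase is exactly zero.
    """
    d = array.distances_to(target_mm) * 1e-3  # m
    if np.isinf(c):
        return np.zeros(array.n_elements)
    dd = d.max() - d
    dd[dd < 1e-12] = 0.0   # equidistant cap: exactly zero, not 1e-14 noise
    return wrap_phase(2.0 * np.pi * f0 * dd / c)


def rasterize_elements(
    array: TransducerArray,
    grid: SimulationGrid,
    supersample: int = 8,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Voxel weight maps for each disc element (super-sampled occupancy).

    Each disc is treated as a one-voxel-thick oriented slab of diameter
    ``element_diameter``; every candidate voxel is subdivided
    ``supersample^3`` times and weighted by the fraction of sub-points
    inside the slab.  The weights then satisfy
    ``sum(w) * dx^2 ~= pi (d/2)^2`` (disc area).

    Returns a list of ``(voxel_indices (m, 3), weights (m,))`` per element,
    indices on the inner grid.
    """
    dx = grid.dx_mm
    a = array.element_diameter / 2.0
    dims = np.asarray(grid.inner_dims)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1) * dx
    out = []
    for i in range(array.n_elements):
        c = array.element_centers[i]
        nrm = array.element_normals[i]
        reach = a + dx
        lo = np.maximum(np.floor((c - reach) / dx).astype(int), 0)
        hi = np.minimum(np.ceil((c + reach) / dx).astype(int), dims - 1)
        if np.any((c - reach) / dx < -0.5) or np.any(
                (c + reach) / dx > dims - 0.5):
            raise ValueError(
                f"element {i} disc extends outside the inner grid")
        ii, jj, kk = np.meshgrid(*[np.arange(l, h + 1) for l, h in
                                   zip(lo, hi)], indexing="ij")
        vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        pts = vox[:, None, :] * dx + sub[None, :, :]   # (V, S, 3)
        rel = pts - c
        axial = rel @ nrm
        rad2 = np.einsum("vsd,vsd->vs", rel, rel) - axial**2
        inside = (np.abs(axial) <= dx / 2.0) & (rad2 <= a * a)
        w = inside.mean(axis=1)
        keep = w > 0
        out.append((vox[keep], w[keep]))
    return out


@dataclass
class CWSourceTerm:
    """Per-step additive pressure source for the solver.

    Element i injects ``amplitude * sin(2 pi f0 t + phase_i)`` over its
    rasterized voxel weights; elements can be switched off through the 0/1
    activation mask.
    """

    f0: float
    amplitude: float
    phases: np.ndarray               # (n,) radians, wrapped
    element_voxels: list             # [(indices (m,3), weights (m,)), ...]
    activation: np.ndarray           # (n,) bool
    t_end: float

    @property
    def n_elements(self) -> int:
        return len(self.element_voxels)

    def element_values(self, t: float) -> np.ndarray:
        """Signal value of every element at time t (inactive -> 0)."""
        s = self.amplitude * np.sin(
            2.0 * np.pi * self.f0 * t + self.phases)
        return np.where(self.activation, s, 0.0)

    def flat_layout(self, grid: SimulationGrid):
        """Concatenated (expanded-grid flat indices, weights, element ids)."""
        pml = np.asarray(grid.boundary_layer)
        exp = grid.expanded_dims
        idx_list, w_list, e_list = [], [], []
        for e, (vox, w) in enumerate(self.element_voxels):
            if len(vox) == 0:
                continue
            v = vox + pml
            flat = np.ravel_multi_index((v[:, 0], v[:, 1], v[:, 2]), exp)
            idx_list.append(flat)
            w_list.append(w)
            e_list.append(np.full(len(w), e, dtype=int))
        if not idx_list:
            return (np.empty(0, dtype=int), np.empty(0), np.empty(0, int))
        return (np.concatenate(idx_list), np.concatenate(w_list),
                np.concatenate(e_list))


def make_cw_source(
    signal: SourceSignal,
    grid: SimulationGrid,
    element_weights: list,
    activation=None,
    dt: float | None = None,
) -> CWSourceTerm:
    """Build the solver source term from a drive signal and weight maps."""
    n = len(element_weights)
    if dt is not None and dt * signal.f0 > 0.5:
        raise ValueError(
            f"time step {dt:g} s does not resolve f0={signal.f0:g} Hz")
    if activation is None:
        activation = np.ones(n, dtype=bool)
    activation = np.asarray(activation).astype(bool)
    if activation.shape != (n,):
        raise ValueError("activation mask length != number of elements")
    return CWSourceTerm(
        f0=signal.f0, amplitude=signal.amplitude_pa,
        phases=signal.phases_for(n), element_voxels=element_weights,
        activation=activation, t_end=signal.t_end)


def save_array_csv(array: TransducerArray, path) -> None:
    df = pd.DataFrame({
        "element_index": np.arange(array.n_elements),
        "x_mm": array.element_centers[:, 0],
        "y_mm": array.element_centers[:, 1],
        "z_mm": array.element_centers[:, 2],
        "nx": array.element_normals[:, 0],
        "ny": array.element_normals[:, 1],
        "nz": array.element_normals[:, 2],
    })
    df.to_csv(path, index=False)


def load_array_csv(path, element_diameter: float = 4.0,
                   focal_depth: float | None = None) -> TransducerArray:
    """Import measured element coordinates (schema of :func:`save_array_csv`).

    The geometric focus is recovered as the point each normal aims at,
    ``center + focal_depth * normal`` averaged over elements; if
    ``focal_depth`` is not given it is taken as the mean distance from the
    centers to their common focal point estimated by least squares.
    """
    df = pd.read_csv(path).sort_values("element_index")
    centers = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    normals = df[["nx", "ny", "nz"]].to_numpy(float)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    if focal_depth is None:
        # least-squares intersection of the element axes
        n = centers.shape[0]
        A = np.zeros((3, 3))
        b = np.zeros(3)
        for c, d in zip(centers, normals):
            P = np.eye(3) - np.outer(d, d)
            A += P
            b += P @ c
        focus = np.linalg.solve(A, b)
        focal_depth = float(np.mean(np.linalg.norm(centers - focus, axis=1)))
    else:
        focus = np.mean(centers + focal_depth * normals, axis=0)
    aperture = 2.0 * float(np.max(np.linalg.norm(
        centers[:, 1:] - focus[1:], axis=1)))
    return TransducerArray(
        element_centers=centers, element_normals=normals,
        focus_mm=np.asarray(focus), element_diameter=element_diameter,
        focal_depth=float(focal_depth), aperture_diameter=aperture)
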