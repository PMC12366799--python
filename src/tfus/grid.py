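"""Computational grid and time-stepping definitions.

The simulation domain is a regular isotropic voxel grid.  The *inner* grid is
the physical region of interest; an absorbing boundary layer is wrapped
around it on every side to emulate free-space radiation with a spectral
(periodic) solver, giving the *expanded* grid the solver actually runs on.

Axis convention: ``x`` (axis 0) is the axial direction along the transducer
axis; ``y``/``z`` (axes 1, 2) are lateral.  Voxel centres sit at
``index * dx`` millimetres, with the origin at the first inner-grid voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationGrid",
    "TimeStepping",
    "compute_dx",
    "auto_boundary_size",
    "largest_prime_factor",
    "compute_dt",
]


def compute_dx(extent_mm: float, n_voxels: int) -> float:
    """Isotropic voxel spacing (mm) from a physical extent and voxel count.

    Returned at full precision; round to two decimals only for display
    (150 mm over 140 voxels displays as 1.07 mm).
    """
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    return extent_mm / n_voxels


def largest_prime_factor(n: int) -> int:
    if n < 2:
        raise ValueError("n must be >= 2")
    largest = 1
    d = 2
    while d * d <= n:
        while n % d == 0:
            largest = d
            n //= d
        d += 1
    if n > 1:
        largest = n
    return largest


def auto_boundary_size(
    inner_dims: tuple[int, ...],
    min_layer: int = 10,
    max_layer: int = 40,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Choose the absorbing-layer thickness per axis automatically.

    For each axis, search layer thickness ``p`` in ``[min_layer, max_layer]``
    (applied to both sides) and pick the ``p`` whose expanded size
    ``inner + 2 p`` has the smallest largest prime factor; ties go to the
    smaller expanded size.  Highly composite expanded sizes keep the FFTs
    fast.  Reproduces 86 -> 128 and 140 -> 162.

    Returns ``(layers, expanded_dims)``.
    """
    layers = []
    expanded = []
    for n in inner_dims:
        if n < 16:
            raise ValueError(f"inner dimension {n} too small (need >= 16)")
        best = None  # (largest prime factor, total, p)
        for p in range(min_layer, max_layer + 1):
            total = n + 2 * p
            key = (largest_prime_factor(total), total)
            if best is None or key < best[:2]:
                best = (*key, p)
        layers.append(best[2])
        expanded.append(best[1])
    return tuple(layers), tuple(expanded)


@dataclass(frozen=True)
class SimulationGrid:
    """Voxel grid geometry shared by media, sources, solver and metrics."""

    inner_dims: tuple[int, int, int] = (86, 140, 140)
    dx_mm: float = 150.0 / 140.0
    boundary_layer: tuple[int, int, int] = (21, 11, 11)

    @classmethod
    def with_auto_boundary(
        cls, inner_dims: tuple[int, int, int] = (86, 140, 140),
        dx_mm: float = 150.0 / 140.0,
    ) -> "SimulationGrid":
        layers, _ = auto_boundary_size(inner_dims)
        return cls(inner_dims=tuple(inner_dims), dx_mm=dx_mm,
                   boundary_layer=layers)

    @property
    def expanded_dims(self) -> tuple[int, int, int]:
        return tuple(n + 2 * p for n, p in
                     zip(self.inner_dims, self.boundary_layer))

    @property
    def dx_m(self) -> float:
        return self.dx_mm * 1e-3

    @property
    def inner_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.dx_mm for n in self.inner_dims)

    def inner_slices(self) -> tuple[slice, slice, slice]:
        """Slices selecting the inner region out of an expanded-grid array."""
        return tuple(slice(p, p + n) for n, p in
                     zip(self.inner_dims, self.boundary_layer))

    def voxel_to_mm(self, idx) -> np.ndarray:
        """Inner-grid voxel index -> position in mm (voxel centres)."""
        return np.asarray(idx, dtype=float) * self.dx_mm

    def mm_to_voxel(self, pos_mm) -> np.ndarray:
        """Position in mm -> nearest inner-grid voxel index."""
        return np.rint(np.asarray(pos_mm, dtype=float) / self.dx_mm).astype(int)

    def contains_mm(self, pos_mm) -> bool:
        idx = np.asarray(pos_mm, dtype=float) / self.dx_mm
        return bool(np.all(idx >= 0) and
                    np.all(idx <= np.asarray(self.inner_dims) - 1))

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping inner voxel indices to mm."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.dx_mm
        return aff


def compute_dt(ppw: float, cfl: float, f0: float) -> float:
    """Period-locked time step: ``dt = 1 / (round(PPW/CFL) * f0)``.

    Locking the step count to an integer number per acoustic period makes
    the phase <-> step-count conversion exact (100 steps/period at the
    defaults PPW=2, CFL=0.02).
    """
    if ppw <= 0 or cfl <= 0 or f0 <= 0:
        raise ValueError("PPW, CFL and f0 must be positive")
    return 1.0 / (round(ppw / cfl) * f0)


@dataclass(frozen=True)
class TimeStepping:
    """Temporal discretization derived from (PPW, CFL, f0, t_end)."""

    f0: float = 700e3
    ppw: float = 2.0
    cfl: float = 0.02
    t_end: float = 50e-6
    c_ref: float = 1482.0  # k-space correction reference speed (water)

    @property
    def steps_per_period(self) -> int:
        return round(self.ppw / self.cfl)

    @property
    def dt(self) -> float:
        return compute_dt(self.ppw, self.cfl, self.f0)

    @property
    def n_steps(self) -> int:
        return round(self.t_end / self.dt)

    @property
    def phase_quantum(self) -> float:
        """Smallest resolvable phase increment, 2*pi*f0*dt (radians)."""
        return 2.0 * np.pi * self.f0 * self.dt
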