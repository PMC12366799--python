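"""Named simulation profiles bundling grid, stepping, array and drive.

``paper``  — the full-scale study setting: 86 x 140 x 140 inner grid at
             dx = 150/140 mm, PPW 2 / CFL 0.02 (100 steps per period,
             dt = 14.2857 ns), t_end = 50 us, 128-element / 64 mm aperture
             / 35 mm focal depth array.  Expensive; kept for fidelity runs.
``desk``   — same array on a 64 x 95 x 95 inner grid at dx = 1.0 mm
             (PPW 2.1: comfortably above the sampling limit that the
             full-scale spacing sits right at), CFL 0.05 (40 steps per
             period), t_end = 40 us.  Odd lateral dims put the array axis
             exactly on a voxel.  A free-field run takes minutes on one
             core.
``mini``   — a scaled-down cap (16 elements of 3.5 mm on a 24 mm
             aperture, 17 mm focal depth) on a 36 x 37 x 37 inner grid,
             CFL 0.1 (20 steps per period); seconds per run.  Used for
             cohort studies and tests where per-element solver runs
             multiply.  Full-array runs integrate 30 us so the cavity
             reverberation settles; single-element delay-estimation runs
             stop at 20 us (the target record is steady well before).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .array_model import SourceSignal, TransducerArray, generate_random_array
from .grid import SimulationGrid, TimeStepping

__all__ = ["SimulationProfile", "paper_profile", "desk_profile",
           "mini_profile", "get_profile", "profile_from_config"]


@dataclass(frozen=True)
class SimulationProfile:
    name: str
    grid: SimulationGrid
    stepping: TimeStepping
    n_elements: int
    aperture_mm: float
    focal_depth_mm: float
    element_diameter_mm: float
    focus_voxel: tuple[int, int, int]
    amplitude_pa: float = 1e6
    solver_dtype: str = "float32"
    single_t_end: float | None = None   # shorter horizon for per-element
                                        # delay-estimation records

    @property
    def focus_mm(self) -> np.ndarray:
        return np.asarray(self.focus_voxel, dtype=float) * self.grid.dx_mm

    @property
    def axis_lateral_mm(self) -> tuple[float, float]:
        return (self.focus_voxel[1] * self.grid.dx_mm,
                self.focus_voxel[2] * self.grid.dx_mm)

    def make_array(self, seed: int = 1) -> TransducerArray:
        return generate_random_array(
            n=self.n_elements, aperture_diameter=self.aperture_mm,
            focal_depth=self.focal_depth_mm,
            element_diameter=self.element_diameter_mm, seed=seed,
            focus_mm=self.focus_mm)

    def make_signal(self) -> SourceSignal:
        return SourceSignal(f0=self.stepping.f0,
                            amplitude_pa=self.amplitude_pa,
                            t_end=self.stepping.t_end)

    @property
    def dtype(self):
        return np.float32 if self.solver_dtype == "float32" else np.float64

    @property
    def single_stepping(self) -> TimeStepping:
        """Stepping for single-element runs (same dt, shorter record)."""
        if self.single_t_end is None:
            return self.stepping
        return replace(self.stepping, t_end=self.single_t_end)


def paper_profile() -> SimulationProfile:
    grid = SimulationGrid.with_auto_boundary((86, 140, 140), 150.0 / 140.0)
    stepping = TimeStepping(f0=700e3, ppw=2.0, cfl=0.02, t_end=50e-6)
    return SimulationProfile(
        name="paper", grid=grid, stepping=stepping, n_elements=128,
        aperture_mm=64.0, focal_depth_mm=35.0, element_diameter_mm=4.0,
        focus_voxel=(37, 70, 70), solver_dtype="float64")


def desk_profile() -> SimulationProfile:
    grid = SimulationGrid.with_auto_boundary((64, 95, 95), 1.0)
    stepping = TimeStepping(f0=700e3, ppw=2.0, cfl=0.05, t_end=40e-6)
    return SimulationProfile(
        name="desk", grid=grid, stepping=stepping, n_elements=128,
        aperture_mm=64.0, focal_depth_mm=35.0, element_diameter_mm=4.0,
        focus_voxel=(40, 47, 47), single_t_end=30e-6)


def mini_profile() -> SimulationProfile:
    grid = SimulationGrid(inner_dims=(36, 37, 37), dx_mm=1.0,
                          boundary_layer=(6, 6, 6))
    stepping = TimeStepping(f0=700e3, ppw=2.0, cfl=0.1, t_end=30e-6)
    return SimulationProfile(
        name="mini", grid=grid, stepping=stepping, n_elements=16,
        aperture_mm=24.0, focal_depth_mm=17.0, element_diameter_mm=3.5,
        focus_voxel=(20, 18, 18), single_t_end=20e-6)


_PROFILES = {"paper": paper_profile, "desk": desk_profile,
             "mini": mini_profile}


def get_profile(name: str) -> SimulationProfile:
    try:
        return _PROFILES[name]()
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")


def profile_from_config(cfg: dict) -> SimulationProfile:
    """Build a profile from a config mapping (YAML-friendly keys).

    Recognized keys: ``profile`` (base name), ``grid.inner_dims``,
    ``grid.dx_mm``, ``grid.boundary`` ("auto" or per-axis list),
    ``transducer.n_elements|aperture_mm|focal_depth_mm|
    element_diameter_mm``, ``source.f0_hz|amplitude_pa|duration_s``,
    ``solver.ppw|cfl|dtype``, ``target_voxel``.
    """
    prof = get_profile(cfg.get("profile", "desk"))
    g = cfg.get("grid", {})
    if g:
        inner = tuple(g.get("inner_dims", prof.grid.inner_dims))
        dx = float(g.get("dx_mm", prof.grid.dx_mm))
        boundary = g.get("boundary", "auto")
        if boundary == "auto":
            grid = SimulationGrid.with_auto_boundary(inner, dx)
        else:
            grid = SimulationGrid(inner, dx, tuple(boundary))
        prof = replace(prof, grid=grid)
    s = cfg.get("solver", {})
    src = cfg.get("source", {})
    if s or src:
        prof = replace(prof, stepping=TimeStepping(
            f0=float(src.get("f0_hz", prof.stepping.f0)),
            ppw=float(s.get("ppw", prof.stepping.ppw)),
            cfl=float(s.get("cfl", prof.stepping.cfl)),
            t_end=float(src.get("duration_s", prof.stepping.t_end))))
        if "dtype" in s:
            prof = replace(prof, solver_dtype=s["dtype"])
        if "amplitude_pa" in src:
            prof = replace(prof, amplitude_pa=float(src["amplitude_pa"]))
    t = cfg.get("transducer", {})
    if t:
        prof = replace(
            prof,
            n_elements=int(t.get("n_elements", prof.n_elements)),
            aperture_mm=float(t.get("aperture_mm", prof.aperture_mm)),
            focal_depth_mm=float(t.get("focal_depth_mm",
                                       prof.focal_depth_mm)),
            element_diameter_mm=float(t.get("element_diameter_mm",
                                            prof.element_diameter_mm)))
    if "target_voxel" in cfg:
        prof = replace(prof, focus_voxel=tuple(cfg["target_voxel"]))
    return prof
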