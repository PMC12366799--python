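"""Cohort experiments: phantoms x correction conditions -> metric tables.

Conditions (labels follow the comparison design):

========  =============================================  ================
label     element phases                                 activation
========  =============================================  ================
NoCorr    zero                                           all on
kPR       full-wave phase-reversal delays                all on
KE        full-wave phase-reversal delays                ray criterion
KE+Ph     straight-ray time-of-flight delays             ray criterion
Ray       straight-ray time-of-flight delays             all on
========  =============================================  ================

Each cohort member is a synthetic calvaria-like phantom: a large-radius
spherical shell (only the cap facing the array lies inside the grid) with
randomized radius, thickness, tilt and axial crossing point, plus an
ellipsoidal target ROI near the geometric focus.  Summaries use paired
two-tailed t-tests between conditions, with no multiple-testing
correction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .array_model import SourceSignal, TransducerArray, make_cw_source, \
    rasterize_elements, wrap_phase
from .media import AcousticMedium, TargetROI, intracranial_region, \
    make_shell_phantom
from .metrics import FocusReport, compute_focus_report
from .phase_reversal import DelaySet, apply_correction, estimate_delays, \
    single_element_records
from .profiles import SimulationProfile
from .ray_baseline import RayResult, ray_delays
from .solver import KSpaceSolver

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec", "CohortRanges", "generate_cohort", "build_phantom",
    "CONDITIONS", "run_condition", "run_cohort", "CohortTable", "summarize",
]

CONDITIONS = ("NoCorr", "kPR", "KE", "KE+Ph", "Ray")

# metrics where the comparison-friendly direction is a decrease
# (positioning errors / extents); all others improve by increasing
DECREASE_IS_IMPROVEMENT = ("X_focus", "X_peak", "X_peak_err", "d_x",
                           "d_y", "d_z", "V_focus")
SUMMARY_METRICS = ("X_focus", "Y_focus", "Z_focus", "d_x", "d_y", "d_z",
                   "X_peak", "X_peak_err", "V_focus", "V_overlap",
                   "overlap_rate", "p_peak", "p_rms", "p_target",
                   "E_density", "E_target")


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic skull + ROI definition (all lengths mm)."""

    phantom_id: int
    shell_radius: float
    thickness: float
    x_cross: float              # axial position where the shell mid-surface
                                # crosses the array axis
    tilt_offset: tuple[float, float]   # lateral shell-center offsets
    roi_axes: tuple[float, float, float]
    roi_offset_vox: tuple[int, int, int]
    seed: int


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for the synthetic cohort (defaults: full scale)."""

    shell_radius: tuple[float, float] = (70.0, 90.0)
    thickness: tuple[float, float] = (4.0, 8.0)
    x_cross: tuple[float, float] = (18.0, 26.0)
    tilt_deg: float = 10.0
    roi_axes: tuple[float, float] = (9.0, 14.0)
    roi_offset_vox: int = 3

    @classmethod
    def mini(cls) -> "CohortRanges":
        """Scaled-down ranges matching the ``mini`` profile geometry.

        The shell radius stays large relative to the target depth so the
        bone cap is gently curved (like a calvaria segment) rather than a
        tight concave mirror around the focus.
        """
        return cls(shell_radius=(28.0, 40.0), thickness=(3.0, 5.0),
                   x_cross=(9.0, 13.0), tilt_deg=10.0,
                   roi_axes=(4.0, 7.0), roi_offset_vox=2)


def generate_cohort(
    n_phantoms: int,
    seed: int,
    ranges: CohortRanges = CohortRanges(),
) -> list[PhantomSpec]:
    """Deterministic cohort of phantom definitions (one RNG stream per seed)."""
    if n_phantoms < 1:
        raise ValueError("need at least one phantom")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_phantoms):
        r = rng.uniform(*ranges.shell_radius)
        tilt = np.deg2rad(rng.uniform(-ranges.tilt_deg, ranges.tilt_deg,
                                      size=2))
        out.append(PhantomSpec(
            phantom_id=i,
            shell_radius=float(r),
            thickness=float(rng.uniform(*ranges.thickness)),
            x_cross=float(rng.uniform(*ranges.x_cross)),
            tilt_offset=tuple(float(r * np.tan(t)) for t in tilt),
            roi_axes=tuple(float(rng.uniform(*ranges.roi_axes))
                           for _ in range(3)),
            roi_offset_vox=tuple(int(v) for v in rng.integers(
                -ranges.roi_offset_vox, ranges.roi_offset_vox + 1, size=3)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def _ellipsoid_mask(grid, center_vox, axes_mm) -> np.ndarray:
    idx = np.indices(grid.inner_dims, dtype=float)
    c = np.asarray(center_vox, dtype=float)
    semi = np.asarray(axes_mm, dtype=float) / 2.0 / grid.dx_mm
    d2 = sum(((idx[a] - c[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def build_phantom(
    spec: PhantomSpec, profile: SimulationProfile,
) -> tuple[np.ndarray, TargetROI, np.ndarray]:
    """Materialize a phantom: (skull mask, ROI, intracranial mask)."""
    grid = profile.grid
    focus = profile.focus_mm
    center = np.array([
        spec.x_cross + spec.shell_radius,
        focus[1] + spec.tilt_offset[0],
        focus[2] + spec.tilt_offset[1],
    ])
    skull = make_shell_phantom(
        grid, spec.shell_radius, spec.thickness, center_mm=center,
        allow_clip=True)
    roi_center = np.asarray(profile.focus_voxel) + \
        np.asarray(spec.roi_offset_vox)
    roi = TargetROI(mask=_ellipsoid_mask(grid, roi_center, spec.roi_axes),
                    grid=grid)
    # restrict the flood fill to beyond the skull's axial entry so the
    # region cannot leak around the clipped cap's rim
    axis_col = skull[:, profile.focus_voxel[1], profile.focus_voxel[2]]
    plane = int(np.argmax(axis_col)) if axis_col.any() else None
    intracranial = intracranial_region(skull, profile.focus_voxel,
                                       fallback_axial_plane=plane)
    return skull, roi, intracranial


def _condition_drive(
    condition: str,
    base_signal: SourceSignal,
    delays: DelaySet | None,
    ray: RayResult | None,
    n_elements: int,
):
    """(SourceSignal with phases, activation mask) for one condition."""
    active = np.ones(n_elements, dtype=bool)
    if condition == "NoCorr":
        return base_signal, active
    if condition in ("kPR", "KE"):
        if delays is None:
            raise ValueError(
                f"condition {condition} needs phase-reversal delays: run "
                "estimate-delays first")
        sig = apply_correction(base_signal, delays, n_elements)
    elif condition in ("KE+Ph", "Ray"):
        if ray is None:
            raise ValueError(f"condition {condition} needs ray results")
        sig = base_signal.with_phases(
            wrap_phase(base_signal.phases_for(n_elements) + ray.dphi_ray))
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if condition in ("KE", "KE+Ph"):
        if ray is None:
            raise ValueError(f"condition {condition} needs ray results")
        active = ray.active.astype(bool)
    return sig, active


def run_condition(
    profile: SimulationProfile,
    medium: AcousticMedium,
    roi: TargetROI,
    intracranial: np.ndarray | None,
    condition: str,
    array: TransducerArray,
    element_weights: list,
    delays: DelaySet | None = None,
    ray: RayResult | None = None,
) -> tuple[FocusReport, np.ndarray]:
    """One full-array run under a condition; returns (report, amplitude map)."""
    sig, active = _condition_drive(condition, profile.make_signal(),
                                   delays, ray, array.n_elements)
    src = make_cw_source(sig, profile.grid, element_weights,
                         activation=active, dt=profile.stepping.dt)
    sol = KSpaceSolver(medium, profile.stepping, dtype=profile.dtype)
    rec = sol.run(src, np.atleast_2d(profile.focus_voxel))
    report = compute_focus_report(
        rec.amplitude_map, profile.grid, roi, region_mask=intracranial,
        axis_lateral_mm=profile.axis_lateral_mm)
    return report, rec.amplitude_map


def run_cohort(
    profile: SimulationProfile,
    phantoms: list[PhantomSpec],
    conditions=("NoCorr", "kPR"),
    array_seed: int = 1,
    out_dir=None,
) -> pd.DataFrame:
    """Run every (phantom, condition) pair; returns the tidy metric table.

    Free-field single-element records are computed once and reused for all
    phantoms (they do not depend on the skull).  When ``out_dir`` is given,
    per-run reports, delay tables and a provenance manifest are written
    there.
    """
    t0 = time.time()
    array = profile.make_array(seed=array_seed)
    weights = rasterize_elements(array, profile.grid)
    signal = profile.make_signal()
    need_delays = any(c in ("kPR", "KE") for c in conditions)
    need_ray = any(c in ("KE", "KE+Ph", "Ray") for c in conditions)
    free_records = None
    if need_delays:
        water = AcousticMedium.from_skull_mask(
            profile.grid, None, f0_hz=profile.stepping.f0)
        free_records = single_element_records(
            array, water, profile.focus_voxel, profile.single_stepping,
            signal, weights, dtype=profile.dtype)
    rows = []
    for spec in phantoms:
        skull, roi, intracranial = build_phantom(spec, profile)
        medium = AcousticMedium.from_skull_mask(
            profile.grid, skull, f0_hz=profile.stepping.f0)
        delays = None
        if need_delays:
            delays = estimate_delays(
                array, medium, profile.focus_voxel,
                profile.single_stepping, signal, weights,
                free_field_records=free_records, dtype=profile.dtype)
        ray = None
        if need_ray:
            ray = ray_delays(array, skull, profile.focus_mm, profile.grid,
                             f0=profile.stepping.f0)
        for cond in conditions:
            report, amp = run_condition(
                profile, medium, roi, intracranial, cond, array, weights,
                delays=delays, ray=ray)
            row = {"phantom_id": spec.phantom_id, "condition": cond,
                   **report.as_dict()}
            row.pop("peak_voxel")
            # derived comparison quantities: axial peak-positioning error
            # relative to the intended target and pressure at the target
            row["X_peak_err"] = abs(report.X_peak
                                    - profile.focus_voxel[0]
                                    * profile.grid.dx_mm)
            row["p_target"] = float(amp[tuple(profile.focus_voxel)])
            rows.append(row)
            log.info("phantom %d %s: X_peak=%.1f V_overlap=%.1f",
                     spec.phantom_id, cond, report.X_peak,
                     report.V_overlap)
        if out_dir is not None and delays is not None:
            from pathlib import Path
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            delays.to_csv(d / f"delays_phantom{spec.phantom_id}.csv")
    df = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        df.to_csv(d / "cohort_rows.csv", index=False)
        manifest = {
            "profile": profile.name,
            "array_seed": array_seed,
            "phantoms": [asdict(p) for p in phantoms],
            "conditions": list(conditions),
            "wall_time_s": round(time.time() - t0, 2),
            "config_hash": hashlib.sha256(
                json.dumps([asdict(p) for p in phantoms],
                           sort_keys=True).encode()).hexdigest()[:16],
        }
        with open(d / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
    return df


@dataclass
class CohortTable:
    """Summary of a cohort run: stats, paired tests, direction counts."""

    rows: pd.DataFrame
    summary: pd.DataFrame          # mean/sd per (condition, metric)
    tests: pd.DataFrame            # paired t-tests between condition pairs
    percent_change: pd.DataFrame   # vs reference condition
    counts: pd.DataFrame           # improved/worsened/unchanged per metric


def summarize(
    rows: pd.DataFrame,
    reference: str = "NoCorr",
    tie_eps_mm: float | None = None,
    dx_mm: float = 1.0,
) -> CohortTable:
    """Cohort summary: mean +/- sd, paired two-tailed t-tests, % change.

    Percent change against the reference condition follows the
    reporting convention: positive means improvement, i.e. a reduction
    for positioning/extent metrics and an increase for
    overlap/energy/pressure metrics.  Per-phantom direction counts treat
    |change| < ``tie_eps_mm`` (default dx/2) as unchanged for mm-scale
    metrics.
    """
    if tie_eps_mm is None:
        tie_eps_mm = dx_mm / 2.0
    metrics = [m for m in SUMMARY_METRICS if m in rows.columns]
    conditions = list(dict.fromkeys(rows["condition"]))
    summary = rows.groupby("condition")[metrics].agg(["mean", "std"])
    wide = rows.pivot(index="phantom_id", columns="condition",
                      values=metrics)
    test_rows, pct_rows, count_rows = [], [], []
    for cond in conditions:
        if cond == reference:
            continue
        for m in metrics:
            a = wide[(m, reference)]
            b = wide[(m, cond)]
            if len(a) >= 2 and not np.allclose(a, b):
                t, p = stats.ttest_rel(a, b)
            else:
                t, p = np.nan, np.nan
            test_rows.append({"metric": m, "pair": f"{reference} vs {cond}",
                              "t": t, "p": p,
                              "degenerate": bool(np.allclose(a, b))})
            ma, mb = a.mean(), b.mean()
            if m in DECREASE_IS_IMPROVEMENT:
                pct = (ma - mb) / ma * 100.0 if ma != 0 else np.nan
            else:
                pct = (mb - ma) / ma * 100.0 if ma != 0 else np.nan
            pct_rows.append({"metric": m, "pair": f"{reference} vs {cond}",
                             "percent_improvement": pct})
            delta = b - a
            eps = tie_eps_mm if m.startswith(("X_", "Y_", "Z_", "d_")) \
                else 0.0
            if m in DECREASE_IS_IMPROVEMENT:
                improved = (delta < -eps).sum()
                worsened = (delta > eps).sum()
            else:
                improved = (delta > eps).sum()
                worsened = (delta < -eps).sum()
            count_rows.append({
                "metric": m, "pair": f"{reference} vs {cond}",
                "improved": int(improved), "worsened": int(worsened),
                "unchanged": int(len(delta) - improved - worsened)})
    return CohortTable(rows=rows, summary=summary,
                       tests=pd.DataFrame(test_rows),
                       percent_change=pd.DataFrame(pct_rows),
                       counts=pd.DataFrame(count_rows))


def plot_condition_comparison(rows: pd.DataFrame, metric: str, out_path,
                              reference: str = "NoCorr") -> None:
    """Paired per-phantom lines for one metric across conditions (PNG).

    Requires matplotlib (the ``plot`` extra); imported lazily so the
    simulation stack stays figure-free.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = rows.pivot(index="phantom_id", columns="condition",
                      values=metric)
    conds = [reference] + [c for c in wide.columns if c != reference]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    xs = np.arange(len(conds))
    for _, row in wide.iterrows():
        ax.plot(xs, [row[c] for c in conds], "o-", color="0.6", alpha=0.7)
    ax.errorbar(xs, [wide[c].mean() for c in conds],
                yerr=[wide[c].std() for c in conds], fmt="s-", color="k",
                capsize=3, zorder=3)
    ax.set_xticks(xs, conds)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
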