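"""Phase-reversal aberration correction.

The skull's higher, spatially varying sound speed advances or retards each
element's wavefront at the target; the correction measures that per-element
arrival shift and pre-compensates the drive phases.

Procedure: fire every element individually in a free field (water only),
recording the pressure at the intended target; reintroduce the skull and
repeat.  For element ``i`` the arrival-time difference (in time steps) is
the difference of the *last detected peak* positions of the two records,

    dt_i = last_peak(skull record) - last_peak(free-field record),

and the phase delay is ``dphi_i = 2 pi f0 dt_i dt_step``.  Adding
``dphi_i`` to element ``i``'s CW source phase re-aligns all transcranial
arrivals at the target.  For steady-state CW records the last-peak
difference is defined modulo one acoustic period, which is exactly the
information a single-frequency correction can use (phase modulo 2 pi).

Free-field single-element records depend only on the array and grid, never
on the skull, so they are computed once and cached across phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_model import (SourceSignal, TransducerArray,
                          make_cw_source, wrap_phase)
from .grid import TimeStepping
from .media import AcousticMedium
from .solver import KSpaceSolver

log = logging.getLogger(__name__)

__all__ = [
    "DelaySet",
    "last_peak_index",
    "arrival_time_difference",
    "phase_delay",
    "single_element_records",
    "estimate_delays",
    "apply_correction",
]


@dataclass
class DelaySet:
    """Per-element arrival-time differences and phase delays."""

    dt_steps: np.ndarray     # (n,) signed int; skull typically negative
    dphi: np.ndarray         # (n,) radians, = 2 pi f0 dt_steps dt (raw)
    reliable: np.ndarray     # (n,) bool; unreliable elements carry dphi = 0

    @property
    def n_elements(self) -> int:
        return len(self.dt_steps)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "element_index": np.arange(self.n_elements),
            "dt_steps": self.dt_steps,
            "dphi_rad": self.dphi,
            "reliable": self.reliable.astype(int),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DelaySet":
        df = pd.read_csv(path).sort_values("element_index")
        return cls(dt_steps=df["dt_steps"].to_numpy(int),
                   dphi=df["dphi_rad"].to_numpy(float),
                   reliable=df["reliable"].to_numpy(bool))

    @classmethod
    def zeros(cls, n: int) -> "DelaySet":
        return cls(dt_steps=np.zeros(n, dtype=int), dphi=np.zeros(n),
                   reliable=np.ones(n, dtype=bool))


def last_peak_index(
    waveform: np.ndarray,
    search_window: float = 0.25,
    height_frac: float = 0.5,
) -> int | None:
    """Index of the last qualifying local maximum of a pressure record.

    A qualifying peak is strictly greater than both neighbours (plateaus
    count once, at their last sample) and at least ``height_frac`` of the
    record's global maximum; the search covers the final ``search_window``
    fraction of the record.  The window rejects start-up transients, the
    height floor rejects ringing.  Returns ``None`` when no peak qualifies
    (flat or all-negative records): the caller flags the element
    unreliable.
    """
    w = np.asarray(waveform, dtype=float)
    n = len(w)
    gmax = w.max()
    if not np.isfinite(gmax) or gmax <= 0:
        return None
    floor = height_frac * gmax
    start = max(0, int(np.floor(n * (1.0 - search_window))))
    # scan from the end; a peak may have a plateau: compare against the
    # nearest differing neighbours
    for i in range(n - 1, start - 1, -1):
        if w[i] < floor:
            continue
        j = i + 1
        while j < n and w[j] == w[i]:
            j += 1
        if j < n and w[j] >= w[i]:
            continue
        if j == n:          # plateau running into the record end
            continue
        h = i - 1
        while h >= 0 and w[h] == w[i]:
            h -= 1
        if h >= 0 and w[h] >= w[i]:
            continue
        if h < 0:
            continue
        if h + 1 != i:      # plateau: report its last index
            pass
        return i
    return None


def arrival_time_difference(
    free_field_wave: np.ndarray,
    transcranial_wave: np.ndarray,
    search_window: float = 0.25,
    height_frac: float = 0.5,
) -> tuple[int, bool]:
    """Signed last-peak step difference (transcranial minus free-field).

    Returns ``(dt_steps, reliable)``; an element whose records yield no
    qualifying peak gets ``(0, False)``.  The skull's higher sound speed
    typically gives negative values (earlier arrival).
    """
    if len(free_field_wave) != len(transcranial_wave):
        raise ValueError("records must share n_steps")
    lf = last_peak_index(free_field_wave, search_window, height_frac)
    ls = last_peak_index(transcranial_wave, search_window, height_frac)
    if lf is None or ls is None:
        return 0, False
    return int(ls - lf), True


def phase_delay(dt_steps, f0: float, dt: float):
    """Phase delay ``2 pi f0 dt_steps dt`` in radians (raw, unwrapped).

    Wrapping to (-pi, pi] happens only when the delay is applied to a
    source; the raw value is retained for reporting.
    """
    return 2.0 * np.pi * f0 * np.asarray(dt_steps, dtype=float) * dt


def single_element_records(
    array: TransducerArray,
    medium: AcousticMedium,
    target_voxel,
    stepping: TimeStepping,
    signal: SourceSignal,
    element_weights: list,
    dtype=np.float32,
) -> np.ndarray:
    """Pressure records at the target for each element fired alone.

    Returns an ``(n_elements, n_steps)`` array.  One solver run per
    element; the solver object (FFT operators, property maps) is built
    once and reused.
    """
    sol = KSpaceSolver(medium, stepping, dtype=dtype)
    target_voxel = np.atleast_2d(np.asarray(target_voxel, int))
    out = np.zeros((array.n_elements, stepping.n_steps))
    for i in range(array.n_elements):
        src = make_cw_source(signal, medium.grid, [element_weights[i]],
                             dt=stepping.dt)
        try:
            rec = sol.run(src, target_voxel, t_end=stepping.t_end,
                          record_amplitude=False)
        except Exception as err:
            raise RuntimeError(
                f"single-element run failed for element {i}: {err}") from err
        out[i] = rec.series[0]
    return out


def estimate_delays(
    array: TransducerArray,
    medium_with_skull: AcousticMedium,
    target_voxel,
    stepping: TimeStepping,
    signal: SourceSignal,
    element_weights: list,
    free_field_records: np.ndarray | None = None,
    transcranial_records: np.ndarray | None = None,
    amp_floor_frac: float = 0.01,
    search_window: float = 0.25,
    height_frac: float = 0.5,
    dtype=np.float32,
) -> DelaySet:
    """Estimate per-element phase delays from paired single-element runs.

    ``free_field_records`` may be passed in from a cache (they are
    phantom-independent); ``transcranial_records`` exists to support
    injection tests where the skull run is replaced by a synthetically
    shifted free-field trace.  Elements whose transcranial steady
    amplitude at the target falls below ``amp_floor_frac`` of the median
    across elements are flagged unreliable and carry zero delay (they stay
    active: the correction keeps all elements firing).
    """
    if free_field_records is None:
        free_field_records = single_element_records(
            array, medium_with_skull.water_only(), target_voxel, stepping,
            signal, element_weights, dtype=dtype)
    if transcranial_records is None:
        transcranial_records = single_element_records(
            array, medium_with_skull, target_voxel, stepping, signal,
            element_weights, dtype=dtype)
    n = array.n_elements
    win = stepping.steps_per_period * 5
    tail = np.abs(transcranial_records[:, -win:]).max(axis=1)
    med_amp = np.median(tail)
    dt_steps = np.zeros(n, dtype=int)
    reliable = np.ones(n, dtype=bool)
    for i in range(n):
        if med_amp > 0 and tail[i] < amp_floor_frac * med_amp:
            reliable[i] = False
            continue
        d, ok = arrival_time_difference(
            free_field_records[i], transcranial_records[i],
            search_window, height_frac)
        dt_steps[i] = d
        reliable[i] &= ok
    dt_steps[~reliable] = 0
    dphi = phase_delay(dt_steps, stepping.f0, stepping.dt)
    n_bad = int((~reliable).sum())
    if n_bad:
        log.warning("%d/%d elements flagged unreliable", n_bad, n)
    return DelaySet(dt_steps=dt_steps, dphi=dphi, reliable=reliable)


def apply_correction(source: SourceSignal, delays: DelaySet,
                     n_elements: int | None = None) -> SourceSignal:
    """Fold phase delays into the CW drive: s_i(t) = A sin(w t + phi_i + dphi_i).

    An element whose transcranial arrival leads its free-field arrival
    (negative dt) receives a negative phase increment, retarding its drive
    so the arrival re-aligns with the free-field reference.
    """
    if n_elements is None:
        n_elements = delays.n_elements
    if delays.n_elements != n_elements:
        raise ValueError("delay set size != element count")
    phases = source.phases_for(n_elements)
    return source.with_phases(wrap_phase(phases + delays.dphi))
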