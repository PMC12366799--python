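"""Shared fixtures.

Solver-backed fixtures are session-scoped because each one costs real
simulation time; everything downstream (metrics, acceptance checks,
experiment invariants) reuses them instead of re-running the solver.
"""

from __future__ import annotations

import numpy as np
import pytest

from tfus.array_model import make_cw_source, rasterize_elements
from tfus.experiment import CohortRanges, generate_cohort, run_cohort
from tfus.media import AcousticMedium
from tfus.profiles import mini_profile
from tfus.solver import KSpaceSolver


@pytest.fixture(scope="session")
def mini_prof():
    return mini_profile()


@pytest.fixture(scope="session")
def mini_array(mini_prof):
    return mini_prof.make_array(seed=1)


@pytest.fixture(scope="session")
def mini_weights(mini_prof, mini_array):
    return rasterize_elements(mini_array, mini_prof.grid)


@pytest.fixture(scope="session")
def mini_free_field(mini_prof, mini_array, mini_weights):
    """Free-field full-array run on the mini profile: (record, amplitude)."""
    medium = AcousticMedium.from_skull_mask(
        mini_prof.grid, None, f0_hz=mini_prof.stepping.f0)
    src = make_cw_source(mini_prof.make_signal(), mini_prof.grid,
                         mini_weights, dt=mini_prof.stepping.dt)
    sol = KSpaceSolver(medium, mini_prof.stepping, dtype=mini_prof.dtype)
    rec = sol.run(src, np.atleast_2d(mini_prof.focus_voxel))
    return rec


@pytest.fixture(scope="session")
def mini_cohort(mini_prof):
    """8-phantom scaled-down cohort, NoCorr vs phase-reversal correction.

    The single most expensive fixture in the suite (a few minutes): it
    backs the end-to-end directional checks.
    """
    phantoms = generate_cohort(8, seed=1, ranges=CohortRanges.mini())
    rows = run_cohort(mini_prof, phantoms, ("NoCorr", "kPR"), array_seed=1)
    return rows
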