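"""Shared fixtures: small helmets and reusable simulated sessions.

Simulations use reduced sensor counts and trial numbers so the whole
suite runs quickly; the protocols and analysis settings themselves are
the full-scale defaults.
"""

from __future__ import annotations

import numpy as np
import pytest

import opmsim as om
from opmsim.geometry import ConductorSphere, CurrentDipole, SourceGrid, build_lead_fields
from opmsim.sensors import SensorModelParams


@pytest.fixture(scope="session")
def sphere():
    return ConductorSphere()


@pytest.fixture(scope="session")
def helmet8():
    return om.build_synthetic_helmet(8, seed=1)


@pytest.fixture(scope="session")
def helmet16():
    return om.build_synthetic_helmet(16, seed=0)


@pytest.fixture(scope="session")
def helmet64():
    return om.build_synthetic_helmet(64, head_radius=0.09, standoff=0.015, seed=1)


@pytest.fixture(scope="session")
def params375():
    return SensorModelParams(sample_rate=375.0)


@pytest.fixture(scope="session")
def beta_scene(helmet16, sphere):
    """Grid-aligned left-sensorimotor dipole, targeted 4-mm ROI grid and
    lead fields, reused across beamformer tests."""
    pos = np.array([-0.04, 0.016, 0.048])
    grid = SourceGrid.regular(sphere, spacing=0.004, centre=pos, half_extent=0.016)
    voxel = grid.nearest_voxel(pos)
    dipole = CurrentDipole(grid.voxel_positions[voxel], np.array([0.0, 1.0, 0.0]))
    leadfields = build_lead_fields(helmet16, grid, sphere)
    return {"grid": grid, "voxel": voxel, "dipole": dipole, "leadfields": leadfields}


def simulate_beta_erd(helmet, sphere, dipole, seed, snr=8.0, n_trials=40,
                      depth=0.5):
    """Catch-trial-like session with a single seeded beta ERD source."""
    params = SensorModelParams(sample_rate=375.0, loop_mode="closed")
    amp = om.sessions.amplitude_for_snr(helmet, sphere, dipole, (13.0, 30.0),
                                        params, snr=snr)
    schedule = om.make_visuomotor_schedule(
        seed, trial_counts={"catch": (n_trials, 0.8)}, start=1.0
    )
    sources = [om.SourceSpec(dipole, "erd", (13.0, 30.0), "catch", amp, depth,
                             (-0.3, 0.3))]
    return om.simulate_visuomotor_session(helmet, schedule, sources, params,
                                          seed=seed, sphere=sphere)
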