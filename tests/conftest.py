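"""Shared fixtures: the reference landscape and its umbrella-window set.

The 9-window aimd_like set (k = 5000 kJ/mol/nm^2, 2e5 steps per window,
seed 42) is the workhorse dataset for the WHAM recovery and error tests;
it is generated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import glycopair as gp

AIMD_CENTERS = [round(0.30 + 0.04 * i, 2) for i in range(9)]
AIMD_EDGES = np.arange(0.28, 0.68 + 1e-12, 0.005)
AIMD_K = 5000.0
AIMD_SEED = 42


@pytest.fixture(scope="session")
def thermo() -> gp.ThermoState:
    return gp.ThermoState(temperature=300.0)


@pytest.fixture(scope="session")
def aimd_potential() -> gp.ModelPotential:
    return gp.make_reference_potential("aimd_like")


@pytest.fixture(scope="session")
def aimd_windows(aimd_potential):
    cfg = gp.LangevinConfig(n_steps=200_000, seed=AIMD_SEED)
    return gp.generate_window_set(aimd_potential, AIMD_CENTERS, AIMD_K, cfg)


@pytest.fixture(scope="session")
def aimd_profile(aimd_windows, thermo):
    profile, _ = gp.solve_wham_1d(aimd_windows, AIMD_EDGES, thermo)
    profile = gp.volume_entropy_correction(profile, thermo)
    return gp.align_profile(profile, "ssp_minimum")


@pytest.fixture(scope="session")
def aimd_reference_curve(aimd_potential, aimd_profile):
    """Analytic potential on the profile grid, SSP-aligned the same way."""
    u = np.asarray(aimd_potential.energy(aimd_profile.bin_centers))
    ssp = (aimd_profile.bin_centers >= 0.45) & (aimd_profile.bin_centers <= 0.65)
    return u - u[ssp].min()
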