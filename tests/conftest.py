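"""Shared fixtures.

The expensive resource is the Monte Carlo reflectance LUT; one
moderate-statistics LUT is built per session and shared by the physics,
simulation and acceptance tests.  Plumbing tests build their own tiny LUTs.
"""

from __future__ import annotations

import numpy as np
import pytest

from swirdos.lut import build_lut
from swirdos.optics import default_table, nir_geometry, swir_geometry

SESSION_LUT_PHOTONS = 100_000
SESSION_LUT_SEED = 20_230_612


@pytest.fixture(scope="session")
def session_lut():
    """Default-grid LUT at moderate photon statistics (g=0.7, n=1.435)."""
    return build_lut(n_photons=SESSION_LUT_PHOTONS, seed=SESSION_LUT_SEED)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def swir_geom():
    return swir_geometry()


@pytest.fixture(scope="session")
def nir_geom():
    return nir_geometry()


@pytest.fixture(scope="session")
def tiny_lut():
    """Small cheap LUT for plumbing tests (coarse grids, few photons)."""
    return build_lut(
        musp_grid=np.array([0.5, 2.0, 5.0]),
        mua_grid=np.geomspace(0.001, 0.2, 6),
        n_photons=20_000,
        seed=5,
    )
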