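"""Shared fixtures: small geometries and cached simulated scans."""

from __future__ import annotations

import numpy as np
import pytest

from meshcarto.core import AnalysisConfig, ExperimentGeometry
from meshcarto.simulate import (
    CrystalSpec,
    SimulationConfig,
    random_rotation,
    reciprocal_basis,
    simulate_mesh,
    simulate_still_spots,
    typical_mx_geometry,
)

THERMOLYSIN_CELL = (93.0, 93.0, 130.0, 90.0, 90.0, 120.0)
TRYPSIN_CELL = (62.0, 64.0, 69.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def geometry() -> ExperimentGeometry:
    """Typical MX still-image geometry, single-node grid."""
    return typical_mx_geometry()


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def single_lattice_image(geometry):
    """One still image of one randomly oriented lattice (seeded)."""
    rng = np.random.default_rng(42)
    basis = reciprocal_basis(THERMOLYSIN_CELL, random_rotation(rng))
    spots, ids = simulate_still_spots([basis], geometry)
    return spots, ids, basis


@pytest.fixture(scope="session")
def three_crystal_scan():
    """A 12x14 still mesh with three disjoint crystals and its truth."""
    geom = typical_mx_geometry(grid_shape=(12, 14))
    crystals = [
        CrystalSpec(centre=(3, 3), semi_axes=(2.5, 1.5), tilt=20,
                    peak_score=12, orientation=(10, 0, 0)),
        CrystalSpec(centre=(8, 9), semi_axes=(3, 2), tilt=120,
                    peak_score=8, orientation=(0, 25, 0)),
        CrystalSpec(centre=(3, 11), semi_axes=(1.5, 1.0), tilt=0,
                    peak_score=15, orientation=(0, 0, 40)),
    ]
    cfg = SimulationConfig(geometry=geom, crystals=crystals, seed=11)
    scan, truth = simulate_mesh(cfg)
    return scan, truth, cfg


@pytest.fixture(scope="session")
def satellite_scan():
    """A large crystal with an overlapping satellite misoriented by 3 deg."""
    geom = typical_mx_geometry(grid_shape=(9, 12))
    crystals = [
        CrystalSpec(centre=(4, 5), semi_axes=(4.5, 2.5), tilt=10,
                    peak_score=10, orientation=(5, 0, 0)),
        CrystalSpec(centre=(6.5, 7.5), semi_axes=(1.5, 1.0), tilt=0,
                    peak_score=4, orientation=(5, 3, 0)),
    ]
    cfg = SimulationConfig(geometry=geom, crystals=crystals, seed=5)
    scan, truth = simulate_mesh(cfg)
    return scan, truth, cfg
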