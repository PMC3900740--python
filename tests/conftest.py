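"""Shared fixtures: small fast lattices for property tests, full defaults for
pipeline-level tests.  Everything is generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from xtal2d import ConformationModel, DimerOp, HelixRod, UnitCell2D
from xtal2d import presets


@pytest.fixture(scope="session")
def small_cell() -> UnitCell2D:
    return UnitCell2D(a=40.0, b=50.0, gamma=90.0)


@pytest.fixture(scope="session")
def small_model(small_cell) -> ConformationModel:
    """Three isotropic rods, no dimer mate: cheap forward model."""
    rods = (
        HelixRod.make("a", 10.0, 12.0, 3.0),
        HelixRod.make("b", 20.0, 30.0, 3.0),
        HelixRod.make("c", 28.0, 18.0, 3.0, mass=1.5),
    )
    return ConformationModel("apo", rods, small_cell, dimer_op=None)


def random_model(seed: int, cell: UnitCell2D, n_rods: int = 3) -> ConformationModel:
    """Random rod model for oracle comparisons (reproducible)."""
    rng = np.random.default_rng(seed)
    rods = []
    for i in range(n_rods):
        x, y = rng.uniform(5, cell.a - 5), rng.uniform(5, cell.b - 5)
        sl = rng.uniform(2.5, 4.5)
        ss = rng.uniform(2.0, sl)
        ang = rng.uniform(0, 180)
        rods.append(HelixRod.make(f"r{i}", x, y, sl, ss, ang, mass=rng.uniform(0.5, 2)))
    return ConformationModel("random", tuple(rods), cell, dimer_op=None)


@pytest.fixture(scope="session")
def apo_model() -> ConformationModel:
    return presets.build_apo_model()


@pytest.fixture(scope="session")
def bound_model() -> ConformationModel:
    return presets.build_bound_model()


@pytest.fixture(scope="session")
def regions() -> dict:
    return {r.id: r for r in presets.default_regions()}
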