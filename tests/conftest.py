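"""Shared fixtures: a validated pipe-flow solution and the comparative run.

The expensive artifacts (the Hagen-Poiseuille reference solve and the full
CGJ/SPGJ comparison at the study resolution) are session-scoped so every test
that needs a converged field reuses the same one.
"""

from __future__ import annotations

import numpy as np
import pytest

from gastroflow.fixtures import straight_tube
from gastroflow.mesh import discretize
from gastroflow.solver import BoundaryConditions, FluidProperties, SolverConfig, solve_steady

TUBE_RADIUS_MM = 12.0
TUBE_LENGTH_MM = 100.0
TUBE_CELL_MM = 2.0
# viscosity raised so the parabolic profile stays developed over the short tube
TUBE_FLUID = FluidProperties(density=998.2, viscosity=0.05)
TUBE_BC = BoundaryConditions(inlet_velocity=0.04, inlet_profile="parabolic")


@pytest.fixture(scope="session")
def tube_solution():
    geom = straight_tube(TUBE_RADIUS_MM, TUBE_LENGTH_MM)
    mesh = discretize(geom, TUBE_CELL_MM)
    field = solve_steady(mesh, TUBE_FLUID, TUBE_BC, SolverConfig())
    return geom, mesh, field


@pytest.fixture(scope="session")
def comparison():
    """Full CGJ-vs-SPGJ study at the default (coarse) resolution."""
    from gastroflow.pipeline import RunConfig, run_comparison

    report, cgj, spgj = run_comparison(RunConfig())
    return report, cgj, spgj
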