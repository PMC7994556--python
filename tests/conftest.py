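"""Shared fixtures: a session-scoped solve cache so expensive flow solutions
are computed once and reused across test modules."""

from __future__ import annotations

import pytest

from stenoflow import (BLOOD_GPL, BLOOD_NEWTONIAN, WATER, build_geometry,
                       generate_grid, make_operating_point,
                       make_poiseuille_case, platelet_trajectory_profile,
                       shear_rate_field, solve_flow)

FLUIDS = {"water": WATER, "blood": BLOOD_NEWTONIAN, "blood-gpl": BLOOD_GPL}

#: grid for the scaled-down reproduction runs (default case comparisons)
ACC_GRID = (384, 96)
#: grid for property sweeps (monotonicity / insensitivity trends)
PROP_GRID = (256, 64)


@pytest.fixture(scope="session")
def solve_case():
    """Cached end-to-end solve: returns (flow, shear map, platelet profile)."""
    cache = {}

    def _solve(S=0.8, alpha=85.0, placement="eccentric", gamma0=1000.0,
               fluid="blood", nx=PROP_GRID[0], ny=PROP_GRID[1]):
        key = (S, alpha, placement, gamma0, fluid, nx, ny)
        if key not in cache:
            geom = build_geometry(S=S, alpha=alpha, placement=placement)
            grid = generate_grid(geom, nx, ny)
            fl = FLUIDS[fluid]
            flow = solve_flow(geom, fl, make_operating_point(gamma0, fl), grid)
            smap = shear_rate_field(flow)
            prof = platelet_trajectory_profile(flow, smap) if S > 0 else None
            cache[key] = (flow, smap, prof)
        return cache[key]

    return _solve


@pytest.fixture(scope="session")
def poiseuille_flow():
    """Straight-channel solve with the attached plane-Poiseuille closed form."""
    case = make_poiseuille_case(Y0=100.0, gamma0=1000.0)
    grid = generate_grid(case.geom, 32, 64)
    flow = solve_flow(case.geom, case.fluid, case.op, grid)
    return case, grid, flow


@pytest.fixture(scope="session")
def mesh_report():
    """Default grid-convergence study, shared between verification tests."""
    from stenoflow import mesh_sensitivity
    return mesh_sensitivity()
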