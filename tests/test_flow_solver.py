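"""Steady-flow solver: analytic oracle, conservation, linearity, robustness."""

from __future__ import annotations

import numpy as np
import pytest

from stenoflow import (BLOOD_GPL, BLOOD_NEWTONIAN, ConstitutiveTable,
                       SolverConfig, SolverError, apparent_viscosity,
                       build_geometry, developed_profile, generate_grid,
                       make_operating_point, solve_flow)

from conftest import ACC_GRID


def test_poiseuille_velocity_profile(poiseuille_flow):
    case, grid, flow = poiseuille_flow
    y = grid.Y[grid.nx // 2, :] * 1e-6
    u_ex = case.closed_form["u"](y)
    assert np.max(np.abs(flow.u[grid.nx // 2, :] - u_ex)) / u_ex.max() < 0.01
    assert flow.converged and flow.iterations <= 10


def test_poiseuille_pressure_gradient(poiseuille_flow):
    case, grid, flow = poiseuille_flow
    w = case.geom.Y0 * 1e-6
    dpdx_exact = -12.0 * case.fluid.mu * case.closed_form["q"] / w ** 3
    x = grid.X[:, 0] * 1e-6
    dpdx = (flow.P[-1, grid.ny // 2] - flow.P[0, grid.ny // 2]) / (x[-1] - x[0])
    assert dpdx == pytest.approx(dpdx_exact, rel=1e-6)


def test_station_flux_conservation(solve_case):
    flow = solve_case(placement="eccentric", gamma0=2000.0,
                      nx=ACC_GRID[0], ny=ACC_GRID[1])[0]
    assert flow.mass_imbalance < 1e-8
    assert np.max(np.abs(flow.station_fluxes() - flow.q2d)) / flow.q2d < 1e-8
    # independent trapezoid-integrated velocity flux agrees to quadrature error
    assert np.max(np.abs(flow.velocity_fluxes() / flow.q2d - 1.0)) < 0.01


def test_no_slip_walls(solve_case):
    flow = solve_case(placement="eccentric", gamma0=2000.0,
                      nx=ACC_GRID[0], ny=ACC_GRID[1])[0]
    assert np.max(np.abs(flow.u[:, 0])) <= 1e-12 * flow.U_ref
    assert np.max(np.abs(flow.v[:, 0])) <= 1e-12 * flow.U_ref
    assert np.max(np.abs(flow.u[:, -1])) <= 1e-12 * flow.U_ref


def test_stokes_regime_linearity(solve_case):
    """Scaling the flow rate 20-fold (gamma0 150 -> 3000) scales the whole
    velocity field by 20 to within a few percent (Re stays order one)."""
    f150 = solve_case(placement="eccentric", gamma0=150.0,
                      nx=ACC_GRID[0], ny=ACC_GRID[1])[0]
    f3000 = solve_case(placement="eccentric", gamma0=3000.0,
                       nx=ACC_GRID[0], ny=ACC_GRID[1])[0]
    err = np.max(np.abs(f3000.u - 20.0 * f150.u)) / np.max(np.abs(f3000.u))
    assert err < 0.03


def test_gpl_developed_channel_matches_oracle():
    """Shear-thinning straight-channel solve reproduces the 1D constitutive
    oracle profile it was fed at the inlet, everywhere downstream."""
    geom = build_geometry(S=0.0, alpha=85.0)
    grid = generate_grid(geom, 32, 64)
    op = make_operating_point(1000.0, BLOOD_GPL)
    flow = solve_flow(geom, BLOOD_GPL, op, grid)
    dev = np.max(np.abs(flow.u[grid.nx // 2, :] - flow.u[0, :])) / flow.u[0, :].max()
    assert dev < 0.01


def test_developed_profile_newtonian_exact():
    eta = np.linspace(0, 1, 65)
    u, psi, om = developed_profile(BLOOD_NEWTONIAN, 1000.0, 100e-6, eta)
    assert om[0] == pytest.approx(-1000.0)      # wall shear = gamma0
    assert psi[-1] == pytest.approx(1000.0 * (100e-6) ** 2 / 6.0, rel=1e-12)
    assert u[0] == 0.0 and u[-1] == 0.0


def test_developed_profile_gpl_flux():
    eta = np.linspace(0, 1, 65)
    u, psi, om = developed_profile(BLOOD_GPL, 800.0, 100e-6, eta)
    q = 800.0 * (100e-6) ** 2 / 6.0
    assert psi[-1] == pytest.approx(q, rel=1e-9)
    # shear thinning flattens the core: higher peak-to-mean than a parabola? no:
    # plug-like profile has LOWER peak velocity than the parabola at equal flux
    assert u.max() < 1.5 * q / 100e-6


def test_constitutive_table_monotone_and_consistent():
    table = ConstitutiveTable(BLOOD_GPL)
    g = np.logspace(-2, 5, 200)
    tau = table.mu_of_gamma(g) * g
    assert np.all(np.diff(tau) > 0), "monotonized stress curve must increase"
    # on the plateau the table matches the raw law
    assert table.mu_of_gamma(2000.0) == pytest.approx(
        apparent_viscosity(BLOOD_GPL, 2000.0), rel=1e-4)
    # inverse lookup consistency
    g0 = np.array([5.0, 500.0, 5e4])
    np.testing.assert_allclose(table.gamma_of_tau(table.mu_of_gamma(g0) * g0),
                               g0, rtol=1e-3)


def test_nonconvergence_raises_with_history():
    geom = build_geometry(S=0.8, alpha=85.0)
    grid = generate_grid(geom, 48, 12)
    op = make_operating_point(1000.0, BLOOD_NEWTONIAN)
    with pytest.raises(SolverError) as exc:
        solve_flow(geom, BLOOD_NEWTONIAN, op, grid,
                   SolverConfig(max_iter=2, compute_pressure=False))
    assert len(exc.value.residual_history) >= 1


def test_input_validation():
    geom = build_geometry(S=0.8, alpha=85.0)
    grid = generate_grid(geom, 16, 8)
    with pytest.raises(ValueError):
        op0 = make_operating_point(0.0, BLOOD_NEWTONIAN)
        solve_flow(geom, BLOOD_NEWTONIAN, op0, grid)
    with pytest.raises(ValueError, match="outside the resolved regime"):
        g2 = build_geometry(S=0.975, alpha=85.0)
        solve_flow(g2, BLOOD_NEWTONIAN, make_operating_point(100.0, BLOOD_NEWTONIAN),
                   generate_grid(g2, 16, 8))
    with pytest.raises(ValueError):
        SolverConfig(relax_u=0.0)
    with pytest.raises(ValueError):
        SolverConfig(convection_scheme="quick")
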