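"""Shear maps, wall stresses, streamlines and platelet shear histories."""

from __future__ import annotations

import numpy as np
import pytest

from stenoflow import (peak_summary, platelet_trajectory_profile,
                       shear_rate_field, trace_streamline)
from stenoflow._numerics import shear_rate_invariant

from conftest import ACC_GRID


def test_shear_invariant_canonical_states():
    # plane shear du/dy = g  ->  gamma = |g|
    assert shear_rate_invariant(0.0, 4.2, 0.0, 0.0) == pytest.approx(4.2)
    assert shear_rate_invariant(0.0, -4.2, 0.0, 0.0) == pytest.approx(4.2)
    # uniform translation and rigid-body rotation are strain free
    assert shear_rate_invariant(0.0, 0.0, 0.0, 0.0) == 0.0
    assert shear_rate_invariant(0.0, -0.9, 0.9, 0.0) == 0.0
    # pure extension u = ex, v = -ey -> gamma = 2e (2D incompressible)
    assert shear_rate_invariant(0.5, 0.0, 0.0, -0.5) == pytest.approx(1.0)


def test_shear_field_poiseuille(poiseuille_flow):
    case, grid, flow = poiseuille_flow
    smap = shear_rate_field(flow)
    eta = np.linspace(0, 1, grid.ny + 1)
    g_exact = 1000.0 * np.abs(1.0 - 2.0 * eta)
    err = np.max(np.abs(smap.gamma[grid.nx // 2, :] - g_exact)) / 1000.0
    assert err < 0.01


def test_wall_stress_uniform_on_straight_channel(poiseuille_flow):
    case, grid, flow = poiseuille_flow
    smap = shear_rate_field(flow)
    tau = smap.walls["bottom"]["tau_Pa"]
    mid = slice(4, -4)
    assert np.max(np.abs(tau[mid] - case.fluid.mu * 1000.0)) \
        / (case.fluid.mu * 1000.0) < 0.01


def test_streamline_straight_channel_horizontal(poiseuille_flow):
    _, grid, flow = poiseuille_flow
    sl = trace_streamline(flow, (-350.0, 30.0))
    assert np.max(np.abs(sl[:, 1] - 30.0)) < 1e-6
    assert sl[-1, 0] >= grid.X[-2, 0]


def test_streamline_concentric_centerline(solve_case):
    flow = solve_case(placement="concentric", gamma0=2000.0,
                      nx=ACC_GRID[0], ny=ACC_GRID[1])[0]
    geom = flow.geom
    sl = trace_streamline(flow, (geom.x_min + 5.0, geom.Y0 / 2.0))
    assert np.max(np.abs(sl[:, 1] - geom.Y0 / 2.0)) < 1e-3 * geom.Y0


def test_streamline_speed_never_vanishes(solve_case):
    flow, smap, _ = solve_case(placement="eccentric", gamma0=2000.0,
                               nx=ACC_GRID[0], ny=ACC_GRID[1])
    sl = trace_streamline(flow, (flow.geom.x_min + 5.0, 92.0))
    from stenoflow.hemodynamics_post import _VelocitySampler
    sampler = _VelocitySampler(flow)
    speeds = np.array([np.hypot(*sampler(x, y)) for x, y in sl[::25]])
    assert speeds.min() > 1e-12 * flow.U_ref


def test_streamline_seed_validation(poiseuille_flow):
    _, _, flow = poiseuille_flow
    with pytest.raises(ValueError):
        trace_streamline(flow, (-350.0, -5.0))       # below the wall
    with pytest.raises(ValueError):
        trace_streamline(flow, (1e4, 50.0))          # outside the channel


def test_platelet_profile_default_case(solve_case):
    flow, smap, prof = solve_case(placement="eccentric", gamma0=2000.0,
                                  nx=ACC_GRID[0], ny=ACC_GRID[1])
    # the peak shear rate sits at the stenosis apex
    assert abs(prof.gamma_max_x) < 5.0
    assert abs(prof.min_wall_clearance - 1.0) <= 0.05
    # the gradient history integrates back to the sampled shear history
    integ = np.trapezoid(prof.gamma_prime, prof.x_um)
    span = prof.gamma_s[-1] - prof.gamma_s[0]
    assert abs(integ - span) < 0.01 * (prof.gamma_s.max() - prof.gamma_s.min())


def test_straight_channel_has_flat_shear_history(poiseuille_flow):
    _, _, flow = poiseuille_flow
    smap = shear_rate_field(flow)
    prof = platelet_trajectory_profile(flow, smap, clearance_um=1.0)
    # 1 um off a straight wall: gamma is constant, so its gradient vanishes
    assert np.max(np.abs(prof.gamma_prime)) < 1e-3 * prof.gamma_s.mean()


def test_wall_peak_inside_stenotic_region(solve_case):
    flow, smap, _ = solve_case(placement="eccentric", gamma0=2000.0,
                               nx=ACC_GRID[0], ny=ACC_GRID[1])
    assert abs(smap.tau_max_x) <= flow.geom.hump_half_footprint


def test_doubling_flow_doubles_wall_stress(solve_case):
    s1 = solve_case(placement="eccentric", gamma0=1000.0)[1]
    s2 = solve_case(placement="eccentric", gamma0=2000.0)[1]
    tau1 = s1.walls["bottom"]["tau_Pa"]
    tau2 = s2.walls["bottom"]["tau_Pa"]
    core = tau1 > 0.05 * tau1.max()
    assert np.max(np.abs(tau2[core] / tau1[core] - 2.0)) / 2.0 < 0.03


def test_peak_summary_consistency(solve_case):
    flow, smap, prof = solve_case(placement="eccentric", gamma0=2000.0,
                                  nx=ACC_GRID[0], ny=ACC_GRID[1])
    rec = peak_summary(prof, smap)
    assert all(rec[k] >= 0 for k in ("gamma_max", "gamma_prime_max",
                                     "tau_max_Pa", "gamma_max_field"))
    assert rec["gamma_max"] <= rec["gamma_max_field"] * (1 + 1e-9)
    assert rec["tau_max_dyn_cm2"] == pytest.approx(10.0 * rec["tau_max_Pa"])
    # Newtonian constitutive identity: tau_max equals mu times the peak wall
    # shear rate by construction
    wall = smap.walls[smap.tau_max_wall]
    assert smap.tau_max == pytest.approx(
        flow.fluid.mu * wall["gamma_wall"].max(), rel=1e-6)


def test_profile_rejects_narrow_throat():
    import stenoflow
    geom = stenoflow.build_geometry(S=0.8, alpha=85.0)
    # clearance wider than half the throat cannot be bracketed
    grid = stenoflow.generate_grid(geom, 96, 24)
    fl = stenoflow.BLOOD_NEWTONIAN
    flow = stenoflow.solve_flow(geom, fl,
                                stenoflow.make_operating_point(500.0, fl), grid)
    with pytest.raises(ValueError):
        platelet_trajectory_profile(flow, clearance_um=15.0)
    with pytest.raises(ValueError):
        platelet_trajectory_profile(flow, clearance_um=-1.0)
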