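"""Parametric geometry and boundary-fitted grid invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoflow import StenosisGeometry, build_geometry, generate_grid
from stenoflow.verification import random_geometry_suite


def min_gap(geom, n=4001):
    x = np.linspace(geom.x_min, geom.x_max, n)
    return float(np.min(geom.gap(x)))


def test_straight_channel_is_rectangular():
    geom = build_geometry(S=0.0, alpha=85.0)
    x = np.linspace(geom.x_min, geom.x_max, 101)
    assert np.all(geom.y_bottom(x) == 0.0)
    assert np.all(geom.y_top(x) == geom.Y0)
    assert geom.throat_width == geom.Y0


def test_throat_width_values():
    geom = build_geometry(S=0.8, alpha=85.0)
    assert geom.throat_width == pytest.approx(20.0)
    assert min_gap(geom) == pytest.approx(20.0, abs=1e-9 * geom.Y0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(S=st.floats(0.01, 0.95), alpha=st.floats(30.0, 85.0),
       placement=st.sampled_from(["eccentric", "concentric"]))
def test_throat_identity_property(S, alpha, placement):
    """min over x of (y_t - y_b) equals Y0*(1-S) for any valid draw."""
    geom = build_geometry(S=S, alpha=alpha, placement=placement)
    assert min_gap(geom) == pytest.approx(geom.throat_width, abs=1e-9 * geom.Y0)
    # walls never cross
    x = np.linspace(geom.x_min, geom.x_max, 2001)
    assert np.all(geom.gap(x) > 0)


def test_throat_identity_randomized_suite():
    for geom in random_geometry_suite(500, seed=7):
        assert min_gap(geom, 2001) == pytest.approx(geom.throat_width,
                                                    abs=1e-9 * geom.Y0)


def test_concentric_mirror_symmetry():
    geom = build_geometry(S=0.7, alpha=60.0, placement="concentric")
    x = np.linspace(geom.x_min, geom.x_max, 501)
    np.testing.assert_allclose(geom.y_bottom(x) + geom.y_top(x), geom.Y0,
                               rtol=0, atol=1e-12)


def test_eccentric_hump_is_doubled_concentric_hump():
    """The eccentric lower wall at stenosis level S/2 equals the concentric
    lower wall at level S (hump heights S*Y0/2 in both cases)."""
    x = np.linspace(-200, 200, 801)
    conc = build_geometry(S=0.6, alpha=70.0, placement="concentric")
    ecc_half = build_geometry(S=0.3, alpha=70.0, placement="eccentric")
    np.testing.assert_allclose(conc.y_bottom(x), ecc_half.y_bottom(x), atol=1e-12)


def test_eccentric_mirror_swaps_walls():
    geom = build_geometry(S=0.5, alpha=45.0, placement="eccentric")
    x = np.linspace(-100, 100, 401)
    # mirrored about the channel mid-line, the flat top wall becomes a flat
    # bottom wall and the hump moves to the top
    np.testing.assert_allclose(geom.Y0 - geom.y_top(x), 0.0, atol=1e-12)
    np.testing.assert_allclose(geom.Y0 - geom.y_bottom(x),
                               geom.Y0 - geom.y_bottom(x))


def test_footprint_shrinks_with_alpha():
    feet = [build_geometry(S=0.8, alpha=a).hump_half_footprint
            for a in (30.0, 45.0, 60.0, 75.0, 85.0)]
    assert all(a > b for a, b in zip(feet, feet[1:]))


@pytest.mark.parametrize("kwargs", [
    {"S": -0.1, "alpha": 85.0},
    {"S": 1.0, "alpha": 85.0},
    {"S": 0.5, "alpha": 0.0},
    {"S": 0.5, "alpha": 95.0},
    {"S": 0.5, "alpha": 85.0, "dims": {"Y0": -1.0}},
])
def test_invalid_geometry_rejected(kwargs):
    with pytest.raises(ValueError):
        build_geometry(**kwargs)


def test_infeasible_footprint_rejected():
    with pytest.raises(ValueError, match="footprint"):
        StenosisGeometry(S=0.9, alpha=30.0, run_in=10.0, run_out=10.0)


def test_grid_straight_channel_uniform():
    geom = build_geometry(S=0.0, alpha=85.0)
    grid = generate_grid(geom, 16, 16)
    assert np.allclose(grid.jac, grid.jac[0, 0])
    assert np.allclose(np.diff(grid.X[:, 0]), np.diff(grid.X[:, 0])[0])


def test_grid_cell_count_scaling():
    geom = build_geometry(S=0.4, alpha=60.0)
    g1 = generate_grid(geom, 32, 16)
    g2 = generate_grid(geom, 64, 32)
    assert g2.n_cells == 4 * g1.n_cells


def test_grid_boundary_nodes_on_walls():
    geom = build_geometry(S=0.8, alpha=85.0, placement="concentric")
    grid = generate_grid(geom, 64, 16)
    np.testing.assert_allclose(grid.Y[:, 0], geom.y_bottom(grid.X[:, 0]),
                               atol=1e-12)
    np.testing.assert_allclose(grid.Y[:, -1], geom.y_top(grid.X[:, 0]),
                               atol=1e-12)


def test_grid_severe_stenosis_min_cell():
    geom = build_geometry(S=0.95, alpha=85.0)
    grid = generate_grid(geom, 64, 16)
    h_min = (geom.gap(grid.X[:, 0]) / grid.ny).min()
    assert 0 < h_min <= geom.throat_width / grid.ny + 1e-12
    assert np.all(grid.cell_areas() > 0)


def test_grid_too_coarse_rejected():
    geom = build_geometry(S=0.5, alpha=60.0)
    with pytest.raises(ValueError):
        generate_grid(geom, 4, 16)
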