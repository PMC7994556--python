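"""Constitutive viscosity laws: exact values, limits and shear-thinning shape."""

from __future__ import annotations

import numpy as np
import pytest

from stenoflow import (BLOOD_CARREAU, BLOOD_CASSON, BLOOD_GPL,
                       BLOOD_NEWTONIAN, BLOOD_POWER_LAW, WATER, FluidModel,
                       apparent_viscosity, viscosity_benchmark)
from stenoflow.rheology import gpl_consistency, gpl_index


@pytest.mark.parametrize("fluid,gamma,expected,rel", [
    (WATER, 1.0, 0.001003, 1e-12),
    (WATER, 5000.0, 0.001003, 1e-12),
    (BLOOD_NEWTONIAN, 123.0, 0.00345, 1e-12),
    # high-shear plateau of the generalized power-law blood model
    (BLOOD_GPL, 1000.0, 0.00345, 1e-3),
    # hand evaluation at gamma = 1: K = 0.24107, n = 0.55833, mu = K*1^(n-1)
    (BLOOD_GPL, 1.0, 0.24107, 1e-4),
])
def test_apparent_viscosity_values(fluid, gamma, expected, rel):
    assert apparent_viscosity(fluid, gamma) == pytest.approx(expected, rel=rel)


def test_gpl_parameters_at_unit_shear():
    assert gpl_consistency(1.0) == pytest.approx(0.24107, rel=1e-4)
    assert gpl_index(1.0) == pytest.approx(0.55833, rel=1e-4)


def test_gpl_asymptotic_limits():
    """K -> mu_inf, n -> 1 at high shear; K -> mu_inf + d_mu, n -> 1 - d_n
    at vanishing shear (evaluated at 1e6 and 1e-6 1/s)."""
    assert gpl_consistency(1e6) == pytest.approx(0.00345, rel=1e-3)
    assert gpl_index(1e6) == pytest.approx(1.0, rel=1e-3)
    assert gpl_consistency(1e-6) == pytest.approx(0.25345, rel=1e-3)
    assert gpl_index(1e-6) == pytest.approx(0.55, rel=1e-3)


def test_gpl_shear_thinning_monotone():
    g = np.logspace(-3, 6, 300)
    mu = apparent_viscosity(BLOOD_GPL, g)
    assert np.all(np.diff(mu) <= 1e-15)
    assert np.all(np.isfinite(mu)) and np.all(mu > 0)


def test_gamma_floor_keeps_viscosity_finite():
    mu = apparent_viscosity(BLOOD_GPL, np.array([0.0, 1e-9, 1e-3]))
    assert np.all(np.isfinite(mu)) and np.all(mu > 0)
    # below the floor everything evaluates at the floor
    assert mu[0] == mu[1] == mu[2]


def test_benchmark_table_model_shapes():
    g = np.geomspace(50.0, 1050.0, 60)
    table = viscosity_benchmark(
        [BLOOD_NEWTONIAN, BLOOD_GPL, BLOOD_CARREAU, BLOOD_CASSON,
         BLOOD_POWER_LAW], g)
    assert list(table.columns[:1]) == ["gamma_s_inv"]
    # Newtonian flat; GPL non-increasing and on its plateau beyond 500 1/s
    assert table["blood"].nunique() == 1
    gpl = table["blood-gpl"].to_numpy()
    assert np.all(np.diff(gpl) <= 1e-15)
    plateau = table.loc[table.gamma_s_inv >= 500.0, "blood-gpl"]
    assert np.all(np.abs(plateau / 0.00345 - 1.0) < 0.05)
    # the simple power law never plateaus: strictly decreasing everywhere
    pl = table["blood-power-law"].to_numpy()
    assert np.all(np.diff(pl) < 0)
    # all models positive over the whole benchmark window
    assert (table.iloc[:, 1:] > 0).all().all()


def test_benchmark_input_validation():
    with pytest.raises(ValueError):
        viscosity_benchmark([], [1.0, 2.0])
    with pytest.raises(ValueError):
        viscosity_benchmark([WATER], [2.0, 1.0])
    with pytest.raises(ValueError):
        viscosity_benchmark([WATER], [-1.0, 1.0])


def test_fluid_model_validation():
    with pytest.raises(ValueError):
        FluidModel("bad", rho=-1.0, mu=1e-3)
    with pytest.raises(ValueError):
        FluidModel("bad", rho=1000.0, law="maxwellian")
    with pytest.raises(ValueError):
        FluidModel("bad", rho=1000.0)     # newtonian without mu
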