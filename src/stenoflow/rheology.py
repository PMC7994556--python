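"""Constitutive viscosity models for the working fluids.

Blood is shear thinning below roughly 1000 1/s and close to Newtonian above.
The primary non-Newtonian law here is the Generalized Power-Law (GPL),

    mu = K(gamma) * gamma**(n(gamma) - 1)
    K  = mu_inf + d_mu * exp(-(1 + gamma/a) * exp(-b/gamma))
    n  = n_inf  - d_n  * exp(-(1 + gamma/c) * exp(-d/gamma))

which plateaus at mu_inf = 0.00345 Pa s for gamma > ~500 1/s and rises toward
(mu_inf + d_mu) with index (n_inf - d_n) as gamma -> 0.

Carreau, Casson and simple Power-Law models are provided for the multi-model
viscosity benchmark.  Their parameter sets are standard literature values for
~40-45% hematocrit blood and are *not* authoritative calibrations:

    Carreau    mu0=0.056 Pa s, mu_inf=0.00345 Pa s, lambda=3.313 s, n=0.3568
    Casson     tau_y=0.005 Pa, mu_p=0.00345 Pa s
    Power-Law  k=0.035 Pa s^n, n=0.6
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluidModel", "apparent_viscosity", "viscosity_benchmark",
    "WATER", "BLOOD_NEWTONIAN", "BLOOD_GPL", "GPL_DEFAULTS",
    "BLOOD_CARREAU", "BLOOD_CASSON", "BLOOD_POWER_LAW", "GAMMA_FLOOR",
]

LAWS = ("newtonian", "gpl", "carreau", "casson", "power_law")

#: shear-rate floor (1/s) guarding the gamma**(n-1) divergence at gamma -> 0
GAMMA_FLOOR = 1e-3

GPL_DEFAULTS = {
    "mu_inf": 0.00345,  # Pa s
    "n_inf": 1.0,
    "d_mu": 0.25,       # Pa s
    "d_n": 0.45,
    "a": 50.0,          # 1/s
    "b": 3.0,           # 1/s
    "c": 50.0,          # 1/s
    "d": 4.0,           # 1/s
}

CARREAU_DEFAULTS = {"mu0": 0.056, "mu_inf": 0.00345, "lam": 3.313, "n": 0.3568}
CASSON_DEFAULTS = {"tau_y": 0.005, "mu_p": 0.00345}
POWER_LAW_DEFAULTS = {"k": 0.035, "n": 0.6}


@dataclass(frozen=True)
class FluidModel:
    """Density plus a viscosity law (constant or shear-rate dependent)."""

    name: str
    rho: float                      # kg/m^3
    law: str = "newtonian"
    mu: float | None = None         # Pa s, Newtonian only
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError(f"density rho={self.rho} must be positive")
        if self.law not in LAWS:
            raise ValueError(f"unknown viscosity law {self.law!r}; expected one of {LAWS}")
        if self.law == "newtonian":
            if self.mu is None or self.mu <= 0:
                raise ValueError("newtonian fluid needs a positive constant viscosity mu")
        else:
            defaults = {"gpl": GPL_DEFAULTS, "carreau": CARREAU_DEFAULTS,
                        "casson": CASSON_DEFAULTS, "power_law": POWER_LAW_DEFAULTS}[self.law]
            merged = {**defaults, **self.params}
            object.__setattr__(self, "params", merged)

    @property
    def mu_ref(self) -> float:
        """Reference (high-shear) viscosity in Pa s, used for Re and scaling."""
        if self.law == "newtonian":
            return self.mu
        if self.law == "gpl":
            return self.params["mu_inf"]
        if self.law == "carreau":
            return self.params["mu_inf"]
        if self.law == "casson":
            return self.params["mu_p"]
        return self.params["k"]  # power_law has no plateau; consistency index


WATER = FluidModel("water", rho=998.0, mu=0.001003)
BLOOD_NEWTONIAN = FluidModel("blood", rho=1060.0, mu=0.00345)
BLOOD_GPL = FluidModel("blood-gpl", rho=1060.0, law="gpl")
BLOOD_CARREAU = FluidModel("blood-carreau", rho=1060.0, law="carreau")
BLOOD_CASSON = FluidModel("blood-casson", rho=1060.0, law="casson")
BLOOD_POWER_LAW = FluidModel("blood-power-law", rho=1060.0, law="power_law")


def gpl_consistency(gamma, params: dict | None = None):
    """Consistency index K(gamma) in Pa s^n."""
    p = params or GPL_DEFAULTS
    g = np.asarray(gamma, dtype=float)
    return p["mu_inf"] + p["d_mu"] * np.exp(-(1.0 + g / p["a"]) * np.exp(-p["b"] / g))


def gpl_index(gamma, params: dict | None = None):
    """Power-law index n(gamma), dimensionless."""
    p = params or GPL_DEFAULTS
    g = np.asarray(gamma, dtype=float)
    return p["n_inf"] - p["d_n"] * np.exp(-(1.0 + g / p["c"]) * np.exp(-p["d"] / g))


def apparent_viscosity(fluid: FluidModel, gamma, gamma_floor: float = GAMMA_FLOOR):
    """Apparent dynamic viscosity (Pa s) at shear rate ``gamma`` (1/s).

    ``gamma`` is clamped from below at ``gamma_floor`` before evaluating the
    shear-dependent laws, so quiescent regions stay finite.
    """
    g = np.maximum(np.asarray(gamma, dtype=float), gamma_floor)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    p = fluid.params
    if fluid.law == "newtonian":
        mu = np.full_like(g, fluid.mu)
    elif fluid.law == "gpl":
        mu = gpl_consistency(g, p) * g ** (gpl_index(g, p) - 1.0)
    elif fluid.law == "carreau":
        mu = p["mu_inf"] + (p["mu0"] - p["mu_inf"]) * (
            1.0 + (p["lam"] * g) ** 2) ** ((p["n"] - 1.0) / 2.0)
    elif fluid.law == "casson":
        mu = (np.sqrt(p["tau_y"] / g) + np.sqrt(p["mu_p"])) ** 2
    elif fluid.law == "power_law":
        mu = p["k"] * g ** (p["n"] - 1.0)
    else:  # pragma: no cover - guarded by FluidModel
        raise ValueError(f"unknown viscosity law {fluid.law!r}")
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise FloatingPointError("viscosity evaluation produced non-positive values")
    return float(mu[0]) if scalar else mu


def viscosity_benchmark(models, gamma_grid) -> pd.DataFrame:
    """Tabulate mu(gamma) for several constitutive models.

    Returns a tidy frame with a ``gamma_s_inv`` column and one Pa s column per
    model, suitable for the multi-model benchmark plot or CSV export.
    """
    models = list(models)
    if not models:
        raise ValueError("empty model list")
    g = np.asarray(gamma_grid, dtype=float)
    if g.size == 0 or np.any(g <= 0):
        raise ValueError("gamma_grid must be positive")
    if np.any(np.diff(g) <= 0):
        raise ValueError("gamma_grid must be strictly increasing")
    data = {"gamma_s_inv": g}
    for m in models:
        data[m.name] = apparent_viscosity(m, g)
    return pd.DataFrame(data)
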