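"""Closed-form operating-point calculators for the rectangular microchannel.

The imposed quantity in the experiments is the bulk (wall) shear rate
``gamma0`` of the unobstructed channel; the pump flow rate follows from the
rectangular-duct relation

    Q = 0.12 * A * D_h * gamma0 / lambda            (Q in uL/min)

evaluated in the device-engineering unit convention A in um^2, D_h in m,
gamma0 in 1/s (0.12 collects the unit conversions; the fully SI-consistent
equivalent is ``Q[m^3/s] = 2 A D_h gamma0 / lambda``).  The shape factor

    lambda = 24 / [(1 - 0.351*Y0/Z0) * (1 + Y0/Z0)]**2

reduces to the plane-Poiseuille value 24 as Y0/Z0 -> 0.

Reynolds and Womersley numbers justify the steady laminar modelling regime:
Re stays well below 2300 over the whole study envelope, and Wo << 1 even at a
120 bpm pulse, so the flow is solved as steady.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .rheology import FluidModel

__all__ = ["OperatingPoint", "cross_section", "flow_rate", "flow_rate_si",
           "reynolds", "womersley", "make_operating_point"]


def cross_section(Y0: float, Z0: float) -> dict:
    """Cross-section descriptors: area (um^2), hydraulic diameter (m), shape factor.

    Parameters are the channel width and height in micrometres.
    """
    if Y0 <= 0 or Z0 <= 0:
        raise ValueError(f"cross-section dims must be positive, got Y0={Y0}, Z0={Z0}")
    A_um2 = Y0 * Z0
    Dh_m = 2.0 * A_um2 / (Y0 + Z0) * 1e-6
    r = Y0 / Z0
    lam = 24.0 / ((1.0 - 0.351 * r) * (1.0 + r)) ** 2
    return {"A_um2": A_um2, "Dh_m": Dh_m, "lam": lam}


def flow_rate(gamma0: float, Y0: float = 100.0, Z0: float = 130.0) -> float:
    """Flow rate in uL/min producing bulk wall shear rate ``gamma0`` (1/s).

    Mixed-unit device convention (A in um^2, D_h in m); see module docstring.
    """
    if gamma0 < 0:
        raise ValueError("gamma0 must be non-negative")
    cs = cross_section(Y0, Z0)
    return 0.12 * cs["A_um2"] * cs["Dh_m"] * gamma0 / cs["lam"]


def flow_rate_si(gamma0: float, Y0: float = 100.0, Z0: float = 130.0) -> float:
    """Fully-SI variant of :func:`flow_rate`: Q in m^3/s with A in m^2."""
    if gamma0 < 0:
        raise ValueError("gamma0 must be non-negative")
    cs = cross_section(Y0, Z0)
    A_m2 = cs["A_um2"] * 1e-12
    return 2.0 * A_m2 * cs["Dh_m"] * gamma0 / cs["lam"]


def reynolds(gamma0: float, fluid: FluidModel, Y0: float = 100.0, Z0: float = 130.0) -> float:
    """Duct Reynolds number Re = rho * Q * D_h / (mu * A), all SI.

    For shear-dependent fluids the high-shear reference viscosity is used.
    """
    cs = cross_section(Y0, Z0)
    Q = flow_rate_si(gamma0, Y0, Z0)
    A_m2 = cs["A_um2"] * 1e-12
    return fluid.rho * Q * cs["Dh_m"] / (fluid.mu_ref * A_m2)


def womersley(f: float, D: float, fluid: FluidModel) -> float:
    """Womersley number Wo = (D/2) * sqrt(rho * omega / mu), omega = 2*pi*f.

    ``f`` in Hz, vessel diameter ``D`` in metres.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    if D <= 0:
        raise ValueError("diameter must be positive")
    omega = 2.0 * math.pi * f
    return 0.5 * D * math.sqrt(fluid.rho * omega / fluid.mu_ref)


@dataclass(frozen=True)
class OperatingPoint:
    """One run's operating point: shear rate, flow rate and dimensionless groups."""

    gamma0: float               # bulk wall shear rate, 1/s
    Q_uL_min: float
    Q_m3_s: float
    A_um2: float
    Dh_m: float
    lam: float
    Re: float
    Wo: float = 0.0
    f_Hz: float | None = None
    D_m: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("gamma0", "Q_uL_min", "Q_m3_s", "A_um2", "Dh_m", "lam", "Re", "Wo")}


def make_operating_point(gamma0: float, fluid: FluidModel,
                         Y0: float = 100.0, Z0: float = 130.0,
                         f_Hz: float | None = None, D_m: float | None = None) -> OperatingPoint:
    """Assemble the full operating-point record for one run."""
    cs = cross_section(Y0, Z0)
    wo = 0.0
    if f_Hz is not None:
        wo = womersley(f_Hz, D_m if D_m is not None else Z0 * 1e-6, fluid)
    return OperatingPoint(
        gamma0=gamma0,
        Q_uL_min=flow_rate(gamma0, Y0, Z0),
        Q_m3_s=flow_rate_si(gamma0, Y0, Z0),
        A_um2=cs["A_um2"], Dh_m=cs["Dh_m"], lam=cs["lam"],
        Re=reynolds(gamma0, fluid, Y0, Z0),
        Wo=wo, f_Hz=f_Hz, D_m=D_m,
    )
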