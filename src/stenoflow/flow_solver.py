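"""Steady laminar incompressible flow in the stenosis microchannel.

Formulation
-----------
The 2D steady variable-viscosity Navier-Stokes equations are solved in a
streamfunction / stress-vorticity form on the boundary-fitted grid mapped to
the unit square.  With u = psi_y, v = -psi_x, omega = v_x - u_y and the
auxiliary unknown chi = mu * omega, taking the curl of the momentum balance
div[mu (grad u + grad u^T)] - grad P = rho (u . grad) u gives exactly

    lap(psi) = -chi / mu
    rho (u . grad)(chi / mu) = lap(chi)

(the identity curl{div[mu(grad u + grad u^T)]} = lap(mu omega) holds for any
solenoidal 2D field).  Working with chi keeps the viscous operator a pure
Laplacian -- no deferred viscosity sources -- so shear-thinning runs are as
stable as Newtonian ones; the viscosity enters only through lagged
coefficients updated in a Picard loop.

Both equations are discretized with conservative second-order 9-point
stencils in mapped coordinates; every metric cross term is carried
implicitly, which keeps the scheme stable on the strongly sheared cells
produced by steep contraction angles (the ramp slope reaches
tan 85 deg ~ 11.4).  The coupled linear system for (psi, chi) is solved
directly (sparse LU) each outer iteration; convergence is measured by the
scaled L1 residual of the coupled equations.

Shear-thinning constitutive handling: the generalized power-law with the
stated blood parameters has a non-monotone stress curve (d(mu*gamma)/dgamma
< 0 for gamma roughly 70-220 1/s), which makes the steady problem ill-posed
exactly where that stress band is crossed.  Inside the solver the law is
therefore replaced by the monotone (Maxwell) envelope of tau(gamma), after a
smooth low-shear regularization gamma -> sqrt(gamma^2 + (f*gamma0)^2) that
bounds the power-law viscosity spike on zero-shear lines.  Both devices act
only at shear rates far below the bulk value, where the viscous stress is
negligible; the rheology module keeps the raw law.

Mass conservation is inherited from the streamfunction: the flux between the
walls at any axial station is psi_top - psi_bottom, which the wall boundary
conditions fix to the imposed line flux exactly.

Boundary conditions: a fully developed velocity profile (Dirichlet psi and
chi) at the inlet carrying the 2D-equivalent line flux q = gamma0 * Y0^2 / 6,
no-slip walls via a second-order one-sided wall-vorticity closure (exact for
cubic near-wall profiles), and zero streamwise gradient at the outlet.  The
pressure field is recovered after convergence from a pressure Poisson
equation (gauge fixed to zero at the outlet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from ._numerics import Metrics, d_dx, d_dy, deriv, deriv4_eta, shear_rate_invariant, \
    velocity_gradients
from .geometry import Grid2D, StenosisGeometry
from .operating_point import OperatingPoint
from .rheology import GAMMA_FLOOR, FluidModel, apparent_viscosity

__all__ = ["SolverConfig", "SolverError", "FlowField", "solve_flow",
           "developed_profile", "ConstitutiveTable"]

#: stenosis levels at/above this are refused (throat too extreme for the
#: sheared-grid discretization; refine the model, not the grid)
S_LIMIT = 0.97


class SolverError(RuntimeError):
    """Raised when the nonlinear iteration fails to converge."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


@dataclass
class SolverConfig:
    """Iteration controls for :func:`solve_flow`."""

    #: scaled L1 residual of the coupled discrete equations
    tol: float = 1e-7
    max_iter: int = 200
    relax_u: float = 1.0        # under-relaxation of the (psi, chi) update
    relax_mu: float = 0.15      # under-relaxation of the viscosity field
    #: additional convergence requirement for non-Newtonian runs: either the
    #: stress-weighted viscosity-field change drops below this (0.1%), or the
    #: peak shear rate drifts by less than this over the trailing
    #: ``stationary_window`` iterations.  The second path exists because the
    #: blood GPL law is non-monotone in stress over a shear-rate band, and
    #: pointwise viscosity consistency is not attainable for runs whose flow
    #: crosses that band even when every observable has converged.
    mu_tol: float = 1e-3
    stationary_window: int = 30
    #: "central" (second order; adequate at the diffusion-dominated Re of the
    #: microchannel), "upwind" (first order), or "auto" = central for constant
    #: viscosity, upwind for shear-thinning runs whose lagged 1/mu convection
    #: coefficients may locally violate the central cell-Peclet limit.
    convection_scheme: str = "auto"
    gamma_floor: float = GAMMA_FLOOR     # 1/s
    #: low-shear regularization scale as a fraction of gamma0 (see module
    #: docstring); affects viscosity evaluation only where gamma << gamma0.
    gamma_reg_frac: float = 0.05
    compute_pressure: bool = True

    def __post_init__(self):
        if not (0 < self.relax_u <= 1 and 0 < self.relax_mu <= 1):
            raise ValueError("under-relaxation factors must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.convection_scheme not in ("central", "upwind", "auto"):
            raise ValueError(f"unknown convection scheme {self.convection_scheme!r}")


class ConstitutiveTable:
    """Monotone in-solver constitutive relation mu(gamma), tabulated.

    Applies the smooth low-shear regularization and replaces tau(gamma) =
    mu * gamma by its monotone non-decreasing envelope so that gamma(tau) is
    single valued.  Interpolation is done in log-log space.
    """

    #: minimum d ln tau / d ln gamma of the monotonized stress curve.  A small
    #: positive tilt (rather than an exactly flat Maxwell plateau) keeps the
    #: shear rate a well-conditioned function of stress inside the otherwise
    #: ill-posed band, so the viscosity iteration has no neutral directions.
    MIN_LOGSLOPE = 0.05

    def __init__(self, fluid: FluidModel, gamma_floor: float = GAMMA_FLOOR,
                 gamma_reg: float = 0.0, n_tab: int = 1600):
        self.fluid = fluid
        self.gamma_reg = gamma_reg
        g = np.logspace(-4, 8, n_tab)
        mu = apparent_viscosity(fluid, np.sqrt(g ** 2 + gamma_reg ** 2), gamma_floor)
        lg = np.log(g)
        ltau = np.log(mu * g)
        # running-max with a minimum slope in log-log space
        step = self.MIN_LOGSLOPE * np.diff(lg)
        ltau = np.maximum.accumulate(ltau - np.concatenate(([0.0], np.cumsum(step))))
        ltau += np.concatenate(([0.0], np.cumsum(step)))
        self._lg = lg
        self._lmu = ltau - lg
        self._ltau = ltau

    def mu_of_gamma(self, gamma):
        lg = np.log(np.clip(gamma, np.exp(self._lg[0]), np.exp(self._lg[-1])))
        return np.exp(np.interp(lg, self._lg, self._lmu))

    def gamma_of_tau(self, tau):
        ltau = np.log(np.clip(tau, np.exp(self._ltau[0]), np.exp(self._ltau[-1])))
        out = np.exp(np.interp(ltau, self._ltau, self._lg))
        return np.where(np.asarray(tau) <= 0, 0.0, out)


@dataclass
class FlowField:
    """Converged steady solution on the boundary-fitted grid (SI units)."""

    geom: StenosisGeometry
    grid: Grid2D
    fluid: FluidModel
    op: OperatingPoint
    cfg: SolverConfig
    psi: np.ndarray          # streamfunction, m^2/s
    omega: np.ndarray        # vorticity, 1/s
    u: np.ndarray            # m/s
    v: np.ndarray            # m/s
    P: np.ndarray | None     # Pa, gauge (zero at outlet)
    mu_field: np.ndarray     # Pa s
    residual_history: list
    converged: bool
    mass_imbalance: float
    q2d: float               # imposed line flux, m^2/s
    U_ref: float             # peak inlet speed, m/s
    metrics_m: Metrics       # metric terms in metres
    dxi: float
    deta: float
    iterations: int = 0

    def station_fluxes(self) -> np.ndarray:
        """Line flux (m^2/s) through each constant-x station, wall to wall.

        The discrete flux carried by the scheme is the streamfunction
        difference between the walls.
        """
        return self.psi[:, -1] - self.psi[:, 0]

    def velocity_fluxes(self) -> np.ndarray:
        """Diagnostic trapezoid-integrated velocity flux per station (m^2/s)."""
        Ym = self.grid.Y * 1e-6
        return np.array([np.trapezoid(self.u[i, :], Ym[i, :])
                         for i in range(self.grid.nx + 1)])

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


# ----------------------------------------------------------------------
# inlet profile
# ----------------------------------------------------------------------

def developed_profile(fluid: FluidModel, gamma0: float, width_m: float,
                      eta: np.ndarray, gamma_floor: float = GAMMA_FLOOR,
                      table: ConstitutiveTable | None = None):
    """Fully developed channel profile carrying q = gamma0 * w^2 / 6.

    Returns ``(u, psi, omega)`` at the cross-channel positions ``eta``
    (0..1), in SI units.  For a Newtonian fluid this is the plane-Poiseuille
    parabola whose wall shear rate is exactly ``gamma0``.  For shear-dependent
    laws the 1D balance tau(y) = G (w/2 - y) is inverted pointwise through the
    (monotone) constitutive table and the pressure gradient G is adjusted by
    bisection until the profile carries the required flux.
    """
    w = width_m
    q = gamma0 * w * w / 6.0
    if fluid.law == "newtonian":
        u = gamma0 * w * (eta - eta ** 2)
        psi = q * (3 * eta ** 2 - 2 * eta ** 3)
        omega = -gamma0 * (1.0 - 2.0 * eta)
        return u, psi, omega

    if table is None:
        table = ConstitutiveTable(fluid, gamma_floor)
    yfine = np.linspace(0.0, w, 801)

    def profile_for(G):
        tau = G * (0.5 * w - yfine)
        du = np.sign(tau) * table.gamma_of_tau(np.abs(tau))
        u = cumulative_trapezoid(du, yfine, initial=0.0)
        return u, du

    def flux_err(G):
        u, _ = profile_for(G)
        return np.trapezoid(u, yfine) - q

    G0 = 2.0 * fluid.mu_ref * gamma0 / w
    Gsol = brentq(flux_err, 0.02 * G0, 100.0 * G0, rtol=1e-12)
    ufine, dufine = profile_for(Gsol)
    u = np.interp(eta * w, yfine, ufine)
    psi_fine = cumulative_trapezoid(ufine, yfine, initial=0.0)
    psi = np.interp(eta * w, yfine, psi_fine)
    psi *= q / psi_fine[-1]   # remove quadrature drift: walls carry exactly q
    omega = -np.interp(eta * w, yfine, dufine)
    return u, psi, omega


# ----------------------------------------------------------------------
# discrete operators
# ----------------------------------------------------------------------

def _lap_coeffs(q11: np.ndarray, q12: np.ndarray, q22: np.ndarray,
                dxi: float, deta: float) -> dict:
    """Conservative 9-point coefficients of J*lap(.) at interior nodes."""
    c = slice(1, -1)
    a_e = 0.5 * (q11[c, c] + q11[2:, c]) / dxi ** 2
    a_w = 0.5 * (q11[c, c] + q11[:-2, c]) / dxi ** 2
    b_n = 0.5 * (q22[c, c] + q22[c, 2:]) / deta ** 2
    b_s = 0.5 * (q22[c, c] + q22[c, :-2]) / deta ** 2
    f = 1.0 / (4.0 * dxi * deta)
    c_e = 0.5 * (q12[c, c] + q12[2:, c]) * f
    c_w = 0.5 * (q12[c, c] + q12[:-2, c]) * f
    d_n = 0.5 * (q12[c, c] + q12[c, 2:]) * f
    d_s = 0.5 * (q12[c, c] + q12[c, :-2]) * f
    return {
        (0, 0): -(a_e + a_w + b_n + b_s),
        (1, 0): a_e + d_n - d_s,
        (-1, 0): a_w - d_n + d_s,
        (0, 1): b_n + c_e - c_w,
        (0, -1): b_s - c_e + c_w,
        (1, 1): c_e + d_n,
        (-1, 1): -c_w - d_n,
        (1, -1): -c_e - d_s,
        (-1, -1): c_w + d_s,
    }


def _assemble(m: Metrics, dxi: float, deta: float, mu_hat: np.ndarray,
              u: np.ndarray, v: np.ndarray, Re: float,
              psi_in: np.ndarray, chi_in: np.ndarray, scheme: str):
    """Coupled (psi, chi) system; returns (A, b) with 2N unknowns.

    psi rows:  Lop(psi) + (J/mu) chi = 0
    chi rows:  Lop(chi) - Re [ (U/mu) chi_xi + (V/mu) chi_eta
                               + (U (1/mu)_xi + V (1/mu)_eta) chi ] = 0
    """
    nxp, nyp = m.jac.shape
    nx, ny = nxp - 1, nyp - 1
    N = nxp * nyp

    def k_of(i, j):
        return i * nyp + j

    lap = _lap_coeffs(m.q11, m.q12, m.q22, dxi, deta)
    II, JJ = np.meshgrid(np.arange(1, nx), np.arange(1, ny), indexing="ij")
    k_int = (II * nyp + JJ).ravel()

    rows, cols, vals = [], [], []
    b = np.zeros(2 * N)

    inv_mu = 1.0 / mu_hat
    Ucv = u * m.y_eta - v * m.x_eta
    Vcv = v * m.x_xi - u * m.y_xi
    Ui = (Re * Ucv * inv_mu)[1:-1, 1:-1]
    Vi = (Re * Vcv * inv_mu)[1:-1, 1:-1]
    # lagged d(1/mu) advection, implicit on the diagonal
    diag_mu = -Re * (Ucv * deriv(inv_mu, dxi, 0)
                     + Vcv * deriv(inv_mu, deta, 1))[1:-1, 1:-1]

    if scheme == "central":
        conv = {
            (1, 0): -Ui / (2 * dxi), (-1, 0): Ui / (2 * dxi),
            (0, 1): -Vi / (2 * deta), (0, -1): Vi / (2 * deta),
            (0, 0): diag_mu,
        }
    else:  # first-order upwind
        up = np.maximum(Ui, 0.0) / dxi
        um = np.minimum(Ui, 0.0) / dxi
        vp = np.maximum(Vi, 0.0) / deta
        vm = np.minimum(Vi, 0.0) / deta
        conv = {
            (1, 0): -um, (-1, 0): up,
            (0, 1): -vm, (0, -1): vp,
            (0, 0): -(up - um + vp - vm) + diag_mu,
        }

    # psi interior rows
    for (di, dj), cval in lap.items():
        rows.append(k_int)
        cols.append(k_int + di * nyp + dj)
        vals.append(cval.ravel())
    rows.append(k_int)
    cols.append(N + k_int)
    vals.append((m.jac * inv_mu)[1:-1, 1:-1].ravel())

    # chi interior rows
    for (di, dj), cval in lap.items():
        coeff = cval + conv.get((di, dj), 0.0)
        rows.append(N + k_int)
        cols.append(N + k_int + di * nyp + dj)
        vals.append(np.broadcast_to(coeff, cval.shape).ravel())

    # --- boundary rows -------------------------------------------------
    j_all = np.arange(nyp)
    k_in = k_of(0, j_all)
    rows.append(k_in); cols.append(k_in); vals.append(np.ones(nyp))
    b[k_in] = psi_in
    rows.append(N + k_in); cols.append(N + k_in); vals.append(np.ones(nyp))
    b[N + k_in] = chi_in

    # outlet i = nx (j interior): zero streamwise gradient, 2nd order
    j_int = np.arange(1, ny)
    for base in (0, N):
        k0 = base + k_of(nx, j_int)
        rows.append(k0); cols.append(k0); vals.append(np.full(ny - 1, 3.0))
        rows.append(k0); cols.append(base + k_of(nx - 1, j_int))
        vals.append(np.full(ny - 1, -4.0))
        rows.append(k0); cols.append(base + k_of(nx - 2, j_int))
        vals.append(np.full(ny - 1, 1.0))

    # walls (j = 0 and j = ny) for i = 1..nx: Dirichlet psi; wall vorticity
    # closure chi_w = -mu_w (q22/J) psi_etaeta with the one-sided second-order
    # estimate (8 psi_1 - psi_2 - 7 psi_w) / (2 deta^2), exact for cubics.
    i_w = np.arange(1, nx + 1)
    for j_w, j1, j2, psi_val in ((0, 1, 2, 0.0), (ny, ny - 1, ny - 2, 1.0)):
        k_w = k_of(i_w, j_w)
        rows.append(k_w); cols.append(k_w); vals.append(np.ones(i_w.size))
        b[k_w] = psi_val
        wcoef = (mu_hat[i_w, j_w] * m.q22[i_w, j_w]
                 / (m.jac[i_w, j_w] * 2.0 * deta ** 2))
        rows.append(N + k_w); cols.append(N + k_w); vals.append(np.ones(i_w.size))
        rows.append(N + k_w); cols.append(k_of(i_w, j1)); vals.append(8.0 * wcoef)
        rows.append(N + k_w); cols.append(k_of(i_w, j2)); vals.append(-wcoef)
        rows.append(N + k_w); cols.append(k_w); vals.append(-7.0 * wcoef)

    A = sp.csc_matrix((np.concatenate([np.asarray(x, dtype=float).ravel() for x in vals]),
                       (np.concatenate([np.asarray(x, dtype=int).ravel() for x in rows]),
                        np.concatenate([np.asarray(x, dtype=int).ravel() for x in cols]))),
                      shape=(2 * N, 2 * N))
    return A, b


def _velocities_from_psi(psi, m: Metrics, dxi, deta, u_in):
    """Nodal velocities u = psi_y, v = -psi_x (4th-order eta derivative)."""
    p_xi = deriv(psi, dxi, 0)
    p_eta = deriv4_eta(psi, deta)
    u = (m.x_xi * p_eta - m.x_eta * p_xi) / m.jac
    v = -(m.y_eta * p_xi - m.y_xi * p_eta) / m.jac
    u[:, 0] = 0.0; u[:, -1] = 0.0
    v[:, 0] = 0.0; v[:, -1] = 0.0
    u[0, :] = u_in
    v[0, :] = 0.0
    return u, v


# ----------------------------------------------------------------------
# pressure recovery
# ----------------------------------------------------------------------

def _solve_pressure(m: Metrics, dxi, deta, mu_hat, u, v, Re):
    """Pressure Poisson solve with Neumann walls/inlet, Dirichlet outlet."""
    nxp, nyp = m.jac.shape
    nx, ny = nxp - 1, nyp - 1
    N = nxp * nyp

    u_x, u_y, v_x, v_y = velocity_gradients(u, v, m, dxi, deta)
    T11 = 2.0 * mu_hat * u_x
    T12 = mu_hat * (u_y + v_x)
    T22 = 2.0 * mu_hat * v_y
    F1 = d_dx(T11, m, dxi, deta) + d_dy(T12, m, dxi, deta) - Re * (u * u_x + v * u_y)
    F2 = d_dx(T12, m, dxi, deta) + d_dy(T22, m, dxi, deta) - Re * (u * v_x + v * v_y)
    rhs = d_dx(F1, m, dxi, deta) + d_dy(F2, m, dxi, deta)

    def k_of(i, j):
        return i * nyp + j

    lap = _lap_coeffs(m.q11, m.q12, m.q22, dxi, deta)
    II, JJ = np.meshgrid(np.arange(1, nx), np.arange(1, ny), indexing="ij")
    k_int = (II * nyp + JJ).ravel()
    rows, cols, vals = [], [], []
    b = np.zeros(N)
    for (di, dj), cval in lap.items():
        rows.append(k_int)
        cols.append(k_int + di * nyp + dj)
        vals.append(cval.ravel())
    b[k_int] = (m.jac[1:-1, 1:-1] * rhs[1:-1, 1:-1]).ravel()

    rows = list(np.concatenate(rows))
    cols = list(np.concatenate(cols))
    vals = list(np.concatenate(vals))

    def add(r, c, val):
        rows.append(r); cols.append(c); vals.append(val)

    # outlet column: gauge zero
    for j in range(nyp):
        add(k_of(nx, j), k_of(nx, j), 1.0)
        b[k_of(nx, j)] = 0.0

    # walls: grad(eta).(grad p - F) = 0
    for j_w, sgn in ((0, 1), (ny, -1)):
        for i in range(0, nx):
            r = k_of(i, j_w)
            q12 = m.q12[i, j_w]; q22 = m.q22[i, j_w]
            add(r, k_of(i, j_w), q22 * (-3.0) * sgn / (2 * deta))
            add(r, k_of(i, j_w + sgn), q22 * 4.0 * sgn / (2 * deta))
            add(r, k_of(i, j_w + 2 * sgn), q22 * (-1.0) * sgn / (2 * deta))
            if i == 0:
                add(r, k_of(0, j_w), -3.0 * q12 / (2 * dxi))
                add(r, k_of(1, j_w), 4.0 * q12 / (2 * dxi))
                add(r, k_of(2, j_w), -1.0 * q12 / (2 * dxi))
            else:
                add(r, k_of(i + 1, j_w), q12 / (2 * dxi))
                add(r, k_of(i - 1, j_w), -q12 / (2 * dxi))
            b[r] = -m.y_xi[i, j_w] * F1[i, j_w] + m.x_xi[i, j_w] * F2[i, j_w]

    # inlet: grad(xi).(grad p - F) = 0
    for j in range(1, ny):
        r = k_of(0, j)
        q11 = m.q11[0, j]; q12 = m.q12[0, j]
        add(r, k_of(0, j), -3.0 * q11 / (2 * dxi))
        add(r, k_of(1, j), 4.0 * q11 / (2 * dxi))
        add(r, k_of(2, j), -1.0 * q11 / (2 * dxi))
        add(r, k_of(0, j + 1), q12 / (2 * deta))
        add(r, k_of(0, j - 1), -q12 / (2 * deta))
        b[r] = m.y_eta[0, j] * F1[0, j] - m.x_eta[0, j] * F2[0, j]

    A = sp.csc_matrix((np.asarray(vals), (np.asarray(rows, dtype=int),
                                          np.asarray(cols, dtype=int))), shape=(N, N))
    return spla.spsolve(A, b).reshape(nxp, nyp)


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

def solve_flow(geom: StenosisGeometry, fluid: FluidModel, op: OperatingPoint,
               grid: Grid2D, cfg: SolverConfig | None = None) -> FlowField:
    """Solve the steady flow for one operating point.

    Raises :class:`SolverError` (carrying the residual history) if the outer
    iteration does not meet the tolerance within ``cfg.max_iter``.
    """
    cfg = cfg or SolverConfig()
    if op.gamma0 <= 0 or op.Q_m3_s <= 0:
        raise ValueError("operating point must carry positive flow (gamma0 > 0)")
    if geom.S >= S_LIMIT:
        raise ValueError(
            f"stenosis level S={geom.S} >= {S_LIMIT} is outside the resolved regime; "
            "reduce S or treat the throat with a dedicated fine model")
    if grid.geom is not geom and (grid.geom.S != geom.S or grid.geom.alpha != geom.alpha
                                  or grid.geom.placement != geom.placement):
        raise ValueError("grid was generated for a different geometry")

    L = geom.Y0 * 1e-6                      # m
    q2d = op.gamma0 * L * L / 6.0           # m^2/s
    U0 = q2d / L
    mu_ref = fluid.mu_ref
    Re = fluid.rho * U0 * L / mu_ref
    gamma_scale = U0 / L                    # converts nondim shear to 1/s

    m = Metrics.from_grid(grid, scale=geom.Y0)   # lengths in units of Y0
    nxp, nyp = grid.nx + 1, grid.ny + 1
    N = nxp * nyp
    dxi, deta = grid.dxi, grid.deta

    newtonian = fluid.law == "newtonian"
    scheme = cfg.convection_scheme
    if scheme == "auto":
        scheme = "central" if newtonian else "upwind"
    table = None
    if not newtonian:
        table = ConstitutiveTable(fluid, cfg.gamma_floor,
                                  gamma_reg=cfg.gamma_reg_frac * op.gamma0)

    eta = np.linspace(0.0, 1.0, nyp)
    u_in_si, psi_in_si, om_in_si = developed_profile(fluid, op.gamma0, L, eta,
                                                     cfg.gamma_floor, table)
    psi_in = psi_in_si / q2d
    omega_in = om_in_si / gamma_scale
    u_in = u_in_si / U0
    if newtonian:
        mu_in = np.ones(nyp)
    else:
        mu_in = table.mu_of_gamma(np.abs(om_in_si)) / mu_ref
    chi_in = mu_in * omega_in

    mu_hat = np.ones((nxp, nyp)) if newtonian else np.tile(mu_in, (nxp, 1))
    u = np.zeros((nxp, nyp))
    v = np.zeros((nxp, nyp))
    psi = np.zeros((nxp, nyp))
    chi = np.zeros((nxp, nyp))

    history = []
    gmax_hist = []
    converged = False
    dmu = 0.0
    it = 0
    state = np.zeros(2 * N)
    for it in range(1, cfg.max_iter + 1):
        A, b = _assemble(m, dxi, deta, mu_hat, u, v, Re, psi_in, chi_in, scheme)
        if it > 1:
            # scaled L1 residual of the coupled discrete equations
            r = b - A @ state
            res = float(np.abs(r).sum() / np.abs(A.diagonal() * state).sum())
            history.append(res)
            nw = cfg.stationary_window
            gmax_stationary = (
                len(gmax_hist) >= nw
                and (max(gmax_hist[-nw:]) - min(gmax_hist[-nw:]))
                < cfg.mu_tol * gmax_hist[-1])
            if res < cfg.tol and (newtonian or dmu < cfg.mu_tol or gmax_stationary):
                converged = True
                break
        x = spla.spsolve(A, b)
        state = state + cfg.relax_u * (x - state) if it > 1 else x
        psi = state[:N].reshape(nxp, nyp)
        chi = state[N:].reshape(nxp, nyp)
        u, v = _velocities_from_psi(psi, m, dxi, deta, u_in)

        if not newtonian:
            gam = shear_rate_invariant(*velocity_gradients(u, v, m, dxi, deta))
            gmax_hist.append(float(gam.max()))
            mu_new = table.mu_of_gamma(gam * gamma_scale) / mu_ref
            # stress-weighted viscosity change: near separation/stagnation
            # points gamma crosses zero and mu(gamma) jitters indefinitely,
            # but the local viscous stress (hence its influence on the flow)
            # vanishes there; weight the relative change accordingly.
            tau_loc = mu_hat * gam
            w = tau_loc / max(tau_loc.max(), 1e-300)
            dmu = float(np.max(np.abs(mu_new - mu_hat) / mu_hat * w))
            mu_hat = mu_hat + cfg.relax_mu * (mu_new - mu_hat)

    if not converged:
        raise SolverError(
            f"flow solve did not converge in {cfg.max_iter} iterations "
            f"(last scaled residual {history[-1]:.3e})", history)

    P = None
    if cfg.compute_pressure:
        p_hat = _solve_pressure(m, dxi, deta, mu_hat, u, v, Re)
        P = p_hat * (mu_ref * U0 / L)

    # snap the Dirichlet rows to their exact values (removes direct-solver
    # roundoff from the wall/inlet streamfunction, hence from station fluxes)
    psi[:, 0] = 0.0
    psi[:, -1] = 1.0
    psi[0, :] = psi_in
    omega = chi / mu_hat
    omega[0, :] = omega_in

    psi_si = psi * q2d
    flux = psi_si[:, -1] - psi_si[:, 0]
    mass_imbalance = float(np.max(np.abs(flux - q2d)) / q2d)

    return FlowField(
        geom=geom, grid=grid, fluid=fluid, op=op, cfg=cfg,
        psi=psi_si, omega=omega * gamma_scale,
        u=u * U0, v=v * U0, P=P, mu_field=mu_hat * mu_ref,
        residual_history=history, converged=True,
        mass_imbalance=mass_imbalance, q2d=q2d,
        U_ref=float(np.max(np.abs(u_in_si))),
        metrics_m=Metrics.from_grid(grid, scale=1e6),
        dxi=dxi, deta=deta, iterations=it,
    )
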