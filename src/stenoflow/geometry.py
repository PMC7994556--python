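"""Parametric stenosis microchannel geometry and boundary-fitted structured grids.

The channel is a straight rectangular microchannel (width ``Y0``, height ``Z0``,
axial analysis length ``X0``, all in micrometres) partially occluded by a
hump-shaped contraction.  The hump is a triangular ramp pair inclined at the
contraction angle ``alpha`` (measured from the unobstructed wall) whose apex is
rounded by a circular fillet centred at ``x = 0``, so the wall profile is
continuous and the wall shear stress is free of corner singularities.

Two placements are supported:

* ``eccentric`` -- a single hump of height ``S*Y0`` on the bottom wall
  (e.g. a medical-device insertion narrowing the lumen from one side);
* ``concentric`` -- two mirrored humps of height ``S*Y0/2`` on both walls
  (e.g. an axisymmetric atherosclerotic narrowing).

In both cases the throat width is exactly ``Y0*(1 - S)``.

The solved plane is x-y (width-wise); ``Z0`` is carried as metadata for the
rectangular-duct operating-point formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StenosisGeometry", "Grid2D", "build_geometry", "generate_grid"]

PLACEMENTS = ("eccentric", "concentric")

#: default apex fillet radius (um).  The crest must be resolvable: with a
#: radius much below ~10 um the 85-degree default contraction behaves like a
#: sharp orifice edge whose shear peak does not converge under desk-scale
#: grid refinement (see the methods note's resolvability study).
DEFAULT_FILLET_UM = 10.0
#: entrance/exit straight runs, in multiples of the channel width
RUN_FACTOR = 3.0


def _hump_params(H: float, alpha_deg: float, fillet_radius: float):
    """Fillet radius actually used, arc half-width and ramp foot half-width.

    For humps shorter than the fillet cap height the radius is shrunk to
    ``H / (1 - cos(alpha))`` so the crest still peaks exactly at ``H``.
    """
    a = math.radians(alpha_deg)
    one_m_cos = 1.0 - math.cos(a)
    r = fillet_radius
    if H < r * one_m_cos:
        r = H / one_m_cos
    x_tangent = r * math.sin(a)
    if alpha_deg >= 90.0:
        x_foot = x_tangent
    else:
        x_foot = x_tangent + (H - r * one_m_cos) / math.tan(a)
    return r, x_tangent, x_foot


def _hump_profile(x: np.ndarray, H: float, alpha_deg: float, fillet_radius: float) -> np.ndarray:
    """Height of a hump of total height ``H`` (um) at axial positions ``x`` (um)."""
    x = np.asarray(x, dtype=float)
    if H <= 0.0:
        return np.zeros_like(x)
    r, x_t, x_foot = _hump_params(H, alpha_deg, fillet_radius)
    ax = np.abs(x)
    y = np.zeros_like(ax)
    arc = ax <= x_t
    y[arc] = (H - r) + np.sqrt(np.maximum(r * r - ax[arc] ** 2, 0.0))
    ramp = (~arc) & (ax <= x_foot)
    if alpha_deg < 90.0:
        m = math.tan(math.radians(alpha_deg))
        y[ramp] = (H - r * (1.0 - math.cos(math.radians(alpha_deg)))) - m * (ax[ramp] - x_t)
    np.clip(y, 0.0, None, out=y)
    return y


@dataclass(frozen=True)
class StenosisGeometry:
    """Parametric stenosis microchannel (all lengths in micrometres).

    Attributes
    ----------
    X0, Y0, Z0 : axial analysis length, channel width and cross-section height.
    S : stenosis level, the fraction of the width occluded (0 <= S < 1).
    alpha : contraction angle in degrees, between ramp face and the wall.
    placement : ``"eccentric"`` or ``"concentric"``.
    fillet_radius : apex rounding radius (um).
    run_in, run_out : entrance/exit straight lengths beyond the +-X0/2
        analysis window; default ``3*Y0`` so the inflow is fully developed.
    """

    X0: float = 200.0
    Y0: float = 100.0
    Z0: float = 130.0
    S: float = 0.8
    alpha: float = 85.0
    placement: str = "eccentric"
    fillet_radius: float = DEFAULT_FILLET_UM
    run_in: float = field(default=-1.0)
    run_out: float = field(default=-1.0)

    def __post_init__(self):
        if self.run_in < 0:
            object.__setattr__(self, "run_in", RUN_FACTOR * self.Y0)
        if self.run_out < 0:
            object.__setattr__(self, "run_out", RUN_FACTOR * self.Y0)
        if not (0.0 <= self.S < 1.0):
            raise ValueError(f"stenosis level S={self.S} outside [0, 1)")
        if not (0.0 < self.alpha <= 90.0):
            raise ValueError(f"contraction angle alpha={self.alpha} outside (0, 90] degrees")
        for name in ("X0", "Y0", "Z0", "fillet_radius"):
            if getattr(self, name) <= 0 and not (name == "fillet_radius" and self.S == 0):
                if getattr(self, name) <= 0:
                    raise ValueError(f"{name}={getattr(self, name)} must be positive")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement {self.placement!r} not one of {PLACEMENTS}")
        if self.S > 0 and 2.0 * self.hump_half_footprint > self.X0 + self.run_in + self.run_out:
            raise ValueError(
                "hump axial footprint "
                f"{2 * self.hump_half_footprint:.1f} um exceeds channel length "
                f"{self.X0 + self.run_in + self.run_out:.1f} um; "
                "the alpha/S combination is infeasible"
            )

    # -- derived scalars ---------------------------------------------------
    @property
    def hump_height(self) -> float:
        """Height of the bottom-wall hump (um)."""
        if self.S == 0:
            return 0.0
        return self.S * self.Y0 if self.placement == "eccentric" else 0.5 * self.S * self.Y0

    @property
    def throat_width(self) -> float:
        return self.Y0 * (1.0 - self.S)

    @property
    def apex_y(self) -> float:
        """y-coordinate of the bottom apex surface at x = 0 (um)."""
        return self.hump_height

    @property
    def hump_half_footprint(self) -> float:
        if self.S == 0:
            return 0.0
        return _hump_params(self.hump_height, self.alpha, self.fillet_radius)[2]

    @property
    def x_min(self) -> float:
        return -(0.5 * self.X0 + self.run_in)

    @property
    def x_max(self) -> float:
        return 0.5 * self.X0 + self.run_out

    # -- wall profiles -----------------------------------------------------
    def y_bottom(self, x) -> np.ndarray:
        """Lower-wall profile y_b(x) (um); the unobstructed wall sits at y = 0."""
        return _hump_profile(np.asarray(x, dtype=float), self.hump_height, self.alpha,
                             self.fillet_radius)

    def y_top(self, x) -> np.ndarray:
        """Upper-wall profile y_t(x) (um)."""
        x = np.asarray(x, dtype=float)
        if self.placement == "concentric" and self.S > 0:
            return self.Y0 - _hump_profile(x, self.hump_height, self.alpha, self.fillet_radius)
        return np.full_like(x, self.Y0)

    def gap(self, x) -> np.ndarray:
        return self.y_top(x) - self.y_bottom(x)


def build_geometry(S: float, alpha: float, placement: str = "eccentric",
                   dims: dict | None = None,
                   fillet_radius: float = DEFAULT_FILLET_UM, **kwargs) -> StenosisGeometry:
    """Build a :class:`StenosisGeometry` from the study control variables.

    ``dims`` may carry ``X0``/``Y0``/``Z0`` in micrometres (defaults
    200 x 100 x 130 um).
    """
    dims = dict(dims or {})
    return StenosisGeometry(
        X0=dims.get("X0", 200.0), Y0=dims.get("Y0", 100.0), Z0=dims.get("Z0", 130.0),
        S=S, alpha=alpha, placement=placement, fillet_radius=fillet_radius, **kwargs,
    )


@dataclass
class Grid2D:
    """Boundary-fitted structured grid between the wall profiles (um).

    Node arrays have shape ``(nx + 1, ny + 1)``; lines of constant ``xi`` are
    vertical (x depends on the i index only) and lines of constant ``eta``
    interpolate linearly between the walls (transfinite interpolation).
    Metric derivatives are evaluated with the same second-order finite
    differences the solver uses.
    """

    geom: StenosisGeometry
    nx: int
    ny: int
    X: np.ndarray
    Y: np.ndarray
    dxi: float
    deta: float
    x_xi: np.ndarray
    x_eta: np.ndarray
    y_xi: np.ndarray
    y_eta: np.ndarray
    jac: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def min_cell_size(self) -> float:
        """Smallest cell edge length (um), used to set the streamline step."""
        dx = np.diff(self.X[:, 0]).min()
        dy = (self.geom.gap(self.X[:, 0]) / self.ny).min()
        return float(min(dx, dy))

    def cell_areas(self) -> np.ndarray:
        """Signed quadrilateral areas (um^2) via the shoelace formula."""
        x, y = self.X, self.Y
        x1, y1 = x[:-1, :-1], y[:-1, :-1]
        x2, y2 = x[1:, :-1], y[1:, :-1]
        x3, y3 = x[1:, 1:], y[1:, 1:]
        x4, y4 = x[:-1, 1:], y[:-1, 1:]
        return 0.5 * ((x1 * y2 - x2 * y1) + (x2 * y3 - x3 * y2)
                      + (x3 * y4 - x4 * y3) + (x4 * y1 - x1 * y4))


def _d_dxi(f: np.ndarray, d: float, axis: int = 0) -> np.ndarray:
    """Second-order first derivative along ``axis`` (central, one-sided ends)."""
    out = np.gradient(f, d, axis=axis, edge_order=2)
    return out


def _clustered_x(geom: StenosisGeometry, nx: int, strength: float) -> np.ndarray:
    """Node abscissae refined toward the apex (x = 0) by a Gaussian density bump."""
    xa, xb = geom.x_min, geom.x_max
    if strength <= 0:
        return np.linspace(xa, xb, nx + 1)
    sigma = min(max(geom.hump_half_footprint, 0.1 * geom.X0), 0.5 * geom.X0)
    xs = np.linspace(xa, xb, 4001)
    density = 1.0 + strength * np.exp(-0.5 * (xs / sigma) ** 2)
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(xs))))
    cum /= cum[-1]
    x = np.interp(np.linspace(0.0, 1.0, nx + 1), cum, xs)
    x[0], x[-1] = xa, xb
    return x


def generate_grid(geom: StenosisGeometry, nx: int, ny: int,
                  x_clustering: float | None = None) -> Grid2D:
    """Generate the boundary-fitted grid.

    Parameters
    ----------
    nx, ny : cell counts in the axial and cross-channel directions (>= 8).
    x_clustering : strength of the axial refinement toward the apex.  ``None``
        selects no clustering for a straight channel and a default of 8 for a
        stenosed one.
    """
    if nx < 8 or ny < 8:
        raise ValueError(f"grid too coarse: nx={nx}, ny={ny} (need >= 8 cells each way)")
    if x_clustering is None:
        x_clustering = 0.0 if geom.S == 0 else 8.0
    x = _clustered_x(geom, nx, x_clustering)
    eta = np.linspace(0.0, 1.0, ny + 1)
    yb = geom.y_bottom(x)
    yt = geom.y_top(x)
    X = np.repeat(x[:, None], ny + 1, axis=1)
    Y = yb[:, None] + eta[None, :] * (yt - yb)[:, None]

    dxi = 1.0 / nx
    deta = 1.0 / ny
    x_xi = _d_dxi(X, dxi, axis=0)
    x_eta = _d_dxi(X, deta, axis=1)
    y_xi = _d_dxi(Y, dxi, axis=0)
    y_eta = _d_dxi(Y, deta, axis=1)
    jac = x_xi * y_eta - x_eta * y_xi

    grid = Grid2D(geom=geom, nx=nx, ny=ny, X=X, Y=Y, dxi=dxi, deta=deta,
                  x_xi=x_xi, x_eta=x_eta, y_xi=y_xi, y_eta=y_eta, jac=jac)

    areas = grid.cell_areas()
    if np.any(areas <= 0) or np.any(jac <= 0):
        bad = np.argwhere(areas <= 0)
        i, j = (bad[0] if len(bad) else np.argwhere(jac <= 0)[0])
        raise ValueError(f"degenerate grid cell at (i={int(i)}, j={int(j)})")
    return grid
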