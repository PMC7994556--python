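"""Finite-difference operators on the mapped (xi, eta) grid.

The boundary-fitted grid maps the physical channel onto the unit square; all
fields live on nodes of shape ``(nx+1, ny+1)``.  Physical derivatives follow
from the chain rule with the discrete metric terms,

    f_x = (y_eta * f_xi - y_xi * f_eta) / J
    f_y = (x_xi * f_eta - x_eta * f_xi) / J

with J = x_xi*y_eta - x_eta*y_xi.  Second-order central differences are used
in the interior with second-order one-sided stencils on the boundaries; a
fourth-order variant of the eta derivative (exact for cubics) is provided for
recovering velocities from the streamfunction without polluting wall shear.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Metrics", "deriv", "deriv4_eta", "d_dx", "d_dy", "velocity_gradients",
           "shear_rate_invariant"]


class Metrics:
    """Nondimensionalized (or raw) metric bundle for derivative evaluation."""

    def __init__(self, x_xi, x_eta, y_xi, y_eta):
        self.x_xi = x_xi
        self.x_eta = x_eta
        self.y_xi = y_xi
        self.y_eta = y_eta
        self.jac = x_xi * y_eta - x_eta * y_xi
        # inverse-metric quadratic forms used by the conservative Laplacian
        self.q11 = (x_eta ** 2 + y_eta ** 2) / self.jac
        self.q12 = -(x_xi * x_eta + y_xi * y_eta) / self.jac
        self.q22 = (x_xi ** 2 + y_xi ** 2) / self.jac

    @classmethod
    def from_grid(cls, grid, scale: float = 1.0):
        """Build metrics from a :class:`~stenoflow.geometry.Grid2D`.

        ``scale`` divides the coordinate metrics (e.g. the reference length in
        um to nondimensionalize a micrometre grid).
        """
        return cls(grid.x_xi / scale, grid.x_eta / scale,
                   grid.y_xi / scale, grid.y_eta / scale)


def deriv(f: np.ndarray, d: float, axis: int) -> np.ndarray:
    """Second-order first derivative (central interior, one-sided ends)."""
    return np.gradient(f, d, axis=axis, edge_order=2)


def deriv4_eta(f: np.ndarray, d: float) -> np.ndarray:
    """Fourth-order first derivative along axis 1 (exact for cubic profiles).

    Needs at least 5 nodes across; the grid generator enforces ny >= 8.
    """
    out = np.empty_like(f)
    out[:, 2:-2] = (f[:, :-4] - 8 * f[:, 1:-3] + 8 * f[:, 3:-1] - f[:, 4:]) / (12 * d)
    out[:, 0] = (-25 * f[:, 0] + 48 * f[:, 1] - 36 * f[:, 2]
                 + 16 * f[:, 3] - 3 * f[:, 4]) / (12 * d)
    out[:, 1] = (-3 * f[:, 0] - 10 * f[:, 1] + 18 * f[:, 2]
                 - 6 * f[:, 3] + f[:, 4]) / (12 * d)
    out[:, -1] = (25 * f[:, -1] - 48 * f[:, -2] + 36 * f[:, -3]
                  - 16 * f[:, -4] + 3 * f[:, -5]) / (12 * d)
    out[:, -2] = (3 * f[:, -1] + 10 * f[:, -2] - 18 * f[:, -3]
                  + 6 * f[:, -4] - f[:, -5]) / (12 * d)
    return out


def d_dx(f: np.ndarray, m: Metrics, dxi: float, deta: float) -> np.ndarray:
    return (m.y_eta * deriv(f, dxi, 0) - m.y_xi * deriv(f, deta, 1)) / m.jac


def d_dy(f: np.ndarray, m: Metrics, dxi: float, deta: float) -> np.ndarray:
    return (m.x_xi * deriv(f, deta, 1) - m.x_eta * deriv(f, dxi, 0)) / m.jac


def velocity_gradients(u, v, m: Metrics, dxi, deta):
    """Return (u_x, u_y, v_x, v_y) on nodes."""
    return (d_dx(u, m, dxi, deta), d_dy(u, m, dxi, deta),
            d_dx(v, m, dxi, deta), d_dy(v, m, dxi, deta))


def shear_rate_invariant(u_x, u_y, v_x, v_y) -> np.ndarray:
    """Scalar shear rate sqrt(2 D:D) from the 2D rate-of-strain tensor."""
    return np.sqrt(2.0 * u_x ** 2 + 2.0 * v_y ** 2 + (u_y + v_x) ** 2)
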