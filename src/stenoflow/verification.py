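"""Verification fixtures: analytic oracles, randomized geometry draws and the
grid-convergence (mesh-sensitivity) study.

All test inputs are generated here -- nothing is downloaded or read from disk.
The plane-Poiseuille fixture carries its closed-form solution

    u(y) = (6 q / w^3) y (w - y),   wall shear = gamma0,   q = gamma0 w^2 / 6

against which the solver is validated; randomized geometry suites exercise the
parametric-geometry invariants; and :func:`mesh_sensitivity` quantifies
discretization error by Richardson extrapolation on systematically refined
grids (refinement ratio 2) with a grid-convergence-index (GCI) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import StenosisGeometry, build_geometry, generate_grid
from .hemodynamics_post import platelet_trajectory_profile, shear_rate_field
from .operating_point import OperatingPoint, make_operating_point
from .rheology import BLOOD_NEWTONIAN, FluidModel
from .flow_solver import SolverConfig, solve_flow

__all__ = ["FixtureCase", "ConvergenceReport", "make_poiseuille_case",
           "random_geometry_suite", "mesh_sensitivity", "verification_report"]


@dataclass
class FixtureCase:
    """A solvable case, optionally with an attached closed-form solution."""

    label: str
    geom: StenosisGeometry
    fluid: FluidModel
    op: OperatingPoint
    closed_form: dict | None = None    # {"u": callable(y_m), "wall_shear": 1/s, "q": m^2/s}
    seed: int | None = None

    def __post_init__(self):
        if (self.closed_form is not None) != (self.geom.S == 0):
            raise ValueError("closed-form solutions are attached exactly to "
                             "straight (S=0) channels")


def make_poiseuille_case(Y0: float = 100.0, gamma0: float = 1000.0,
                         fluid: FluidModel = BLOOD_NEWTONIAN,
                         Z0: float = 130.0, X0: float = 200.0) -> FixtureCase:
    """Straight-channel fixture with the plane-Poiseuille closed form."""
    if Y0 <= 0 or gamma0 <= 0:
        raise ValueError("Y0 and gamma0 must be positive")
    geom = StenosisGeometry(X0=X0, Y0=Y0, Z0=Z0, S=0.0, alpha=85.0,
                            placement="eccentric")
    w = Y0 * 1e-6
    q = gamma0 * w * w / 6.0

    def u_exact(y_m):
        return 6.0 * q / w ** 3 * y_m * (w - y_m)

    return FixtureCase(
        label=f"poiseuille-Y0{Y0:g}-g{gamma0:g}", geom=geom, fluid=fluid,
        op=make_operating_point(gamma0, fluid, Y0, Z0),
        closed_form={"u": u_exact, "wall_shear": gamma0, "q": q})


def random_geometry_suite(n: int, seed: int = 0) -> list[StenosisGeometry]:
    """Reproducible random draws over the study envelope.

    S in [0, 0.95], alpha in [30, 85] degrees, both placements; every returned
    geometry satisfies the constructor invariants.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        S = rng.uniform(0.0, 0.95)
        alpha = rng.uniform(30.0, 85.0)
        placement = "eccentric" if rng.random() < 0.5 else "concentric"
        try:
            out.append(build_geometry(S=S, alpha=alpha, placement=placement))
        except ValueError:
            continue   # infeasible footprint draw; resample
    return out


@dataclass
class ConvergenceReport:
    """Richardson-extrapolation summary over systematically refined grids."""

    case_label: str
    observable: str
    grids: list = field(default_factory=list)        # [(nx, ny), ...]
    values: list = field(default_factory=list)
    refinement_ratio: float = 2.0
    observed_order: float = float("nan")
    extrapolated: float = float("nan")
    gci: list = field(default_factory=list)          # per fine level, fraction
    asymptotic: bool = False
    monotone: bool = False

    def as_dict(self) -> dict:
        return {
            "case": self.case_label, "observable": self.observable,
            "grids": [list(g) for g in self.grids], "values": self.values,
            "observed_order": self.observed_order,
            "extrapolated": self.extrapolated, "gci": self.gci,
            "asymptotic": self.asymptotic, "monotone": self.monotone,
        }


#: moderate default verification case: smooth enough that discretization error
#: is dominated by the second-order interior truncation rather than by the
#: ramp-crest curvature jumps of steeper geometries
def default_verification_case() -> FixtureCase:
    geom = build_geometry(S=0.5, alpha=45.0, placement="eccentric")
    return FixtureCase(label="verify-S50-a45", geom=geom, fluid=BLOOD_NEWTONIAN,
                       op=make_operating_point(1000.0, BLOOD_NEWTONIAN))


def _observable(case: FixtureCase, nx: int, ny: int, name: str,
                cfg: SolverConfig | None) -> float:
    grid = generate_grid(case.geom, nx, ny)
    flow = solve_flow(case.geom, case.fluid, case.op, grid, cfg)
    if name == "u_max":
        return float(flow.speed().max())
    if name == "dp":
        return float(flow.P[0, grid.ny // 2])
    if name == "wall_shear_max":
        smap = shear_rate_field(flow)
        return float(smap.tau_max / case.fluid.mu_ref)
    if name == "gamma_max":
        if case.geom.S == 0:
            smap = shear_rate_field(flow)
            return float(smap.walls["bottom"]["gamma_wall"].max())
        smap = shear_rate_field(flow)
        return platelet_trajectory_profile(flow, smap).gamma_max
    raise ValueError(f"unknown observable {name!r}")


def mesh_sensitivity(case: FixtureCase | None = None, levels: int = 3,
                     base_grid: tuple[int, int] = (96, 24),
                     observable: str = "u_max",
                     cfg: SolverConfig | None = None) -> ConvergenceReport:
    """Grid-convergence study with refinement ratio 2.

    Solves the case on ``levels`` grids starting at ``base_grid`` and doubling
    both counts per level, then computes the observed order
    p = ln((f1 - f2)/(f2 - f3)) / ln 2, the Richardson extrapolate and the GCI
    (safety factor 1.25).  A non-monotone value sequence is reported with
    ``asymptotic=False`` rather than raised.
    """
    if levels < 3:
        raise ValueError("need at least 3 grid levels")
    if case is None:
        case = default_verification_case()
    grids = [(base_grid[0] * 2 ** k, base_grid[1] * 2 ** k) for k in range(levels)]
    values = [_observable(case, nx, ny, observable, cfg) for nx, ny in grids]

    rep = ConvergenceReport(case_label=case.label, observable=observable,
                            grids=grids, values=values)
    f1, f2, f3 = values[-3], values[-2], values[-1]
    d1, d2 = f2 - f1, f3 - f2
    rep.monotone = bool(d1 * d2 > 0)
    scale = max(abs(f3), 1e-300)
    if max(abs(d1), abs(d2)) < 1e-6 * scale:
        # levels indistinguishable (roundoff level): the scheme resolves this
        # case exactly
        rep.asymptotic = True
        rep.observed_order = float("nan")
        rep.extrapolated = f3
        rep.gci = [0.0]
        return rep
    if rep.monotone:
        p = float(np.log(abs(d1 / d2)) / np.log(2.0))
        rep.observed_order = p
        if p > 0.2:
            rep.extrapolated = f3 + d2 / (2.0 ** p - 1.0)
            rep.gci = [float(1.25 * abs(d2 / f3) / (2.0 ** p - 1.0))]
            rep.asymptotic = abs(d2) < abs(d1)
        else:
            rep.extrapolated = f3
            rep.gci = [float(1.25 * abs(d2 / f3))]
    return rep


def verification_report(seed: int = 0, n_random: int = 100) -> dict:
    """End-to-end verification summary (used by the ``verify`` CLI command).

    Runs the Poiseuille oracle comparison, the randomized geometry-invariant
    suite and the default grid-convergence study, returning one JSON-ready
    record.
    """
    rec = {}

    case = make_poiseuille_case()
    grid = generate_grid(case.geom, 32, 64)
    flow = solve_flow(case.geom, case.fluid, case.op, grid)
    y = grid.Y[grid.nx // 2, :] * 1e-6
    u_num = flow.u[grid.nx // 2, :]
    u_ex = case.closed_form["u"](y)
    rec["poiseuille_uerr_rel"] = float(np.max(np.abs(u_num - u_ex)) / u_ex.max())
    smap = shear_rate_field(flow)
    rec["poiseuille_wall_shear_rel_err"] = float(
        abs(smap.walls["bottom"]["gamma_wall"][grid.nx // 2]
            - case.closed_form["wall_shear"]) / case.closed_form["wall_shear"])
    rec["poiseuille_mass_imbalance"] = flow.mass_imbalance

    geoms = random_geometry_suite(n_random, seed)
    throat_err = max(
        abs(float(np.min(g.gap(np.linspace(g.x_min, g.x_max, 4001))))
            - g.throat_width) / g.Y0
        for g in geoms)
    rec["random_geometries"] = len(geoms)
    rec["max_throat_identity_err"] = float(throat_err)

    rep = mesh_sensitivity()
    rec["mesh_study"] = rep.as_dict()
    return rec
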