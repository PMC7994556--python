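"""The four parametric studies: reproducible sweeps over the control variables.

Study 1 sweeps the bulk shear rate gamma0 (150-3000 1/s) at the default
geometry; study 2 the stenosis level S (30-95%); study 3 the contraction
angle alpha (30-85 deg); study 4 benchmarks the working fluid (water,
Newtonian blood, shear-thinning blood) over gamma0 = 50-1050 1/s.  Each member
run builds the geometry, solves the steady flow and extracts the peak
observables (gamma_max and gamma'_max along the platelet trajectory, tau_max
on the walls); results are returned as a tidy table with fold changes
relative to the first swept value and, for the gamma0 sweep, the fitted
slope and R^2 of the peak-versus-gamma0 line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import build_geometry, generate_grid
from .hemodynamics_post import peak_summary, platelet_trajectory_profile, \
    shear_rate_field
from .operating_point import make_operating_point
from .rheology import BLOOD_GPL, BLOOD_NEWTONIAN, WATER, FluidModel
from .flow_solver import SolverConfig, solve_flow

__all__ = ["STUDIES", "SweepResult", "run_study", "report"]

#: control-variable grids and per-study defaults
STUDIES = {
    "gamma0_sweep": {
        "variable": "gamma0",
        "values": [150.0, 600.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0],
        "defaults": {"S": 0.8, "alpha": 85.0, "fluid": "blood"},
    },
    "S_sweep": {
        "variable": "S",
        "values": [0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95],
        "defaults": {"gamma0": 1000.0, "alpha": 85.0, "fluid": "blood"},
    },
    "alpha_sweep": {
        "variable": "alpha",
        "values": [30.0, 45.0, 60.0, 75.0, 85.0],
        "defaults": {"gamma0": 1000.0, "S": 0.8, "fluid": "blood"},
    },
    "medium_benchmark": {
        "variable": "fluid",
        "values": ["water", "blood", "blood-gpl"],
        #: desk-scale selection spanning the 50-1050 1/s benchmark window
        "gamma0_values": [50.0, 550.0, 1050.0],
        "defaults": {"S": 0.8, "alpha": 85.0},
    },
}

_FLUIDS = {"water": WATER, "blood": BLOOD_NEWTONIAN, "blood-gpl": BLOOD_GPL}

DEFAULT_GRID = (384, 96)


@dataclass
class SweepResult:
    """Tidy result of one study sweep."""

    study: str
    variable: str
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def fold_changes(self, column: str = "gamma_max") -> pd.DataFrame:
        """Per-group fold change of a peak column relative to the first value."""
        gcols = [c for c in ("placement", "fluid") if c != self.variable
                 and c in self.df.columns]
        out = self.df.copy()
        out["fold_change"] = out.groupby(gcols or (lambda _: 0))[column] \
            .transform(lambda s: s / s.iloc[0])
        return out


def _one_run(gamma0: float, S: float, alpha: float, placement: str,
             fluid: FluidModel, grid_size, solver_cfg) -> dict:
    geom = build_geometry(S=S, alpha=alpha, placement=placement)
    grid = generate_grid(geom, *grid_size)
    op = make_operating_point(gamma0, fluid)
    flow = solve_flow(geom, fluid, op, grid, solver_cfg)
    smap = shear_rate_field(flow)
    prof = platelet_trajectory_profile(flow, smap)
    rec = {"gamma0": gamma0, "S": S, "alpha": alpha, "placement": placement,
           "fluid": fluid.name, "Q_uL_min": op.Q_uL_min, "Re": op.Re,
           "iterations": flow.iterations, "mass_imbalance": flow.mass_imbalance}
    rec.update(peak_summary(prof, smap))
    return rec


def run_study(study: str, placements=("eccentric", "concentric"),
              grid_size=DEFAULT_GRID, solver_cfg: SolverConfig | None = None,
              values=None, gamma0_values=None, logger=None) -> SweepResult:
    """Run one of the four sweeps; any failing member aborts the sweep.

    ``values`` (and ``gamma0_values`` for the medium benchmark) override the
    standard grids, e.g. for reduced-size runs.
    """
    if study not in STUDIES:
        raise ValueError(f"unknown study {study!r}; expected one of {sorted(STUDIES)}")
    spec = STUDIES[study]
    var = spec["variable"]
    vals = list(values if values is not None else spec["values"])
    defaults = spec["defaults"]

    rows = []
    for placement in placements:
        for val in vals:
            params = {
                "gamma0": defaults.get("gamma0"),
                "S": defaults.get("S"),
                "alpha": defaults.get("alpha"),
                "fluid": defaults.get("fluid", "blood"),
            }
            params[var] = val
            fluid = _FLUIDS[params["fluid"]] if isinstance(params["fluid"], str) \
                else params["fluid"]
            g0_list = [params["gamma0"]]
            if study == "medium_benchmark":
                g0_list = list(gamma0_values if gamma0_values is not None
                               else spec["gamma0_values"])
            for g0 in g0_list:
                try:
                    if logger:
                        logger.info("run %s: %s=%s placement=%s gamma0=%s",
                                    study, var, val, placement, g0)
                    rows.append(_one_run(g0, params["S"], params["alpha"],
                                         placement, fluid, grid_size, solver_cfg))
                except Exception as exc:
                    raise RuntimeError(
                        f"sweep {study!r} failed at {var}={val}, "
                        f"placement={placement}, gamma0={g0}: {exc}") from exc

    df = pd.DataFrame(rows)
    meta = {"study": study, "variable": var, "values": vals,
            "defaults": defaults, "grid": list(grid_size),
            "placements": list(placements)}
    if study == "gamma0_sweep":
        meta["fits"] = {}
        for placement, sub in df.groupby("placement"):
            coef = np.polyfit(sub["gamma0"], sub["gamma_max"], 1)
            pred = np.polyval(coef, sub["gamma0"])
            ss_res = float(np.sum((sub["gamma_max"] - pred) ** 2))
            ss_tot = float(np.sum((sub["gamma_max"] - sub["gamma_max"].mean()) ** 2))
            meta["fits"][placement] = {
                "slope": float(coef[0]), "intercept": float(coef[1]),
                "r2": 1.0 - ss_res / ss_tot}
    return SweepResult(study=study, variable=var, df=df, meta=meta)


def report(result: SweepResult, outdir) -> dict:
    """Write the per-study CSV, summary JSON and peak-vs-variable figure.

    Output is deterministic for identical results: fixed float formatting,
    sorted JSON keys, no timestamps.
    """
    from pathlib import Path
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .io import write_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = result.fold_changes()
    csv_path = outdir / f"{result.study}.csv"
    df.to_csv(csv_path, index=False, float_format="%.8g")

    summary = {"meta": result.meta}
    for (keys), sub in df.groupby([c for c in ("placement", "fluid")
                                   if c in df.columns]):
        label = "/".join(map(str, keys if isinstance(keys, tuple) else (keys,)))
        summary[label] = {
            "gamma_max_fold": float(sub["gamma_max"].iloc[-1]
                                    / sub["gamma_max"].iloc[0]),
            "tau_max_fold": float(sub["tau_max_Pa"].iloc[-1]
                                  / sub["tau_max_Pa"].iloc[0]),
        }
    json_path = outdir / f"{result.study}_summary.json"
    write_json(json_path, summary)

    xcol = result.variable if result.variable != "fluid" else "gamma0"
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (keys), sub in df.groupby([c for c in ("placement", "fluid")
                                   if c in df.columns]):
        label = "/".join(map(str, keys if isinstance(keys, tuple) else (keys,)))
        ax.plot(sub[xcol], sub["gamma_max"], "o-", label=label, ms=4)
    ax.set_xlabel(xcol)
    ax.set_ylabel(r"peak shear rate $\gamma_{max}$ (1/s)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    png_path = outdir / f"{result.study}.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    return {"csv": str(csv_path), "json": str(json_path), "png": str(png_path)}
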