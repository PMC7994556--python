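"""Run configuration, structured output and logging helpers.

Configurations are YAML mappings with ``geometry``, ``fluid``, ``operating``,
``solver`` and ``output`` blocks; every key has a default, so an empty file is
a valid configuration (the default study case).  Outputs are plain text:
legacy-ASCII VTK structured grids for fields, tidy CSV for curves and sweeps,
JSON for scalar records.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .geometry import StenosisGeometry
from .rheology import BLOOD_GPL, BLOOD_NEWTONIAN, WATER, FluidModel

__all__ = ["load_config", "config_hash", "geometry_from_config",
           "fluid_from_config", "write_vtk_structured_grid", "write_json",
           "setup_logging"]

CONFIG_DEFAULTS = {
    "geometry": {
        "X0_um": 200.0, "Y0_um": 100.0, "Z0_um": 130.0,
        "S": 0.8, "alpha_deg": 85.0, "placement": "eccentric",
        "fillet_um": None,          # None -> package default
    },
    "fluid": "blood",               # water | blood | blood-gpl, or a mapping
    "operating": {"gamma0_s_inv": 1000.0, "f_Hz": None},
    "solver": {"nx": 384, "ny": 96, "tol": 1e-7, "max_iter": 200},
    "output": {"outdir": "results"},
}

NAMED_FLUIDS = {"water": WATER, "blood": BLOOD_NEWTONIAN, "blood-gpl": BLOOD_GPL}


def _merge(defaults, user):
    if not isinstance(user, dict):
        return user if user is not None else defaults
    out = dict(defaults)
    for k, v in user.items():
        out[k] = _merge(defaults.get(k, {}), v) if isinstance(v, dict) else v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Read a YAML run configuration, filling every missing key with defaults."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {k: _merge(v, user.get(k)) if isinstance(v, dict) else user.get(k, v)
           for k, v in CONFIG_DEFAULTS.items()}
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash stamped on every run's outputs and logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def geometry_from_config(cfg: dict) -> StenosisGeometry:
    g = cfg["geometry"]
    kwargs = {}
    if g.get("fillet_um") is not None:
        kwargs["fillet_radius"] = float(g["fillet_um"])
    return StenosisGeometry(
        X0=float(g["X0_um"]), Y0=float(g["Y0_um"]), Z0=float(g["Z0_um"]),
        S=float(g["S"]), alpha=float(g["alpha_deg"]),
        placement=g["placement"], **kwargs)


def fluid_from_config(cfg: dict) -> FluidModel:
    f = cfg["fluid"]
    if isinstance(f, str):
        try:
            return NAMED_FLUIDS[f]
        except KeyError:
            raise ValueError(f"unknown fluid {f!r}; expected one of "
                             f"{sorted(NAMED_FLUIDS)}") from None
    return FluidModel(name=f.get("name", "custom"), rho=float(f["rho"]),
                      law=f.get("law", "newtonian"),
                      mu=f.get("mu"), params=f.get("params", {}))


def write_vtk_structured_grid(path: str | Path, X: np.ndarray, Y: np.ndarray,
                              point_data: dict | None = None) -> None:
    """Write a 2D structured grid (nodes in um) as legacy-ASCII VTK.

    ``point_data`` values are nodal arrays of shape ``X.shape`` (scalars) or
    tuples ``(u, v)`` of such arrays (vectors, z = 0).
    """
    nxp, nyp = X.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstenoflow field\nASCII\n")
        fh.write("DATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nxp} {nyp} 1\n")
        fh.write(f"POINTS {nxp * nyp} double\n")
        for j in range(nyp):
            for i in range(nxp):
                fh.write(f"{X[i, j]:.10g} {Y[i, j]:.10g} 0\n")
        if point_data:
            fh.write(f"POINT_DATA {nxp * nyp}\n")
            for name, arr in point_data.items():
                if isinstance(arr, tuple):
                    u, v = arr
                    fh.write(f"VECTORS {name} double\n")
                    for j in range(nyp):
                        for i in range(nxp):
                            fh.write(f"{u[i, j]:.10g} {v[i, j]:.10g} 0\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for j in range(nyp):
                        for i in range(nxp):
                            fh.write(f"{arr[i, j]:.10g}\n")


def write_json(path: str | Path, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def setup_logging(outdir: str | Path | None = None, level: str = "INFO",
                  run_hash: str = "") -> logging.Logger:
    """Console + optional per-run file logging, stamped with the config hash."""
    logger = logging.getLogger("stenoflow")
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    fmt = logging.Formatter(
        f"%(asctime)s %(levelname)s [{run_hash or 'no-config'}] %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(outdir) / "run.log")
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
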