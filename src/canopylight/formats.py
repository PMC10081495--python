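"""File-format plumbing: CSV tables, parameter JSON, meshes, results.

Units are fixed package-wide (µmol, m, s; percent for ``p_ad``/``p_dw``) and
asserted at the IO boundary; there is no unit inference.

Schemas
-------
gas exchange CSV: ``E`` (total PPFD, µmol m⁻² s⁻¹), ``p_ad`` (%), ``pn``
(µmol m⁻² s⁻¹), ``das`` (int), ``leaf_rank`` (int).

ETR CSV: ``J`` (µmol m⁻² s⁻¹), ``surface`` (``adaxial``/``abaxial``), ``E``,
``das``, ``leaf_rank``.

Parameter JSON: one record per leaf class with the five bilateral parameters,
``rd``, the shape coefficients, and convergence diagnostics.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import trimesh

from .exceptions import DomainError
from .fitting import BilateralFitResult
from .leaf import BilateralLRCParams, ShapeParams

GAS_EXCHANGE_COLUMNS = ("E", "p_ad", "pn", "das", "leaf_rank")
ETR_COLUMNS = ("J", "surface", "E", "das", "leaf_rank")


def _check_columns(df: pd.DataFrame, required, label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"{label} is missing columns {missing}")


def read_gas_exchange(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GAS_EXCHANGE_COLUMNS, "gas-exchange table")
    bad = df.index[(df["E"] < 0) | (df["p_ad"] < 0) | (df["p_ad"] > 100)].tolist()
    if bad:
        raise DomainError(f"gas-exchange rows out of range (0-based): {bad}")
    return df


def read_etr(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ETR_COLUMNS, "ETR table")
    bad = df.index[
        (df["J"] < 0) | (~df["surface"].isin(["adaxial", "abaxial"]))
    ].tolist()
    if bad:
        raise DomainError(f"ETR rows out of range (0-based): {bad}")
    return df


def params_to_dict(params: BilateralLRCParams) -> dict:
    return {
        "phi_ad": params.phi_ad,
        "phi_ab": params.phi_ab,
        "p_max": params.p_max,
        "theta_ad": params.theta_ad,
        "theta_ab": params.theta_ab,
        "rd": params.rd,
        "shape_a": list(params.shape.a),
        "shape_b": list(params.shape.b),
    }


def params_from_dict(d: dict) -> BilateralLRCParams:
    return BilateralLRCParams(
        phi_ad=d["phi_ad"],
        phi_ab=d["phi_ab"],
        p_max=d["p_max"],
        theta_ad=d["theta_ad"],
        theta_ab=d["theta_ab"],
        rd=d["rd"],
        shape=ShapeParams(a=tuple(d["shape_a"]), b=tuple(d["shape_b"])),
    )


def write_fit_results(path, fits: dict[str, BilateralFitResult], meta: dict | None = None):
    """Write per-leaf-class fitted parameters with convergence diagnostics."""
    payload = {"meta": meta or {}, "classes": {}}
    for key, fit in fits.items():
        payload["classes"][key] = {
            **params_to_dict(fit.params),
            "converged": bool(fit.converged),
            "n_iter": fit.n_iter,
            "objective_path": fit.objective_path,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_fit_results(path) -> dict[str, BilateralLRCParams]:
    with open(path) as fh:
        payload = json.load(fh)
    return {k: params_from_dict(v) for k, v in payload["classes"].items()}


def write_irradiance(path, irr) -> None:
    irr.triangles.to_csv(path, index=False, float_format="%.6g")


def load_plant_mesh(path) -> trimesh.Trimesh:
    """Load an externally supplied plant mesh (OBJ/PLY) as a triangle soup."""
    mesh = trimesh.load(path, force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise DomainError(f"no triangles found in {path}")
    return mesh


def plant_to_trimesh(plant) -> trimesh.Trimesh:
    """Convert a :class:`~canopylight.canopy.PlantModel` to a trimesh object."""
    tris = np.concatenate([plant.blade_tris, plant.petiole_tris])
    v = tris.reshape(-1, 3)
    f = np.arange(len(v)).reshape(-1, 3)
    return trimesh.Trimesh(vertices=v, faces=f, process=False)
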