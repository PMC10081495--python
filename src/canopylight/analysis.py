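"""Canopy-level photosynthesis and light metrics over the experiment grid.

Per-triangle two-sided irradiances from the transport engine are converted to
net photosynthesis through the bilateral leaf model of each triangle's leaf
rank, then summed over the canopy:

    CPn = sum_i Pn_i * A_i,      CPg = sum_i (Pn_i - Rd_rank(i)) * A_i.

Light metrics per condition: the photon flux incident on the canopy
``Phi_leaves = sum_i E_i * A_i`` (all crossings, both sides), the
area-weighted mean leaf PPFD, and the area-weighted population standard
deviation ``SD_E`` of per-triangle total PPFD — the index of spatial PPFD
uniformity within the canopy.

The default experiment grid crosses five leaf-area-index levels, four total
lamp fluxes and eleven downward-lighting fractions (220 conditions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, MissingDataError
from .leaf import BilateralLRCParams, bilateral_pn_arrays
from .scene import ExperimentCondition, build_scene
from .transport import IrradianceMap, trace

__all__ = [
    "DEFAULT_LAI_LEVELS",
    "DEFAULT_PHI_LEVELS",
    "DEFAULT_PDW_LEVELS",
    "CanopyMetrics",
    "canopy_pn",
    "canopy_light_metrics",
    "condition_grid",
    "run_grid",
    "ratio_to_downward_only",
    "vertical_profile",
    "normalize_metrics",
    "lamp_cost_share",
    "default_leaf_params",
]

DEFAULT_LAI_LEVELS = (0.5, 1.5, 2.5, 3.5, 4.5)
DEFAULT_PHI_LEVELS = (122.0, 244.0, 366.0, 488.0)  # µmol s⁻¹
DEFAULT_PDW_LEVELS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)


@dataclass(frozen=True)
class CanopyMetrics:
    """Summary of one simulated condition."""

    cpn: float  # canopy net photosynthetic rate, µmol s⁻¹
    cpg: float  # canopy gross rate, µmol s⁻¹
    phi_leaves: float  # photon flux incident on leaves, µmol s⁻¹
    sd_e: float  # area-weighted SD of per-triangle total PPFD, µmol m⁻² s⁻¹
    mean_ppfd: float  # area-weighted mean total leaf PPFD, µmol m⁻² s⁻¹


def default_leaf_params(n_leaves: int = 7) -> dict[int, BilateralLRCParams]:
    """Built-in bilateral parameter set per leaf rank (0 = cotyledon).

    The measured second- and third-leaf maxima anchor the profile; other
    ranks follow a hump-shaped capacity profile typical of a young rosette.
    Anchors: adaxial slope/convexity exceed the abaxial ones, reflecting the
    lower absorptance and chloroplast activity of the abaxial side.
    """
    pmax_profile = {0: 35.0, 1: 45.0, 2: 50.2, 3: 53.7, 4: 50.0, 5: 45.0, 6: 38.0}
    out = {}
    for rank in range(n_leaves):
        p_max = pmax_profile.get(rank, 38.0)
        out[rank] = BilateralLRCParams(
            phi_ad=0.055,
            phi_ab=0.042,
            p_max=p_max,
            theta_ad=0.75,
            theta_ab=0.55,
            rd=-0.03 * p_max,
        )
    return out


def canopy_pn(
    irr: IrradianceMap, params_by_rank: dict[int, BilateralLRCParams]
) -> tuple[float, float]:
    """Canopy net and gross photosynthetic rates (µmol s⁻¹) from an irradiance map."""
    df = irr.triangles
    if len(df) == 0:
        raise MissingDataError("empty irradiance map")
    cpn = 0.0
    cpg = 0.0
    for rank, sub in df.groupby("rank"):
        rank = int(rank)
        if rank not in params_by_rank:
            raise MissingDataError(f"no leaf parameters for rank {rank}")
        params = params_by_rank[rank]
        pn = bilateral_pn_arrays(
            sub["e_ad"].to_numpy(), sub["e_ab"].to_numpy(), params
        )
        a = sub["area"].to_numpy()
        cpn += float(np.sum(pn * a))
        cpg += float(np.sum((pn - params.rd) * a))
    return cpn, cpg


def canopy_light_metrics(irr: IrradianceMap) -> tuple[float, float, float]:
    """``(phi_leaves, sd_e, mean_ppfd)`` for an irradiance map.

    All three are area-weighted over leaf triangles; per-triangle PPFD sums
    both sides.  ``sd_e`` uses the population (not sample) convention.
    """
    df = irr.triangles
    if len(df) == 0:
        raise MissingDataError("empty irradiance map")
    e = (df["e_ad"] + df["e_ab"]).to_numpy()
    a = df["area"].to_numpy()
    total_area = float(a.sum())
    phi_leaves = float(np.sum(e * a))
    mean_ppfd = phi_leaves / total_area
    sd_e = float(np.sqrt(np.sum(a * (e - mean_ppfd) ** 2) / total_area))
    return phi_leaves, sd_e, mean_ppfd


def condition_grid(
    lai_levels=DEFAULT_LAI_LEVELS,
    phi_levels=DEFAULT_PHI_LEVELS,
    pdw_levels=DEFAULT_PDW_LEVELS,
) -> list[ExperimentCondition]:
    """Enumerate the experiment conditions (default 5 x 4 x 11 = 220)."""
    if not (len(lai_levels) and len(phi_levels) and len(pdw_levels)):
        raise DomainError("all grid level lists must be non-empty")
    return [
        ExperimentCondition(lai=la, phi_lamps=ph, p_dw=pd)
        for la, ph, pd in itertools.product(lai_levels, phi_levels, pdw_levels)
    ]


def run_condition(
    condition: ExperimentCondition,
    photons: int,
    seed: int,
    params_by_rank: dict[int, BilateralLRCParams] | None = None,
    **scene_kwargs,
) -> tuple[CanopyMetrics, IrradianceMap]:
    """Simulate one condition: build scene, trace, aggregate."""
    params_by_rank = params_by_rank or default_leaf_params()
    ss = np.random.SeedSequence(seed)
    canopy_seed, trace_seed = (int(s & 0x7FFFFFFF) for s in ss.generate_state(2))
    scene = build_scene(condition, seed=canopy_seed, **scene_kwargs)
    irr = trace(scene, n_photons=photons, seed=trace_seed)
    cpn, cpg = canopy_pn(irr, params_by_rank)
    phi_leaves, sd_e, mean_ppfd = canopy_light_metrics(irr)
    return (
        CanopyMetrics(
            cpn=cpn, cpg=cpg, phi_leaves=phi_leaves, sd_e=sd_e, mean_ppfd=mean_ppfd
        ),
        irr,
    )


def run_grid(
    lai_levels=DEFAULT_LAI_LEVELS,
    phi_levels=DEFAULT_PHI_LEVELS,
    pdw_levels=DEFAULT_PDW_LEVELS,
    photons: int = 10_000,
    seed: int = 0,
    params_by_rank: dict[int, BilateralLRCParams] | None = None,
    progress=None,
    **scene_kwargs,
) -> pd.DataFrame:
    """Run the full condition grid; one row per condition.

    Per-condition seeds derive deterministically from the master ``seed``.
    Failed conditions are recorded (``error`` column) and the run continues.
    """
    conditions = condition_grid(lai_levels, phi_levels, pdw_levels)
    rows = []
    for k, cond in enumerate(conditions):
        cond_seed = int(
            np.random.SeedSequence([seed, k]).generate_state(1)[0] & 0x7FFFFFFF
        )
        row = {
            "lai": cond.lai,
            "phi_lamps": cond.phi_lamps,
            "p_dw": cond.p_dw,
            "seed": cond_seed,
            "photons": photons,
            "error": "",
        }
        try:
            metrics, _ = run_condition(
                cond, photons, cond_seed, params_by_rank, **scene_kwargs
            )
            row.update(
                cpn=metrics.cpn,
                cpg=metrics.cpg,
                phi_leaves=metrics.phi_leaves,
                sd_e=metrics.sd_e,
                mean_ppfd=metrics.mean_ppfd,
            )
        except Exception as exc:  # record and continue per-condition failures
            row.update(
                cpn=np.nan, cpg=np.nan, phi_leaves=np.nan, sd_e=np.nan, mean_ppfd=np.nan
            )
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if progress is not None:
            progress(k + 1, len(conditions), row)
    return pd.DataFrame(rows)


def ratio_to_downward_only(results: pd.DataFrame) -> pd.DataFrame:
    """Per (lai, phi_lamps): the CPn-maximizing ``p_dw`` and its CPg ratio.

    The ratio compares canopy gross rate at the optimum with the downward-only
    baseline (``p_dw = 100``); ties in CPn resolve to the larger ``p_dw``.
    A zero baseline is flagged (``ratio_defined = False``) rather than divided.
    """
    out = []
    for (lai, phi), grp in results.groupby(["lai", "phi_lamps"]):
        base = grp.loc[grp["p_dw"] == 100.0]
        if len(base) == 0:
            raise MissingDataError(
                f"group (lai={lai}, phi={phi}) lacks the p_dw = 100 baseline"
            )
        cpn = grp["cpn"].to_numpy()
        pdw = grp["p_dw"].to_numpy()
        best_cpn = np.nanmax(cpn)
        best_pdw = float(np.max(pdw[cpn >= best_cpn - 1e-12]))
        cpg_best = float(grp.loc[grp["p_dw"] == best_pdw, "cpg"].iloc[0])
        cpg_base = float(base["cpg"].iloc[0])
        defined = cpg_base != 0.0
        out.append(
            {
                "lai": lai,
                "phi_lamps": phi,
                "best_p_dw": best_pdw,
                "cpn_max": float(best_cpn),
                "cpg_ratio": cpg_best / cpg_base if defined else np.nan,
                "ratio_defined": defined,
            }
        )
    return pd.DataFrame(out)


def vertical_profile(irr: IrradianceMap, n_layers: int) -> pd.DataFrame:
    """Area-weighted mean total PPFD per horizontal layer of the canopy."""
    if n_layers < 1:
        raise DomainError("n_layers must be >= 1")
    df = irr.triangles
    if len(df) == 0:
        raise MissingDataError("empty irradiance map")
    z = df["z"].to_numpy()
    e = (df["e_ad"] + df["e_ab"]).to_numpy()
    a = df["area"].to_numpy()
    zlo, zhi = float(z.min()), float(z.max())
    if zhi == zlo:
        edges = np.array([zlo - 0.5, zhi + 0.5])
        n_layers = 1
    else:
        edges = np.linspace(zlo, zhi, n_layers + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_layers - 1)
    rows = []
    for layer in range(n_layers):
        m = idx == layer
        area = float(a[m].sum())
        rows.append(
            {
                "layer": layer,
                "z_lo": float(edges[layer]),
                "z_hi": float(edges[layer + 1]),
                "area": area,
                "mean_ppfd": float(np.sum(e[m] * a[m]) / area) if area > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def normalize_metrics(
    results: pd.DataFrame,
    columns=("phi_leaves", "sd_e"),
    group_keys=("lai", "phi_lamps"),
) -> pd.DataFrame:
    """Divide each metric by its within-group maximum (outputs in (0, 1]).

    All-zero groups are flagged via ``<col>_norm_defined`` instead of divided.
    """
    out = results.copy()
    for col in columns:
        out[f"{col}_norm"] = np.nan
        out[f"{col}_norm_defined"] = True
    for _, grp in results.groupby(list(group_keys)):
        for col in columns:
            mx = grp[col].max()
            if not np.isfinite(mx) or mx == 0:
                out.loc[grp.index, f"{col}_norm_defined"] = False
            else:
                out.loc[grp.index, f"{col}_norm"] = grp[col] / mx
    return out


def lamp_cost_share(depr_share: float, lamp_fraction: float) -> float:
    """Lamp depreciation as a percentage of total production cost.

    ``depr_share`` is the fraction of production cost that is depreciation;
    ``lamp_fraction`` the fraction of depreciation attributable to lamps.
    """
    for name, v in (("depr_share", depr_share), ("lamp_fraction", lamp_fraction)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    return 100.0 * depr_share * lamp_fraction
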