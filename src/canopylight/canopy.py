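"""Synthetic komatsuna stand-ins: rosette meshes, gas-exchange and ETR records.

The study's photogrammetric plant reconstructions and raw physiological data
are not deposited, so this module generates replacements with the statistical
structure the analysis assumes:

* :func:`generate_plant` — a rosette of elliptical, gently drooping leaf
  blades on short petioles, spiral (golden-angle) phyllotaxis, rank-dependent
  size and elevation.  Blade triangle count is ~100 per plant and the summed
  one-sided blade area is rescaled to the target (110.2 cm² by default, well
  inside the 90-110% window used for the reconstructed meshes).  All blade
  triangle normals point to the adaxial (upper) side at generation pose.
* :func:`generate_gas_exchange` — net photosynthesis records on the
  measurement grid of 10 total-PPFD levels x 7 adaxial proportions, with
  multiplicative Gaussian noise whose spread scales with the gross rate
  (the rationale for the 1/Pg² fitting weights).
* :func:`generate_etr` — electron-transport-rate light-response records per
  irradiated surface, obtained by pushing single-surface gross rates through
  the inverse of a known through-origin quadratic calibration.

Every generator is a pure function of its seed and arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .fitting import ETRCalibration
from .leaf import BilateralLRCParams, bilateral_pn_arrays, gross_rate
from .scene import MEAN_BLADE_AREA_M2, PlantingLayout

__all__ = [
    "DEFAULT_E_LEVELS",
    "DEFAULT_PAD_LEVELS",
    "PlantModel",
    "generate_plant",
    "generate_gas_exchange",
    "generate_etr",
    "place_canopy",
]

#: Total-PPFD levels of the gas-exchange measurement design (µmol m⁻² s⁻¹).
DEFAULT_E_LEVELS = (0.0, 30.0, 70.0, 150.0, 240.0, 330.0, 470.0, 700.0, 1100.0, 1900.0)
#: Adaxial-proportion levels of the design (%); 1% is the near-abaxial extreme.
DEFAULT_PAD_LEVELS = (1.0, 17.0, 33.0, 50.0, 67.0, 83.0, 100.0)

_GOLDEN_ANGLE = math.radians(137.507764)

# Relative one-sided blade area by leaf rank (0 = cotyledon) for a 7-leaf
# rosette; normalized at build time.  Mid-rank leaves dominate.
_RANK_AREA_WEIGHTS = (0.25, 0.45, 0.90, 1.25, 1.20, 0.85, 0.50)


@dataclass
class PlantModel:
    """One synthetic rosette plant.

    ``blade_tris``: (n, 3, 3) world vertices of blade triangles, wound so the
    geometric normal points to the adaxial side; ``blade_rank``: leaf rank per
    triangle; ``petiole_tris``: petiole triangle soup.
    """

    blade_tris: np.ndarray
    blade_rank: np.ndarray
    petiole_tris: np.ndarray
    target_area: float

    @property
    def blade_area(self) -> float:
        return float(np.sum(triangle_areas(self.blade_tris)))

    def export_obj(self, path, plant_id: int = 0) -> None:
        """Write the plant as an OBJ file, one object per organ and rank."""
        with open(path, "w") as fh:
            fh.write("# canopylight synthetic rosette plant\n")
            v_off = 1
            for rank in np.unique(self.blade_rank):
                tris = self.blade_tris[self.blade_rank == rank]
                fh.write(f"o plant{plant_id}_blade_rank{int(rank)}\n")
                v_off = _write_obj_tris(fh, tris, v_off)
            if len(self.petiole_tris):
                fh.write(f"o plant{plant_id}_petioles\n")
                _write_obj_tris(fh, self.petiole_tris, v_off)


def _write_obj_tris(fh, tris: np.ndarray, v_off: int) -> int:
    for t in tris:
        for v in t:
            fh.write(f"v {v[0]:.7f} {v[1]:.7f} {v[2]:.7f}\n")
    for i in range(len(tris)):
        a = v_off + 3 * i
        fh.write(f"f {a} {a + 1} {a + 2}\n")
    return v_off + 3 * len(tris)


def triangle_areas(tris: np.ndarray) -> np.ndarray:
    """Areas of a (n, 3, 3) triangle soup."""
    if len(tris) == 0:
        return np.zeros(0)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def _blade_mesh(length: float, width: float, elevation: float, droop: float, ns: int):
    """Triangulate one blade: a tapered strip along a drooping midrib.

    Returns an (2*ns - 2, 3, 3) array in the blade's local frame (growing
    along +x, adaxial normal towards +z at zero elevation).
    """
    s = np.linspace(0.0, 1.0, ns + 1)
    ang = elevation - droop * (s[:-1] + s[1:]) / 2.0
    step = length / ns
    mid = np.zeros((ns + 1, 3))
    for i in range(ns):
        mid[i + 1] = mid[i] + step * np.array([math.cos(ang[i]), 0.0, math.sin(ang[i])])
    half = 0.5 * width * np.sin(np.pi * s) ** 0.8
    left = mid + np.outer(half, [0.0, 1.0, 0.0])
    right = mid - np.outer(half, [0.0, 1.0, 0.0])

    tris = []
    tris.append([mid[0], right[1], left[1]])
    for i in range(1, ns - 1):
        tris.append([left[i], right[i], right[i + 1]])
        tris.append([left[i], right[i + 1], left[i + 1]])
    tris.append([left[ns - 1], right[ns - 1], mid[ns]])
    return np.array(tris)


def _petiole_mesh(start: np.ndarray, end: np.ndarray, half_width: float):
    """Two perpendicular thin quads along the petiole segment (4 triangles)."""
    d = end - start
    n1 = np.array([0.0, 1.0, 0.0])
    axis = d / np.linalg.norm(d)
    n1 = n1 - axis * (n1 @ axis)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(axis, n1)
    tris = []
    for n in (n1, n2):
        a, b = start + half_width * n, start - half_width * n
        c, e = end - half_width * n, end + half_width * n
        tris.append([a, b, c])
        tris.append([a, c, e])
    return np.array(tris)


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_plant(
    seed: int,
    target_area: float = MEAN_BLADE_AREA_M2,
    n_leaves: int = 7,
    n_blade_tris: int = 100,
) -> PlantModel:
    """Generate one seeded rosette plant.

    Blade areas follow a rank-dependent weight profile summing exactly to
    ``target_area``; azimuths follow golden-angle phyllotaxis with seeded
    jitter; elevation increases with rank (younger leaves stand more upright).
    """
    if n_leaves < 1 or target_area <= 0:
        raise DomainError("need n_leaves >= 1 and target_area > 0")
    rng = np.random.default_rng(seed)
    weights = np.array(
        [_RANK_AREA_WEIGHTS[min(r, len(_RANK_AREA_WEIGHTS) - 1)] for r in range(n_leaves)],
        dtype=float,
    )
    areas = target_area * weights / weights.sum()
    ns = max(3, int(round((n_blade_tris / n_leaves + 2) / 2)))

    blade_list, rank_list, petiole_list = [], [], []
    width_ratio = 0.62
    for rank in range(n_leaves):
        elevation = math.radians(20.0 + 5.0 * rank + rng.normal(0.0, 3.0))
        droop = math.radians(rng.uniform(25.0, 40.0))
        unit = _blade_mesh(1.0, width_ratio, elevation, droop, ns)
        k = math.sqrt(areas[rank] / float(np.sum(triangle_areas(unit))))
        blade = unit * k
        azimuth = rank * _GOLDEN_ANGLE + rng.normal(0.0, math.radians(10.0))
        rot = _rot_z(azimuth)

        pet_len = 0.30 * k + 0.008
        pet_elev = elevation + math.radians(8.0)
        pet_start = np.array([0.0, 0.0, 0.003])
        pet_end = pet_start + pet_len * np.array(
            [math.cos(pet_elev), 0.0, math.sin(pet_elev)]
        )
        blade = blade + pet_end
        petiole = _petiole_mesh(pet_start, pet_end, 0.0015)

        blade = blade @ rot.T
        petiole = petiole @ rot.T
        blade_list.append(blade)
        rank_list.append(np.full(len(blade), rank, dtype=np.int32))
        petiole_list.append(petiole)

    model = PlantModel(
        blade_tris=np.concatenate(blade_list),
        blade_rank=np.concatenate(rank_list),
        petiole_tris=np.concatenate(petiole_list),
        target_area=target_area,
    )
    # widths were scaled per blade from exact unit areas, so the total lands on
    # target up to float round-off; renormalize to be safe
    scale = math.sqrt(target_area / model.blade_area)
    model.blade_tris[:, :, :2] *= scale  # in-plane only, keeps heights realistic
    return model


def place_canopy(
    layout: PlantingLayout,
    seed: int,
    target_area: float = MEAN_BLADE_AREA_M2,
    n_leaves: int = 7,
    base_height: float = 0.10,
):
    """Generate and place one plant per layout position.

    Returns ``(blade_tris, blade_plant, blade_rank, petiole_tris)`` in world
    coordinates (panel surface at ``z = base_height``).  Per-plant seeds
    derive deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(layout.n_plants)
    blades, plants, ranks, petioles = [], [], [], []
    for i, (x, y) in enumerate(layout.positions):
        plant = generate_plant(
            int(child_seeds[i] & 0x7FFFFFFF), target_area=target_area, n_leaves=n_leaves
        )
        offset = np.array([x, y, base_height])
        blades.append(plant.blade_tris + offset)
        petioles.append(plant.petiole_tris + offset)
        plants.append(np.full(len(plant.blade_tris), i, dtype=np.int32))
        ranks.append(plant.blade_rank)
    return (
        np.concatenate(blades),
        np.concatenate(plants),
        np.concatenate(ranks),
        np.concatenate(petioles),
    )


def generate_gas_exchange(
    truth: BilateralLRCParams,
    e_levels=DEFAULT_E_LEVELS,
    pad_levels=DEFAULT_PAD_LEVELS,
    replicates: int = 3,
    cv: float = 0.05,
    dark_sd: float = 0.1,
    seed: int = 0,
    das: int = 18,
    leaf_rank: int = 3,
) -> pd.DataFrame:
    """Gas-exchange records from a known bilateral truth.

    ``Pn_obs = Pn_true + eps`` with ``sd(eps) = cv * max(Pg_true, 0.5)`` at
    ``E > 0`` and ``sd = dark_sd`` at ``E = 0`` (instrument noise floor).
    """
    if cv < 0:
        raise DomainError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows_e, rows_p = [], []
    for e in e_levels:
        for p in pad_levels if e > 0 else (100.0,):
            for _ in range(replicates):
                rows_e.append(e)
                rows_p.append(p)
    e = np.array(rows_e)
    p_ad = np.array(rows_p)
    e_ad = e * p_ad / 100.0
    pn_true = bilateral_pn_arrays(e_ad, e - e_ad, truth)
    pg_true = pn_true - truth.rd
    sd = np.where(e > 0, cv * np.maximum(pg_true, 0.5), dark_sd)
    pn_obs = pn_true + rng.normal(0.0, 1.0, size=e.size) * sd
    return pd.DataFrame(
        {
            "E": e,
            "p_ad": p_ad,
            "pn": pn_obs,
            "das": das,
            "leaf_rank": leaf_rank,
        }
    )


def generate_etr(
    truth: BilateralLRCParams,
    calib_ad: ETRCalibration,
    calib_ab: ETRCalibration,
    e_levels=tuple(x for x in DEFAULT_E_LEVELS if x > 0),
    replicates: int = 3,
    cv: float = 0.0,
    seed: int = 0,
    das: int = 18,
    leaf_rank: int = 1,
) -> pd.DataFrame:
    """ETR light-response records per irradiated surface from a known truth.

    Gross rates along each single-surface curve are mapped to electron
    transport rates through the inverse calibration (monotone branch), then
    multiplicative noise is applied.  Raises if any gross rate lies beyond the
    calibration quadratic's vertex.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for surface, calib, phi, theta in (
        ("adaxial", calib_ad, truth.phi_ad, truth.theta_ad),
        ("abaxial", calib_ab, truth.phi_ab, truth.theta_ab),
    ):
        e = np.repeat(np.asarray(e_levels, dtype=float), replicates)
        pg = gross_rate(e, phi, truth.p_max, theta)
        j = calib.invert(pg)
        j_obs = np.maximum(j * (1.0 + cv * rng.normal(0.0, 1.0, size=j.size)), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "J": j_obs,
                    "surface": surface,
                    "E": e,
                    "das": das,
                    "leaf_rank": leaf_rank,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
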