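"""Cultivation-system scene: geometry, materials, lamps, plant placement.

The simulated system is a 1.25 x 1.25 m cultivation bed whose top surface (the
cultivation panel) sits 0.10 m above the floor.  Four vertical perfect-mirror
planes stand 0.0135 m outside the floor edges and span from the floor to the
ceiling, emulating an infinite array of neighbouring systems.  Linear lamps
(1.22 m x 0.03 m) run between plant rows: upward-facing lamps rest on the
panel, downward-facing lamps hang 0.30 m above it, directly above the upward
ones, with a reflective ceiling sheet just above the downward lamps.

Photometry: the downward lamp intensity follows I(alpha) = I0 / cos(alpha) on
a cone of half-angle pi/3 about the downward axis (uniform irradiance design);
the upward lamp is uniform over its emitting hemisphere.  alpha is the polar
angle from the emission axis with azimuthal uniformity, so the flux
normalizations are closed-form: I0 = ppf / (2*pi*ln 2) (downward) and
I = ppf / (2*pi) (upward).

Optics are three-band (400-500, 500-600, 600-700 nm, stored in that
wavelength order) reflectance/transmittance fractions per material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError, SceneError

__all__ = [
    "DEFAULT_BAND_WEIGHTS",
    "DEFAULT_MATERIALS",
    "MEAN_BLADE_AREA_M2",
    "ExperimentCondition",
    "LampSpec",
    "OpticalProperties",
    "PlantingLayout",
    "SceneSpec",
    "band_weights",
    "lamp_array",
    "lamp_intensity_norm",
    "planting_layout",
]

#: Mean one-sided leaf-blade area per plant at 18 days after sowing (m²).
MEAN_BLADE_AREA_M2 = 110.2e-4

#: Photon-flux fractions of a 5000 K white LED in the 400-500/500-600/600-700 nm
#: bands (blue pump plus phosphor hump; see docs/methods.md).
DEFAULT_BAND_WEIGHTS = (0.20, 0.40, 0.40)


@dataclass(frozen=True)
class OpticalProperties:
    """Three-band reflectance and transmittance fractions (wavelength order)."""

    reflectance: tuple[float, float, float]
    transmittance: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for r, t in zip(self.reflectance, self.transmittance):
            if not (0.0 <= r <= 1.0 and 0.0 <= t <= 1.0):
                raise DomainError("band reflectance/transmittance must lie in [0, 1]")
            if r + t > 1.0 + 1e-12:
                raise DomainError("reflectance + transmittance exceeds 1 in a band")


# Measured/picked optical properties of the scene items.  Values are fractions
# in wavelength band order (400-500, 500-600, 600-700 nm).
DEFAULT_MATERIALS: dict[str, OpticalProperties] = {
    "leaf": OpticalProperties((0.0190, 0.0565, 0.0331), (0.00637, 0.104, 0.0433)),
    "petiole": OpticalProperties((0.0729, 0.552, 0.341), (0.0141, 0.134, 0.0811)),
    "panel": OpticalProperties((0.904, 0.899, 0.895)),
    "container": OpticalProperties((0.005, 0.354, 0.734)),
    "floor": OpticalProperties((0.70, 0.70, 0.70)),
    "ceiling": OpticalProperties((0.914, 0.913, 0.909)),
}


@dataclass(frozen=True)
class ExperimentCondition:
    """One cell of the experiment grid."""

    lai: float
    phi_lamps: float  # total lamp photon flux, µmol s⁻¹
    p_dw: float  # percent of phi_lamps assigned to downward lamps

    def __post_init__(self) -> None:
        if not self.lai > 0:
            raise DomainError("lai must be > 0")
        if self.phi_lamps < 0:
            raise DomainError("phi_lamps must be >= 0")
        if not 0.0 <= self.p_dw <= 100.0:
            raise DomainError("p_dw must lie in [0, 100]")


@dataclass(frozen=True)
class PlantingLayout:
    """Near-square planting grid on the cultivation panel."""

    n_plants: int
    rows: int
    cols: int
    distance: float  # planting distance = floor side / rows, m
    positions: tuple[tuple[float, float], ...]  # (x, y) centres, panel frame


def planting_layout(
    lai: float,
    mean_leaf_area: float = MEAN_BLADE_AREA_M2,
    floor_side: float = 1.25,
) -> PlantingLayout:
    """Plant count and grid positions achieving a target leaf area index.

    ``n = round(lai * floor_area / mean_leaf_area)`` plants on a near-square
    grid; the planting distance (lamp spacing) is the floor side divided by
    the row count.
    """
    if lai <= 0 or mean_leaf_area <= 0:
        raise DomainError("lai and mean_leaf_area must be > 0")
    floor_area = floor_side * floor_side
    n = int(round(lai * floor_area / mean_leaf_area))
    if n < 1:
        raise SceneError(f"target LAI {lai} yields {n} plants")
    rows = max(int(round(math.sqrt(n))), 1)
    cols = int(math.ceil(n / rows))
    dy = floor_side / rows
    dx = floor_side / cols
    positions = []
    for i in range(rows):
        for j in range(cols):
            if len(positions) >= n:
                break
            x = -floor_side / 2.0 + (j + 0.5) * dx
            y = -floor_side / 2.0 + (i + 0.5) * dy
            positions.append((x, y))
    return PlantingLayout(
        n_plants=n,
        rows=rows,
        cols=cols,
        distance=dy,
        positions=tuple(positions),
    )


@dataclass(frozen=True)
class LampSpec:
    """A linear lamp with an analytic photometric curve.

    ``kind`` is ``"downward"`` (cosine-secant cone of half-angle pi/3 about
    the -z axis) or ``"upward"`` (uniform intensity over the +z hemisphere).
    """

    kind: str
    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)  # long-axis direction
    length: float = 1.22
    width: float = 0.03
    ppf: float = 0.0
    band_weights: tuple[float, float, float] = DEFAULT_BAND_WEIGHTS

    def __post_init__(self) -> None:
        if self.kind not in ("downward", "upward"):
            raise DomainError(f"unknown lamp kind {self.kind!r}")
        if self.ppf < 0:
            raise DomainError("ppf must be >= 0")
        if abs(sum(self.band_weights) - 1.0) > 1e-9:
            raise DomainError("band_weights must sum to 1")


def lamp_intensity_norm(spec: LampSpec) -> float:
    """On-axis photon intensity (µmol s⁻¹ sr⁻¹) normalizing the flux integral.

    Downward: ppf = 2*pi*I0 * ∫₀^{pi/3} tan(a) da = 2*pi*ln(2)*I0.
    Upward:   ppf = 2*pi*I (uniform hemisphere).
    """
    if spec.ppf <= 0:
        raise DomainError("lamp intensity undefined for non-positive ppf")
    if spec.kind == "downward":
        return spec.ppf / (2.0 * math.pi * math.log(2.0))
    return spec.ppf / (2.0 * math.pi)


def lamp_array(
    condition: ExperimentCondition,
    layout: PlantingLayout,
    floor_side: float = 1.25,
    panel_height: float = 0.10,
    lamp_height: float = 0.30,
    band_weights: tuple[float, float, float] = DEFAULT_BAND_WEIGHTS,
) -> list[LampSpec]:
    """Place the lamp arrays for one experiment condition.

    One upward lamp lies in each of the ``rows + 1`` aisles (between adjacent
    plant rows and flanking the outer rows, clipped to the floor edge), on the
    panel; downward lamps sit directly above at ``panel + lamp_height``.  The
    per-lamp photon flux splits ``condition.phi_lamps`` by ``p_dw``; lamps
    with zero flux are omitted so the total placed flux is exact.
    """
    n_aisles = layout.rows + 1
    dy = floor_side / layout.rows
    ys = [-floor_side / 2.0 + i * dy for i in range(n_aisles)]
    f_dw = condition.p_dw / 100.0
    phi_dw = condition.phi_lamps * f_dw
    phi_uw = condition.phi_lamps - phi_dw
    lamps: list[LampSpec] = []
    if phi_uw > 0:
        per = phi_uw / n_aisles
        for y in ys:
            lamps.append(
                LampSpec(
                    kind="upward",
                    center=(0.0, y, panel_height),
                    ppf=per,
                    band_weights=band_weights,
                )
            )
    if phi_dw > 0:
        per = phi_dw / n_aisles
        for y in ys:
            lamps.append(
                LampSpec(
                    kind="downward",
                    center=(0.0, y, panel_height + lamp_height),
                    ppf=per,
                    band_weights=band_weights,
                )
            )
    return lamps


def band_weights(wavelength_nm, photon_flux) -> tuple[float, float, float]:
    """Integrate a photon-flux spectrum into the three band fractions.

    Trapezoid integration over 400-500, 500-600 and 600-700 nm, normalized to
    sum to one.  Monochromatic lines (single samples inside one band) are
    handled by summation.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    fx = np.asarray(photon_flux, dtype=float)
    if np.any(fx < 0):
        raise DomainError("photon flux must be non-negative")
    edges = (400.0, 500.0, 600.0, 700.0)
    parts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (wl >= lo) & (wl <= hi)
        if mask.sum() >= 2:
            parts.append(float(np.trapezoid(fx[mask], wl[mask])))
        elif mask.sum() == 1:
            parts.append(float(fx[mask].sum()))
        else:
            parts.append(0.0)
    total = sum(parts)
    if total <= 0:
        raise DomainError("zero photon flux in 400-700 nm")
    return tuple(p / total for p in parts)


@dataclass
class SceneSpec:
    """Complete geometric and optical description of one simulated condition.

    ``plants`` is a list of placed plant meshes (see :mod:`canopylight.canopy`);
    ``blade_*`` / ``petiole_*`` arrays are the concatenated world-space
    triangle soups with per-triangle plant id and leaf rank for blades.
    """

    condition: ExperimentCondition
    layout: PlantingLayout
    lamps: list[LampSpec]
    floor_side: float = 1.25
    mirror_offset: float = 0.0135
    panel_height: float = 0.10
    lamp_height: float = 0.30
    ceiling_clearance: float = 0.05  # ceiling sits just above the downward lamps
    materials: dict[str, OpticalProperties] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS)
    )
    # blade triangles: (n, 3, 3) vertices, plus per-triangle plant id and rank
    blade_tris: np.ndarray | None = None
    blade_plant: np.ndarray | None = None
    blade_rank: np.ndarray | None = None
    petiole_tris: np.ndarray | None = None

    @property
    def mirror_half(self) -> float:
        return self.floor_side / 2.0 + self.mirror_offset

    @property
    def ceiling_height(self) -> float:
        return self.panel_height + self.lamp_height + self.ceiling_clearance


def build_scene(
    condition: ExperimentCondition,
    seed: int = 0,
    mean_leaf_area: float = MEAN_BLADE_AREA_M2,
    n_leaves: int = 7,
    band_weights: tuple[float, float, float] = DEFAULT_BAND_WEIGHTS,
    materials: dict[str, OpticalProperties] | None = None,
    with_plants: bool = True,
) -> SceneSpec:
    """Assemble the full scene for one experiment condition.

    Generates a seeded synthetic canopy at the condition's LAI (unless
    ``with_plants`` is false), places it on the planting grid, and lays out
    the lamp arrays.
    """
    from .canopy import place_canopy  # local import to avoid a cycle

    layout = planting_layout(condition.lai, mean_leaf_area)
    lamps = lamp_array(condition, layout, band_weights=band_weights)
    spec = SceneSpec(condition=condition, layout=layout, lamps=lamps)
    if materials:
        spec.materials.update(materials)
    if with_plants:
        blade_tris, blade_plant, blade_rank, petiole_tris = place_canopy(
            layout,
            seed=seed,
            target_area=mean_leaf_area,
            n_leaves=n_leaves,
            base_height=spec.panel_height,
        )
        spec.blade_tris = blade_tris
        spec.blade_plant = blade_plant
        spec.blade_rank = blade_rank
        spec.petiole_tris = petiole_tris
    else:
        spec.blade_tris = np.zeros((0, 3, 3))
        spec.blade_plant = np.zeros(0, dtype=np.int32)
        spec.blade_rank = np.zeros(0, dtype=np.int32)
        spec.petiole_tris = np.zeros((0, 3, 3))
    return spec


def scene_with_materials(scene: SceneSpec, **overrides: OpticalProperties) -> SceneSpec:
    """Return a copy of ``scene`` with some materials replaced (test hook)."""
    mats = dict(scene.materials)
    mats.update(overrides)
    return replace(scene, materials=mats)
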