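"""Three-band Monte Carlo photon transport through the cultivation scene.

Photon packets are emitted from the lamp faces (uniform over each emitting
rectangle, direction drawn from the lamp's photometric density), traced
through a closed box bounded by four perfect-specular mirror planes, a floor
and a reflective ceiling, and scattered by Lambertian surfaces whose per-band
reflectance/transmittance follow the material table.  Every crossing of a
leaf-blade triangle tallies *incident* flux on the struck side (the geometric
normal marks the adaxial surface); per-triangle PPFD is the tallied flux
divided by the one-sided triangle area.  Paths terminate by absorption or by
Russian roulette (survival 0.8, weight-compensated) after ``max_bounces``
interactions.

Acceleration: a uniform voxel grid with 3D-DDA traversal; the mirror planes
are handled analytically so the box can never leak.  Identical
``(scene, n_photons, seed)`` inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .canopy import triangle_areas
from .exceptions import SceneError, TransportError
from .scene import LampSpec, SceneSpec, lamp_intensity_norm

__all__ = ["IrradianceMap", "trace", "direct_illumination_oracle", "compile_scene"]

# material slot order inside the kernel arrays
_MATERIAL_ORDER = ("leaf", "petiole", "panel", "container", "floor", "ceiling")
_EPS_T = 1e-9
_OFFSET = 1e-7


@dataclass
class IrradianceMap:
    """Per-triangle two-sided PPFD estimates plus photon-budget accounting.

    ``triangles`` columns: ``tri``, ``plant``, ``rank``, ``area`` (m²), ``z``
    (centroid height, m), ``e_ad``/``e_ab`` (µmol m⁻² s⁻¹) and their Monte
    Carlo standard errors.  ``budget`` maps band index to emitted/absorbed/
    escaped/roulette-killed photon flux (µmol s⁻¹).
    """

    triangles: pd.DataFrame
    budget: dict

    @property
    def total_ppfd(self) -> np.ndarray:
        return (self.triangles["e_ad"] + self.triangles["e_ab"]).to_numpy()


def _box_rect(z: float, half: float):
    """Two triangles tiling the horizontal square |x|,|y| <= half at height z."""
    a, b = -half, half
    v = np.array(
        [
            [[a, a, z], [b, a, z], [b, b, z]],
            [[a, a, z], [b, b, z], [a, b, z]],
        ]
    )
    return v


def _panel_and_container(scene: SceneSpec):
    h = scene.floor_side / 2.0
    z = scene.panel_height
    panel = _box_rect(z, h)
    sides = []
    for sgn in (-1.0, 1.0):
        x = sgn * h
        sides.append([[x, -h, 0.0], [x, h, 0.0], [x, h, z]])
        sides.append([[x, -h, 0.0], [x, h, z], [x, -h, z]])
        y = sgn * h
        sides.append([[-h, y, 0.0], [h, y, 0.0], [h, y, z]])
        sides.append([[-h, y, 0.0], [h, y, z], [-h, y, z]])
    return panel, np.array(sides)


def compile_scene(scene: SceneSpec):
    """Flatten a :class:`SceneSpec` into kernel-ready triangle/material arrays."""
    if scene.blade_tris is None:
        raise SceneError("scene has no plant arrays; call build_scene first")
    pad = 0.02  # structural planes overhang the mirror box so edges cannot leak
    half_pad = scene.mirror_half + pad
    panel, container = _panel_and_container(scene)
    floor = _box_rect(0.0, half_pad)
    ceiling = _box_rect(scene.ceiling_height, half_pad)

    groups = [
        (scene.blade_tris, 0, True),
        (scene.petiole_tris, 1, False),
        (panel, 2, False),
        (container, 3, False),
        (floor, 4, False),
        (ceiling, 5, False),
    ]
    tris, mats, leaf_ids = [], [], []
    next_leaf = 0
    for arr, mat, is_leaf in groups:
        if len(arr) == 0:
            continue
        tris.append(np.asarray(arr, dtype=np.float64))
        mats.append(np.full(len(arr), mat, dtype=np.int32))
        if is_leaf:
            leaf_ids.append(np.arange(next_leaf, next_leaf + len(arr), dtype=np.int32))
            next_leaf += len(arr)
        else:
            leaf_ids.append(np.full(len(arr), -1, dtype=np.int32))
    tri = np.concatenate(tris)
    mat_id = np.concatenate(mats)
    leaf_id = np.concatenate(leaf_ids)

    v0 = np.ascontiguousarray(tri[:, 0])
    e1 = np.ascontiguousarray(tri[:, 1] - tri[:, 0])
    e2 = np.ascontiguousarray(tri[:, 2] - tri[:, 0])
    nrm = np.cross(e1, e2)
    norm = np.linalg.norm(nrm, axis=1)
    if np.any(norm <= 0):
        raise SceneError("degenerate triangle in scene")
    nrm = np.ascontiguousarray(nrm / norm[:, None])

    matR = np.zeros((len(_MATERIAL_ORDER), 3))
    matT = np.zeros((len(_MATERIAL_ORDER), 3))
    for i, name in enumerate(_MATERIAL_ORDER):
        props = scene.materials[name]
        matR[i] = props.reflectance
        matT[i] = props.transmittance

    gmin = np.array([-half_pad, -half_pad, -1e-6])
    gmax = np.array([half_pad, half_pad, scene.ceiling_height + 1e-6])
    n_tris = len(tri)
    nx = int(min(64, max(8, np.sqrt(n_tris / 6.0) + 1)))
    dims = np.array([nx, nx, 16], dtype=np.int64)
    cell = (gmax - gmin) / dims
    cell_start, cell_tris = _build_grid(tri, gmin, cell, dims)

    return {
        "v0": v0,
        "e1": e1,
        "e2": e2,
        "nrm": nrm,
        "mat_id": mat_id,
        "leaf_id": leaf_id,
        "matR": matR,
        "matT": matT,
        "gmin": gmin,
        "cell": cell,
        "dims": dims,
        "cell_start": cell_start,
        "cell_tris": cell_tris,
        "box": np.array(
            [
                -scene.mirror_half,
                scene.mirror_half,
                -scene.mirror_half,
                scene.mirror_half,
            ]
        ),
        "n_leaf": next_leaf,
    }


@njit(cache=True)
def _build_grid_counts(tri, gmin, cell, dims):
    n = tri.shape[0]
    ncell = dims[0] * dims[1] * dims[2]
    counts = np.zeros(ncell, dtype=np.int64)
    for t in range(n):
        lo = np.empty(3, dtype=np.int64)
        hi = np.empty(3, dtype=np.int64)
        for k in range(3):
            mn = min(tri[t, 0, k], min(tri[t, 1, k], tri[t, 2, k]))
            mx = max(tri[t, 0, k], max(tri[t, 1, k], tri[t, 2, k]))
            lo[k] = max(0, min(dims[k] - 1, int((mn - gmin[k]) / cell[k])))
            hi[k] = max(0, min(dims[k] - 1, int((mx - gmin[k]) / cell[k])))
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    counts[(ix * dims[1] + iy) * dims[2] + iz] += 1
    return counts


@njit(cache=True)
def _build_grid_fill(tri, gmin, cell, dims, start):
    n = tri.shape[0]
    cursor = start[:-1].copy()
    items = np.zeros(start[-1], dtype=np.int32)
    for t in range(n):
        lo = np.empty(3, dtype=np.int64)
        hi = np.empty(3, dtype=np.int64)
        for k in range(3):
            mn = min(tri[t, 0, k], min(tri[t, 1, k], tri[t, 2, k]))
            mx = max(tri[t, 0, k], max(tri[t, 1, k], tri[t, 2, k]))
            lo[k] = max(0, min(dims[k] - 1, int((mn - gmin[k]) / cell[k])))
            hi[k] = max(0, min(dims[k] - 1, int((mx - gmin[k]) / cell[k])))
        for ix in range(lo[0], hi[0] + 1):
            for iy in range(lo[1], hi[1] + 1):
                for iz in range(lo[2], hi[2] + 1):
                    c = (ix * dims[1] + iy) * dims[2] + iz
                    items[cursor[c]] = t
                    cursor[c] += 1
    return items


def _build_grid(tri, gmin, cell, dims):
    counts = _build_grid_counts(tri, gmin, cell, dims)
    start = np.zeros(counts.size + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    items = _build_grid_fill(tri, gmin, cell, dims, start)
    return start, items


@njit(cache=True, inline="always")
def _hit_triangle(px, py, pz, dx, dy, dz, v0, e1, e2, t_i):
    """Möller–Trumbore; returns hit distance or -1."""
    ax, ay, az = e1[t_i, 0], e1[t_i, 1], e1[t_i, 2]
    bx, by, bz = e2[t_i, 0], e2[t_i, 1], e2[t_i, 2]
    hx = dy * bz - dz * by
    hy = dz * bx - dx * bz
    hz = dx * by - dy * bx
    det = ax * hx + ay * hy + az * hz
    if -1e-14 < det < 1e-14:
        return -1.0
    inv = 1.0 / det
    sx = px - v0[t_i, 0]
    sy = py - v0[t_i, 1]
    sz = pz - v0[t_i, 2]
    u = (sx * hx + sy * hy + sz * hz) * inv
    if u < 0.0 or u > 1.0:
        return -1.0
    qx = sy * az - sz * ay
    qy = sz * ax - sx * az
    qz = sx * ay - sy * ax
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < 0.0 or u + v > 1.0:
        return -1.0
    t = (bx * qx + by * qy + bz * qz) * inv
    if t <= _EPS_T:
        return -1.0
    return t


@njit(cache=True)
def _grid_hit(px, py, pz, dx, dy, dz, t_max, v0, e1, e2, gmin, cell, dims, cstart, ctris):
    """Nearest triangle hit along the ray within t <= t_max, via 3D-DDA."""
    ix = int((px - gmin[0]) / cell[0])
    iy = int((py - gmin[1]) / cell[1])
    iz = int((pz - gmin[2]) / cell[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= dims[0]:
        ix = dims[0] - 1
    if iy >= dims[1]:
        iy = dims[1] - 1
    if iz >= dims[2]:
        iz = dims[2] - 1

    big = 1e30
    if dx > 0:
        sx, tnx = 1, ((gmin[0] + (ix + 1) * cell[0]) - px) / dx
        tdx = cell[0] / dx
    elif dx < 0:
        sx, tnx = -1, ((gmin[0] + ix * cell[0]) - px) / dx
        tdx = -cell[0] / dx
    else:
        sx, tnx, tdx = 0, big, big
    if dy > 0:
        sy, tny = 1, ((gmin[1] + (iy + 1) * cell[1]) - py) / dy
        tdy = cell[1] / dy
    elif dy < 0:
        sy, tny = -1, ((gmin[1] + iy * cell[1]) - py) / dy
        tdy = -cell[1] / dy
    else:
        sy, tny, tdy = 0, big, big
    if dz > 0:
        sz, tnz = 1, ((gmin[2] + (iz + 1) * cell[2]) - pz) / dz
        tdz = cell[2] / dz
    elif dz < 0:
        sz, tnz = -1, ((gmin[2] + iz * cell[2]) - pz) / dz
        tdz = -cell[2] / dz
    else:
        sz, tnz, tdz = 0, big, big

    best_t = big
    best_i = -1
    while True:
        t_exit = min(tnx, min(tny, tnz))
        c = (ix * dims[1] + iy) * dims[2] + iz
        for k in range(cstart[c], cstart[c + 1]):
            t_i = ctris[k]
            t = _hit_triangle(px, py, pz, dx, dy, dz, v0, e1, e2, t_i)
            if t > 0.0 and t < best_t:
                best_t = t
                best_i = t_i
        if best_i >= 0 and best_t <= t_exit + 1e-12:
            if best_t <= t_max:
                return best_t, best_i
            return big, -1
        if t_exit > t_max:
            if best_i >= 0 and best_t <= t_max:
                return best_t, best_i
            return big, -1
        if tnx <= tny and tnx <= tnz:
            ix += sx
            tnx += tdx
            if ix < 0 or ix >= dims[0]:
                break
        elif tny <= tnz:
            iy += sy
            tny += tdy
            if iy < 0 or iy >= dims[1]:
                break
        else:
            iz += sz
            tnz += tdz
            if iz < 0 or iz >= dims[2]:
                break
    if best_i >= 0 and best_t <= t_max:
        return best_t, best_i
    return big, -1


@njit(cache=True, inline="always")
def _cosine_dir(nx, ny, nz):
    """Cosine-weighted direction about the unit normal (nx, ny, nz)."""
    u1 = np.random.random()
    u2 = np.random.random()
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    z = np.sqrt(max(0.0, 1.0 - u1))
    # orthonormal basis around the normal
    if abs(nx) > 0.9:
        tx, ty, tz = 0.0, 1.0, 0.0
    else:
        tx, ty, tz = 1.0, 0.0, 0.0
    bx = ny * tz - nz * ty
    by = nz * tx - nx * tz
    bz = nx * ty - ny * tx
    bl = np.sqrt(bx * bx + by * by + bz * bz)
    bx, by, bz = bx / bl, by / bl, bz / bl
    cx = ny * bz - nz * by
    cy = nz * bx - nx * bz
    cz = nx * by - ny * bx
    return (
        x * bx + y * cx + z * nx,
        x * by + y * cy + z * ny,
        x * bz + y * cz + z * nz,
    )


@njit(cache=True)
def _trace_band(
    seed,
    n_photons,
    w0,
    lamp_c,
    lamp_u,
    lamp_v,
    lamp_kind,
    lamp_cdf,
    v0,
    e1,
    e2,
    nrm,
    mat_id,
    leaf_id,
    Rb,
    Tb,
    gmin,
    cell,
    dims,
    cstart,
    ctris,
    box,
    max_bounces,
    rr_survival,
    tal_ad,
    tal_ab,
    tal_ad2,
    tal_ab2,
    absorbed,
    counters,
):
    np.random.seed(seed)
    xlo, xhi, ylo, yhi = box[0], box[1], box[2], box[3]
    n_lamps = lamp_cdf.shape[0]
    for _ in range(n_photons):
        u = np.random.random()
        li = 0
        while li < n_lamps - 1 and lamp_cdf[li] < u:
            li += 1
        r1 = 2.0 * np.random.random() - 1.0
        r2 = 2.0 * np.random.random() - 1.0
        px = lamp_c[li, 0] + r1 * lamp_u[li, 0] + r2 * lamp_v[li, 0]
        py = lamp_c[li, 1] + r1 * lamp_u[li, 1] + r2 * lamp_v[li, 1]
        pz = lamp_c[li, 2] + r1 * lamp_u[li, 2] + r2 * lamp_v[li, 2]
        phi = 2.0 * np.pi * np.random.random()
        if lamp_kind[li] == 0:  # downward cone, pdf(alpha) ∝ tan(alpha)
            cosa = 2.0 ** (-np.random.random())  # inverse CDF of tan on [0, pi/3]
            sina = np.sqrt(max(0.0, 1.0 - cosa * cosa))
            dx = sina * np.cos(phi)
            dy = sina * np.sin(phi)
            dz = -cosa
            pz -= _OFFSET
        else:  # uniform-intensity hemisphere
            cosa = np.random.random()
            sina = np.sqrt(max(0.0, 1.0 - cosa * cosa))
            dx = sina * np.cos(phi)
            dy = sina * np.sin(phi)
            dz = cosa
            pz += _OFFSET
        w = w0
        depth = 0
        alive = True
        while alive:
            # analytic distance to the nearest mirror plane
            tm = 1e30
            axis = -1
            if dx > 0.0:
                t = (xhi - px) / dx
                if _EPS_T < t < tm:
                    tm = t
                    axis = 0
            elif dx < 0.0:
                t = (xlo - px) / dx
                if _EPS_T < t < tm:
                    tm = t
                    axis = 0
            if dy > 0.0:
                t = (yhi - py) / dy
                if _EPS_T < t < tm:
                    tm = t
                    axis = 1
            elif dy < 0.0:
                t = (ylo - py) / dy
                if _EPS_T < t < tm:
                    tm = t
                    axis = 1
            t_hit, t_i = _grid_hit(
                px, py, pz, dx, dy, dz, tm, v0, e1, e2, gmin, cell, dims, cstart, ctris
            )
            if t_i < 0:
                if axis >= 0:
                    px += tm * dx
                    py += tm * dy
                    pz += tm * dz
                    if axis == 0:
                        dx = -dx
                        px += _OFFSET * dx
                    else:
                        dy = -dy
                        py += _OFFSET * dy
                    depth += 1
                else:
                    counters[0] += 1.0
                    counters[1] += w
                    alive = False
            else:
                px += t_hit * dx
                py += t_hit * dy
                pz += t_hit * dz
                mi = mat_id[t_i]
                nxv, nyv, nzv = nrm[t_i, 0], nrm[t_i, 1], nrm[t_i, 2]
                cosi = dx * nxv + dy * nyv + dz * nzv
                front = cosi < 0.0
                lid = leaf_id[t_i]
                if lid >= 0:
                    if front:
                        tal_ad[lid] += w
                        tal_ad2[lid] += w * w
                    else:
                        tal_ab[lid] += w
                        tal_ab2[lid] += w * w
                uu = np.random.random()
                if uu < Rb[mi]:  # Lambertian reflection into the incident side
                    if front:
                        hx, hy, hz = nxv, nyv, nzv
                    else:
                        hx, hy, hz = -nxv, -nyv, -nzv
                    dx, dy, dz = _cosine_dir(hx, hy, hz)
                    px += _OFFSET * hx
                    py += _OFFSET * hy
                    pz += _OFFSET * hz
                    depth += 1
                elif uu < Rb[mi] + Tb[mi]:  # Lambertian transmission
                    if front:
                        hx, hy, hz = -nxv, -nyv, -nzv
                    else:
                        hx, hy, hz = nxv, nyv, nzv
                    dx, dy, dz = _cosine_dir(hx, hy, hz)
                    px += _OFFSET * hx
                    py += _OFFSET * hy
                    pz += _OFFSET * hz
                    depth += 1
                else:
                    absorbed[mi] += w
                    alive = False
            if alive and depth > max_bounces:
                if np.random.random() < rr_survival:
                    w /= rr_survival
                    depth = 0
                else:
                    counters[2] += w
                    alive = False


def _lamp_arrays(lamps: list[LampSpec], band: int):
    n = len(lamps)
    c = np.zeros((n, 3))
    u = np.zeros((n, 3))
    v = np.zeros((n, 3))
    kind = np.zeros(n, dtype=np.int32)
    flux = np.zeros(n)
    up = np.array([0.0, 0.0, 1.0])
    for i, lamp in enumerate(lamps):
        c[i] = lamp.center
        axis = np.asarray(lamp.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        wvec = np.cross(up, axis)
        if np.linalg.norm(wvec) < 1e-12:
            raise SceneError("lamp long axis must not be vertical")
        wvec /= np.linalg.norm(wvec)
        u[i] = axis * (lamp.length / 2.0)
        v[i] = wvec * (lamp.width / 2.0)
        kind[i] = 0 if lamp.kind == "downward" else 1
        flux[i] = lamp.ppf * lamp.band_weights[band]
    total = flux.sum()
    cdf = np.cumsum(flux) / total if total > 0 else np.ones(n)
    return c, u, v, kind, cdf, total


def trace(
    scene: SceneSpec,
    n_photons: int,
    seed: int,
    max_bounces: int = 20,
    rr_survival: float = 0.8,
) -> IrradianceMap:
    """Trace ``n_photons`` packets per waveband and estimate leaf irradiances.

    Returns an :class:`IrradianceMap`; raises :class:`TransportError` if any
    photon escapes the (closed) scene, which indicates broken geometry.
    """
    if n_photons < 1:
        raise TransportError("n_photons must be >= 1")
    if not scene.lamps:
        raise SceneError("scene has no lamps")
    geo = compile_scene(scene)
    n_leaf = geo["n_leaf"]
    tal_ad = np.zeros(n_leaf)
    tal_ab = np.zeros(n_leaf)
    tal_ad2 = np.zeros(n_leaf)
    tal_ab2 = np.zeros(n_leaf)
    budget = {}
    band_seeds = np.random.SeedSequence(seed).generate_state(3)
    escaped_total = 0.0
    for band in range(3):
        c, u, v, kind, cdf, flux = _lamp_arrays(scene.lamps, band)
        if flux <= 0:
            budget[band] = {"emitted": 0.0, "absorbed": {}, "escaped": 0.0, "roulette": 0.0}
            continue
        w0 = flux / n_photons
        absorbed = np.zeros(len(_MATERIAL_ORDER))
        counters = np.zeros(3)
        _trace_band(
            np.int64(band_seeds[band]),
            n_photons,
            w0,
            c,
            u,
            v,
            kind,
            cdf,
            geo["v0"],
            geo["e1"],
            geo["e2"],
            geo["nrm"],
            geo["mat_id"],
            geo["leaf_id"],
            np.ascontiguousarray(geo["matR"][:, band]),
            np.ascontiguousarray(geo["matT"][:, band]),
            geo["gmin"],
            geo["cell"],
            geo["dims"],
            geo["cell_start"],
            geo["cell_tris"],
            geo["box"],
            max_bounces,
            rr_survival,
            tal_ad,
            tal_ab,
            tal_ad2,
            tal_ab2,
            absorbed,
            counters,
        )
        escaped_total += counters[0]
        budget[band] = {
            "emitted": flux,
            "absorbed": {
                name: float(absorbed[i]) for i, name in enumerate(_MATERIAL_ORDER)
            },
            "escaped": float(counters[1]),
            "roulette": float(counters[2]),
        }
    if escaped_total > 0:
        raise TransportError(
            f"{int(escaped_total)} photon(s) escaped the scene; geometry is not closed"
        )

    if n_leaf:
        areas = triangle_areas(scene.blade_tris)
        cz = scene.blade_tris[:, :, 2].mean(axis=1)
        df = pd.DataFrame(
            {
                "tri": np.arange(n_leaf),
                "plant": scene.blade_plant,
                "rank": scene.blade_rank,
                "area": areas,
                "z": cz,
                "e_ad": tal_ad / areas,
                "e_ab": tal_ab / areas,
                "se_ad": np.sqrt(tal_ad2) / areas,
                "se_ab": np.sqrt(tal_ab2) / areas,
            }
        )
    else:
        df = pd.DataFrame(
            columns=["tri", "plant", "rank", "area", "z", "e_ad", "e_ab", "se_ad", "se_ab"]
        )
    return IrradianceMap(triangles=df, budget=budget)


def direct_illumination_oracle(
    point,
    normal,
    lamps: list[LampSpec],
    n_sub: int = 200,
) -> float:
    """Deterministic direct-only PPFD at a point (validation oracle).

    Numerically integrates each lamp's photometric intensity over its emitting
    rectangle: every surface patch acts as a point emitter with the lamp's
    angular pattern, so the irradiance contribution is
    ``I(alpha) * (dA/A) * cos(theta_recv) / d**2``.  Valid only when no
    occluder lies between the point and the lamps (caller's responsibility).
    """
    p = np.asarray(point, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    up = np.array([0.0, 0.0, 1.0])
    total = 0.0
    for lamp in lamps:
        if lamp.ppf <= 0:
            continue
        i_norm = lamp_intensity_norm(lamp)
        axis = np.asarray(lamp.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        wvec = np.cross(up, axis)
        wvec /= np.linalg.norm(wvec)
        m1 = n_sub
        m2 = max(3, int(np.ceil(n_sub * lamp.width / lamp.length)))
        s1 = (np.arange(m1) + 0.5) / m1 - 0.5
        s2 = (np.arange(m2) + 0.5) / m2 - 0.5
        frac = 1.0 / (m1 * m2)
        centers = (
            np.asarray(lamp.center)[None, None, :]
            + s1[:, None, None] * lamp.length * axis[None, None, :]
            + s2[None, :, None] * lamp.width * wvec[None, None, :]
        ).reshape(-1, 3)
        d = p[None, :] - centers
        dist = np.linalg.norm(d, axis=1)
        dhat = d / dist[:, None]
        if lamp.kind == "downward":
            cos_alpha = -dhat[:, 2]
            ok = cos_alpha >= 0.5  # alpha <= pi/3
            intens = np.where(ok, i_norm / np.maximum(cos_alpha, 1e-12), 0.0)
        else:
            cos_alpha = dhat[:, 2]
            intens = np.where(cos_alpha > 0.0, i_norm, 0.0)
        # receiver faces the lamp when the incoming direction opposes its normal
        cos_recv = np.maximum(-dhat @ nrm, 0.0)
        total += float(np.sum(intens * frac * cos_recv / dist**2))
    return total
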