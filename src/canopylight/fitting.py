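"""Estimation of the bilateral light-response model from measured data.

The measurement design provides net photosynthesis (gas-exchange) records on a
grid of total PPFD ``E`` and adaxial proportion ``p_ad``, plus electron
transport rate (ETR) records for leaf ranks whose gas exchange cannot be
measured directly.  Fitting proceeds in stages:

1. ``fit_rd`` — dark respiration as the mean of Pn at ``E = 0``.
2. ``fit_lrc_group`` — per-``p_ad`` non-rectangular hyperbolas with one shared
   ``P_max`` for a leaf class, by iteratively reweighted least squares (IRLS)
   with weights ``1 / Pg_model**2`` (heteroscedastic errors whose spread
   scales with the gross rate).
3. ``standardize`` / ``fit_shape_params`` — z-score the per-``p_ad`` parameter
   profiles across leaf classes and fit the two shape functions.
4. ``fit_bilateral`` — the five bilateral parameters (two phi anchors, two
   theta anchors, one shared ``P_max``) jointly, interpolating intermediate
   ``p_ad`` through the affine-rescaled shape functions.
5. ``fit_etr_calibration`` / ``lrc_from_etr`` — a through-origin quadratic
   ``Pg = k1*J + k2*J**2`` per irradiated surface, used to convert ETR
   light-response records into pseudo gas-exchange records and fit the
   bilateral model for unmeasured leaf ranks.

``E = 0`` records never enter the weighted objectives (they determine ``Rd``
separately); weights use ``1 / max(Pg, 0.5)**2`` to avoid the singularity at
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    DomainError,
    FitError,
    MissingDataError,
    UnidentifiableError,
)
from .leaf import BilateralLRCParams, ShapeParams, shape_phi, shape_theta

__all__ = [
    "ETRCalibration",
    "GroupFitResult",
    "BilateralFitResult",
    "ShapeFitResult",
    "fit_rd",
    "fit_lrc_group",
    "standardize",
    "fit_shape_params",
    "fit_bilateral",
    "fit_etr_calibration",
    "lrc_from_etr",
    "etr_to_pseudo_gas_exchange",
]

WEIGHT_FLOOR = 0.5  # µmol m⁻² s⁻¹; Pg floor inside the 1/Pg² weights
IRLS_TOL = 1e-6
IRLS_MAX_ITER = 50


def fit_rd(records: pd.DataFrame) -> float:
    """Dark respiration: arithmetic mean of observed Pn at ``E = 0``."""
    dark = records.loc[records["E"] == 0.0, "pn"]
    if len(dark) == 0:
        raise MissingDataError("no records at E = 0; cannot estimate Rd")
    return float(dark.mean())


def standardize(values) -> np.ndarray:
    """z-scores ``(x - mean) / sd`` using the sample (ddof=1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DomainError("standardize requires >= 2 distinct values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DomainError("zero variance; z-scores undefined")
    return (x - x.mean()) / sd


def _irls(residual_fn, model_fn, x0, bounds):
    """IRLS driver: unweighted pilot fit, then refits with weights
    ``1 / max(Pg_model, floor)**2`` refreshed from each pass, iterated to a
    fixed point (relative parameter change below :data:`IRLS_TOL`).

    ``residual_fn(x, sqrt_w)`` returns weighted residuals; ``model_fn(x)``
    returns the modelled Pg used to refresh the weights.  Returns
    ``(x, converged, n_iter, objective_path)``; the weighted objective path is
    recorded so regressions in the reweighting are visible in diagnostics.
    """
    sqrt_w = np.ones_like(model_fn(x0))
    x = np.asarray(x0, dtype=float)
    path = []
    converged = False
    n_iter = 0
    for n_iter in range(1, IRLS_MAX_ITER + 1):
        sol = least_squares(residual_fn, x, bounds=bounds, args=(sqrt_w,), method="trf")
        if not sol.success:
            raise FitError(f"inner least-squares failed: {sol.message}")
        path.append(float(2.0 * sol.cost))
        step = np.max(np.abs(sol.x - x) / np.maximum(np.abs(x), 1.0))
        x = sol.x
        pg = np.maximum(model_fn(x), WEIGHT_FLOOR)
        sqrt_w = 1.0 / pg
        if n_iter > 1 and step < IRLS_TOL:
            converged = True
            break
    return x, converged, n_iter, path


def _positive_records(records: pd.DataFrame, rd: float):
    sub = records.loc[records["E"] > 0.0]
    if len(sub) == 0:
        raise MissingDataError("no records with E > 0")
    e = sub["E"].to_numpy(dtype=float)
    pg_obs = sub["pn"].to_numpy(dtype=float) - rd
    p_ad = sub["p_ad"].to_numpy(dtype=float)
    return e, pg_obs, p_ad


@dataclass
class GroupFitResult:
    """Per-``p_ad`` hyperbola parameters with one shared maximum for a leaf class."""

    p_max: float
    phi: dict[float, float]
    theta: dict[float, float]
    rd: float
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)


def fit_lrc_group(records: pd.DataFrame, rd: float) -> GroupFitResult:
    """Fit phi and theta per ``p_ad`` level plus one shared ``P_max``.

    ``records`` holds one leaf class (one day-after-sowing × leaf-rank cell)
    with columns ``E``, ``p_ad``, ``pn``.  Raises :class:`FitError` when the
    data cannot support the fit (e.g. all-zero rates); flags non-convergence
    in the result otherwise.
    """
    e, pg_obs, p_ad = _positive_records(records, rd)
    levels = np.unique(p_ad)
    for lv in levels:
        if np.unique(e[p_ad == lv]).size < 3:
            raise UnidentifiableError(
                f"p_ad level {lv} has fewer than 3 distinct E levels"
            )
    if np.max(pg_obs) <= 0.0:
        raise FitError("no positive gross rates at E > 0; degenerate input")

    k = levels.size
    idx = np.searchsorted(levels, p_ad)
    pmax0 = 1.05 * float(np.max(pg_obs))
    phi0 = np.full(k, _slope_guess(e, pg_obs))
    theta0 = np.full(k, 0.7)
    x0 = np.concatenate([[pmax0], phi0, theta0])
    lo = np.concatenate([[0.1 * pmax0], np.full(k, 1e-6), np.full(k, 1e-6)])
    hi = np.concatenate([[10.0 * pmax0], np.full(k, 1.0), np.full(k, 1.0)])

    def model(x):
        pmax = x[0]
        phi = x[1 : 1 + k][idx]
        theta = x[1 + k :][idx]
        s = phi * e + pmax
        disc = np.maximum(s * s - 4.0 * phi * e * pmax * theta, 0.0)
        return (s - np.sqrt(disc)) / (2.0 * np.maximum(theta, 1e-12))

    def residual(x, sqrt_w):
        return sqrt_w * (pg_obs - model(x))

    x, converged, n_iter, path = _irls(residual, model, x0, (lo, hi))
    return GroupFitResult(
        p_max=float(x[0]),
        phi={float(lv): float(v) for lv, v in zip(levels, x[1 : 1 + k])},
        theta={float(lv): float(v) for lv, v in zip(levels, x[1 + k :])},
        rd=rd,
        converged=converged,
        n_iter=n_iter,
        objective_path=path,
    )


def _slope_guess(e, pg):
    low = e <= np.percentile(e, 30)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = pg[low] / e[low]
    r = r[np.isfinite(r) & (r > 0)]
    return float(np.clip(np.median(r) if r.size else 0.05, 1e-4, 0.5))


@dataclass
class ShapeFitResult:
    shape: ShapeParams
    rss_phi: float
    rss_theta: float


def fit_shape_params(
    phi_points, theta_points, seed: int = 0, n_starts: int = 20
) -> ShapeFitResult:
    """Fit the two standardized shape functions to pooled z-score profiles.

    ``phi_points`` and ``theta_points`` are sequences of ``(p_ad, z)`` pairs.
    The quadratic is solved by ordinary least squares; the seven-parameter
    sigmoid-plus-exponential is multimodal and weakly identified from few
    design points, so it is fitted with ``n_starts`` seeded random restarts
    and the best residual sum of squares is kept — downstream results depend
    only on the fitted curve, not the coefficients (affine invariance).
    """
    phi_pts = np.asarray(phi_points, dtype=float)
    th_pts = np.asarray(theta_points, dtype=float)
    if np.unique(phi_pts[:, 0]).size < 4:
        raise UnidentifiableError("quadratic shape needs >= 4 distinct p_ad levels")
    if np.unique(th_pts[:, 0]).size < 7:
        raise UnidentifiableError("convexity shape needs >= 7 distinct p_ad levels")
    if np.unique(th_pts[:, 1]).size < 2:
        raise DomainError("constant convexity z-scores; shape fit degenerate")

    # Eq-linear quadratic: design matrix [1, p, p²].
    p = phi_pts[:, 0]
    A = np.column_stack([np.ones_like(p), p, p * p])
    a_coef, rss_phi, *_ = np.linalg.lstsq(A, phi_pts[:, 1], rcond=None)
    rss_phi = float(np.sum((A @ a_coef - phi_pts[:, 1]) ** 2))

    pt, zt = th_pts[:, 0], th_pts[:, 1]

    def theta_model(b, pp):
        b1, b2, b3, b4, b5, b6, b7 = b
        return b1 + b2 / (1.0 + b3 * np.exp(-b4 * (pp - b5))) - b6 * np.exp(
            b4 * (pp - b7)
        )

    def resid(b):
        with np.errstate(over="ignore"):
            m = theta_model(b, pt)
        return np.where(np.isfinite(m), m - zt, 1e6)

    rng = np.random.default_rng(seed)
    zspan = zt.max() - zt.min()
    best = None
    for _ in range(n_starts):
        b0 = np.array(
            [
                zt.min() + zspan * rng.uniform(-1, 1),
                zspan * rng.uniform(0.5, 3.0),
                rng.uniform(0.1, 5.0),
                rng.uniform(0.005, 0.2),
                rng.uniform(-100.0, 100.0),
                zspan * rng.uniform(0.0, 0.2),
                rng.uniform(-100.0, 100.0),
            ]
        )
        try:
            sol = least_squares(resid, b0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("all convexity-shape starts failed")
    rss_theta = float(2.0 * best.cost)
    shape = ShapeParams(a=tuple(a_coef), b=tuple(best.x))
    return ShapeFitResult(shape=shape, rss_phi=rss_phi, rss_theta=rss_theta)


@dataclass
class BilateralFitResult:
    params: BilateralLRCParams
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)


def fit_bilateral(
    records: pd.DataFrame, rd: float, shape: ShapeParams | None = None
) -> BilateralFitResult:
    """Joint IRLS fit of the five bilateral parameters for one leaf class.

    Intermediate ``p_ad`` records constrain the anchors through the affine
    rescale of the shape functions.  Requires at least two distinct ``p_ad``
    levels; a single level cannot separate the adaxial and abaxial anchors.
    """
    shape = shape or ShapeParams()
    e, pg_obs, p_ad = _positive_records(records, rd)
    if np.unique(p_ad).size < 2:
        raise UnidentifiableError(
            "records cover a single p_ad level; anchor parameters unidentifiable"
        )
    if np.max(pg_obs) <= 0.0:
        raise FitError("no positive gross rates at E > 0; degenerate input")

    s_phi = np.asarray(shape_phi(p_ad, shape), dtype=float)
    s_th = np.asarray(shape_theta(p_ad, shape), dtype=float)
    sp0, sp100 = float(shape_phi(0.0, shape)), float(shape_phi(100.0, shape))
    st0, st100 = float(shape_theta(0.0, shape)), float(shape_theta(100.0, shape))
    u_phi = (s_phi - sp0) / (sp100 - sp0)  # 0 at abaxial anchor, 1 at adaxial
    u_th = (s_th - st0) / (st100 - st0)

    pmax0 = 1.05 * float(np.max(pg_obs))
    x0 = np.array([_slope_guess(e, pg_obs), _slope_guess(e, pg_obs), pmax0, 0.7, 0.7])
    lo = np.array([1e-6, 1e-6, 0.1 * pmax0, 1e-6, 1e-6])
    hi = np.array([1.0, 1.0, 10.0 * pmax0, 1.0, 1.0])

    def model(x):
        phi_ad, phi_ab, pmax, th_ad, th_ab = x
        phi = np.maximum(phi_ab + (phi_ad - phi_ab) * u_phi, 1e-9)
        theta = np.clip(th_ab + (th_ad - th_ab) * u_th, 1e-9, 1.0 - 1e-9)
        s = phi * e + pmax
        disc = np.maximum(s * s - 4.0 * phi * e * pmax * theta, 0.0)
        return (s - np.sqrt(disc)) / (2.0 * theta)

    def residual(x, sqrt_w):
        return sqrt_w * (pg_obs - model(x))

    x, converged, n_iter, path = _irls(residual, model, x0, (lo, hi))
    params = BilateralLRCParams(
        phi_ad=float(x[0]),
        phi_ab=float(x[1]),
        p_max=float(x[2]),
        theta_ad=float(x[3]),
        theta_ab=float(x[4]),
        rd=rd,
        shape=shape,
    )
    return BilateralFitResult(
        params=params, converged=converged, n_iter=n_iter, objective_path=path
    )


@dataclass(frozen=True)
class ETRCalibration:
    """Through-origin quadratic ``Pg = k1*J + k2*J**2`` for one leaf surface."""

    k1: float
    k2: float
    surface: str

    def predict(self, j):
        j = np.asarray(j, dtype=float)
        return self.k1 * j + self.k2 * j * j

    def invert(self, pg):
        """Electron transport rate on the monotone branch through the origin."""
        pg = np.asarray(pg, dtype=float)
        disc = self.k1 * self.k1 + 4.0 * self.k2 * pg
        if np.any(disc < 0.0):
            raise DomainError("Pg beyond the calibration quadratic's vertex")
        denom = self.k1 + np.sqrt(disc)
        if np.any(denom <= 0.0):
            raise DomainError("calibration not invertible over the requested range")
        return 2.0 * pg / denom


def fit_etr_calibration(j, pg, surface: str) -> ETRCalibration:
    """Least-squares fit of ``Pg = k1*J + k2*J**2`` through the origin."""
    j = np.asarray(j, dtype=float)
    pg = np.asarray(pg, dtype=float)
    if j.size < 3:
        raise MissingDataError("ETR calibration needs >= 3 (J, Pg) pairs per surface")
    A = np.column_stack([j, j * j])
    coef, *_ = np.linalg.lstsq(A, pg, rcond=None)
    return ETRCalibration(k1=float(coef[0]), k2=float(coef[1]), surface=surface)


def etr_to_pseudo_gas_exchange(
    etr_records: pd.DataFrame,
    calib_ad: ETRCalibration,
    calib_ab: ETRCalibration,
    rd: float,
) -> pd.DataFrame:
    """Convert ETR light-response records into pseudo gas-exchange records.

    Adaxially irradiated records map to ``p_ad = 100`` and abaxially
    irradiated ones to ``p_ad = 0``; ``Pn = Pg(J) + Rd``.
    """
    frames = []
    for surface, calib, p_ad in (
        ("adaxial", calib_ad, 100.0),
        ("abaxial", calib_ab, 0.0),
    ):
        sub = etr_records.loc[etr_records["surface"] == surface]
        if len(sub) == 0:
            raise UnidentifiableError(f"missing {surface} ETR records")
        pg = calib.predict(sub["J"].to_numpy(dtype=float))
        frames.append(
            pd.DataFrame(
                {
                    "E": sub["E"].to_numpy(dtype=float),
                    "p_ad": p_ad,
                    "pn": pg + rd,
                    "das": sub["das"].to_numpy() if "das" in sub else 0,
                    "leaf_rank": sub["leaf_rank"].to_numpy()
                    if "leaf_rank" in sub
                    else 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lrc_from_etr(
    etr_records: pd.DataFrame,
    calib_ad: ETRCalibration,
    calib_ab: ETRCalibration,
    rd: float,
    shape: ShapeParams | None = None,
) -> BilateralFitResult:
    """Bilateral light-response parameters for a leaf class measured only by ETR."""
    pseudo = etr_to_pseudo_gas_exchange(etr_records, calib_ad, calib_ab, rd)
    return fit_bilateral(pseudo, rd, shape)


def rd_from_neighbours(rd_by_class: dict[tuple[int, int], float], das: int) -> float:
    """Dark respiration for an ETR-derived leaf class.

    Mean of the measured second- and third-leaf Rd values at the same
    day-after-sowing.
    """
    vals = [v for (d, rank), v in rd_by_class.items() if d == das and rank in (2, 3)]
    if not vals:
        raise MissingDataError(f"no measured 2nd/3rd-leaf Rd at {das} DAS")
    return float(np.mean(vals))
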