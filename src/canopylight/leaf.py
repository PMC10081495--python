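"""Bilateral light-response model of leaf net photosynthesis.

A leaf irradiated on both surfaces receives a total photosynthetic photon flux
density (PPFD) ``E = E_ad + E_ab`` with an adaxial proportion
``p_ad = 100 * E_ad / E`` (percent).  The net photosynthetic rate follows a
non-rectangular hyperbola

    Pn(E) = Pg(E) + Rd,
    theta * Pg^2 - (phi*E + P_max) * Pg + phi*E*P_max = 0   (smaller root),

whose initial slope ``phi`` and convexity ``theta`` depend on ``p_ad``.  The
dependence is carried by two empirical *shape functions* fitted on z-score
standardized parameters (a quadratic for ``phi``, a sigmoid-plus-exponential
for ``theta``), which are affinely rescaled so that they pass exactly through
the two single-surface anchors at ``p_ad = 0`` (abaxial only) and
``p_ad = 100`` (adaxial only).  Because the rescale is affine, only the *shape*
of the standardized curves matters; any affine transform of a shape function
leaves every model prediction unchanged.

Units: PPFD and photosynthetic rates in µmol m⁻² s⁻¹; ``p_ad`` in percent;
``phi`` is a dimensionless quantum-yield-like slope; ``theta`` dimensionless
in [0, 1]; dark respiration ``Rd <= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateAnchorError, DomainError

__all__ = [
    "DEFAULT_SHAPE",
    "AffineMap",
    "BilateralIrradiance",
    "BilateralLRCParams",
    "LRCParams",
    "ShapeParams",
    "bilateral_pn",
    "bilateral_pn_arrays",
    "pn_curve",
    "rescale",
    "shape_phi",
    "shape_theta",
]

# Convexity values are clamped just below 1 so the discriminant stays positive.
_THETA_MAX = 1.0 - 1e-9
_THETA_MIN = 1e-9
_PHI_MIN = 1e-9


@dataclass(frozen=True)
class ShapeParams:
    """Coefficients of the two standardized shape functions.

    ``a = (a1, a2, a3)`` define the quadratic z-score shape of the initial
    slope; ``b = (b1 ... b7)`` define the sigmoid-plus-exponential z-score
    shape of the convexity.  Defaults are the fitted values for komatsuna.
    """

    a: tuple[float, float, float] = (-0.87, -0.026, 0.00028)
    b: tuple[float, float, float, float, float, float, float] = (
        -226.0,
        267.0,
        2.4,
        0.0054,
        -98.0,
        0.0017,
        -5.7,
    )

    def __post_init__(self) -> None:
        if len(self.a) != 3 or len(self.b) != 7:
            raise DomainError("ShapeParams requires 3 'a' and 7 'b' coefficients")


DEFAULT_SHAPE = ShapeParams()


def _check_pad(p_ad) -> np.ndarray:
    p = np.asarray(p_ad, dtype=float)
    if np.any(p < 0.0) or np.any(p > 100.0):
        raise DomainError(f"p_ad must lie in [0, 100], got {p_ad!r}")
    return p


def shape_phi(p_ad, shape: ShapeParams = DEFAULT_SHAPE):
    """Standardized initial slope phi' at adaxial proportion ``p_ad`` (%)."""
    p = _check_pad(p_ad)
    a1, a2, a3 = shape.a
    return a1 + a2 * p + a3 * p * p


def shape_theta(p_ad, shape: ShapeParams = DEFAULT_SHAPE):
    """Standardized convexity theta' at adaxial proportion ``p_ad`` (%).

    theta' = b1 + b2 / (1 + b3*exp(-b4*(p_ad - b5))) - b6*exp(b4*(p_ad - b7))
    """
    p = _check_pad(p_ad)
    b1, b2, b3, b4, b5, b6, b7 = shape.b
    return b1 + b2 / (1.0 + b3 * np.exp(-b4 * (p - b5))) - b6 * np.exp(b4 * (p - b7))


@dataclass(frozen=True)
class LRCParams:
    """Single light-response curve: initial slope, maximum, convexity, respiration."""

    phi: float
    p_max: float
    theta: float
    rd: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise DomainError(f"phi must be > 0, got {self.phi}")
        if not self.p_max > 0:
            raise DomainError(f"p_max must be > 0, got {self.p_max}")
        if not 0.0 <= self.theta <= 1.0:
            raise DomainError(f"theta must lie in [0, 1], got {self.theta}")
        if self.rd > 0:
            raise DomainError(f"rd must be <= 0, got {self.rd}")


def gross_rate(E, phi: float, p_max: float, theta: float):
    """Gross photosynthetic rate Pg(E): smaller root of the hyperbola quadratic.

    Vectorized over ``E``.  ``theta == 0`` falls back to the rectangular
    hyperbola limit ``phi*E*p_max / (phi*E + p_max)``.
    """
    e = np.asarray(E, dtype=float)
    if np.any(e < 0.0):
        raise DomainError("E must be non-negative")
    s = phi * e + p_max
    if theta == 0.0:
        with np.errstate(invalid="ignore"):
            pg = np.where(s > 0, phi * e * p_max / s, 0.0)
        return pg if pg.shape else float(pg)
    disc = s * s - 4.0 * phi * e * p_max * theta
    if np.any(disc < -1e-9 * p_max * p_max):
        raise RuntimeError("negative discriminant in the hyperbola quadratic")
    disc = np.maximum(disc, 0.0)
    pg = (s - np.sqrt(disc)) / (2.0 * theta)
    return pg if pg.shape else float(pg)


def pn_curve(E, params: LRCParams):
    """Net photosynthetic rate Pn(E) = Pg(E) + Rd for a single-surface curve."""
    return gross_rate(E, params.phi, params.p_max, params.theta) + params.rd


@dataclass(frozen=True)
class BilateralIrradiance:
    """Per-surface photon flux densities on a leaf (µmol m⁻² s⁻¹)."""

    e_ad: float
    e_ab: float

    def __post_init__(self) -> None:
        if self.e_ad < 0 or self.e_ab < 0:
            raise DomainError("surface irradiances must be non-negative")

    @property
    def total(self) -> float:
        return self.e_ad + self.e_ab

    @property
    def p_ad(self) -> float:
        """Adaxial proportion in percent; 100 by convention for a dark leaf."""
        e = self.total
        if e == 0.0:
            return 100.0
        return 100.0 * self.e_ad / e


@dataclass(frozen=True)
class AffineMap:
    """Affine rescale ``x -> c1 + c2 * x`` pinning a shape curve to two anchors."""

    c1: float
    c2: float

    def __call__(self, x):
        return self.c1 + self.c2 * np.asarray(x, dtype=float)


def _anchor_map(val_ab: float, val_ad: float, shape_fn, shape: ShapeParams) -> AffineMap:
    s0 = float(shape_fn(0.0, shape))
    s100 = float(shape_fn(100.0, shape))
    if s0 == s100:
        raise DegenerateAnchorError(
            "shape function takes equal values at p_ad = 0 and 100; anchors indistinguishable"
        )
    c2 = (val_ad - val_ab) / (s100 - s0)
    c1 = val_ab - c2 * s0
    return AffineMap(c1, c2)


def rescale(val_ab: float, val_ad: float, shape_fn, p_ad, shape: ShapeParams = DEFAULT_SHAPE):
    """Interpolate a curve parameter between its two single-surface anchors.

    The standardized shape ``shape_fn`` fixes *how* the parameter varies with
    ``p_ad``; the affine map pins it to ``val_ab`` at ``p_ad = 0`` and
    ``val_ad`` at ``p_ad = 100``.  Exact at the anchors; invariant to any
    affine pre-transform of ``shape_fn``.
    """
    m = _anchor_map(val_ab, val_ad, shape_fn, shape)
    return m(shape_fn(p_ad, shape))


@dataclass(frozen=True)
class BilateralLRCParams:
    """Five-parameter bilateral light-response curve for one leaf class.

    ``phi_ad``/``theta_ad`` are the single-surface parameters for purely
    adaxial irradiation (``p_ad = 100``), ``phi_ab``/``theta_ab`` for purely
    abaxial (``p_ad = 0``).  ``p_max`` is shared across ``p_ad``.
    """

    phi_ad: float
    phi_ab: float
    p_max: float
    theta_ad: float
    theta_ab: float
    rd: float
    shape: ShapeParams = field(default_factory=ShapeParams)

    def __post_init__(self) -> None:
        if not (self.phi_ad > 0 and self.phi_ab > 0):
            raise DomainError("phi anchors must be > 0")
        if not self.p_max > 0:
            raise DomainError("p_max must be > 0")
        for name, th in (("theta_ad", self.theta_ad), ("theta_ab", self.theta_ab)):
            if not 0.0 < th <= 1.0:
                raise DomainError(f"{name} must lie in (0, 1], got {th}")
        if self.rd > 0:
            raise DomainError("rd must be <= 0")

    def params_at(self, p_ad: float) -> LRCParams:
        """Single-surface curve parameters at an arbitrary adaxial proportion."""
        phi = float(rescale(self.phi_ab, self.phi_ad, shape_phi, p_ad, self.shape))
        theta = float(rescale(self.theta_ab, self.theta_ad, shape_theta, p_ad, self.shape))
        phi = max(phi, _PHI_MIN)
        theta = min(max(theta, _THETA_MIN), _THETA_MAX)
        return LRCParams(phi=phi, p_max=self.p_max, theta=theta, rd=self.rd)


def bilateral_pn(irr: BilateralIrradiance, params: BilateralLRCParams) -> float:
    """Net photosynthetic rate for a leaf lit on both surfaces."""
    sub = params.params_at(irr.p_ad)
    return float(pn_curve(irr.total, sub))


def bilateral_pn_arrays(e_ad, e_ab, params: BilateralLRCParams):
    """Vectorized :func:`bilateral_pn` over arrays of per-surface irradiances.

    Used by the canopy aggregation step where tens of thousands of triangles
    are evaluated at once.
    """
    e_ad = np.asarray(e_ad, dtype=float)
    e_ab = np.asarray(e_ab, dtype=float)
    if np.any(e_ad < 0) or np.any(e_ab < 0):
        raise DomainError("surface irradiances must be non-negative")
    total = e_ad + e_ab
    p_ad = np.where(total > 0, 100.0 * e_ad / np.where(total > 0, total, 1.0), 100.0)
    p_ad = np.clip(p_ad, 0.0, 100.0)  # guard float round-off at the anchors

    phi_map = _anchor_map(params.phi_ab, params.phi_ad, shape_phi, params.shape)
    theta_map = _anchor_map(params.theta_ab, params.theta_ad, shape_theta, params.shape)
    phi = np.maximum(phi_map(shape_phi(p_ad, params.shape)), _PHI_MIN)
    theta = np.clip(theta_map(shape_theta(p_ad, params.shape)), _THETA_MIN, _THETA_MAX)

    s = phi * total + params.p_max
    disc = np.maximum(s * s - 4.0 * phi * total * params.p_max * theta, 0.0)
    pg = (s - np.sqrt(disc)) / (2.0 * theta)
    return pg + params.rd
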