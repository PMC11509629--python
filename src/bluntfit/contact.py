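"""Exact forward contact-mechanics models for rigid indenters on an elastic
half-space.

The central objects are the blunted-cone and blunted-pyramid force laws.
Both are expressed in terms of the contact radius ``a``; the matching depth
``h(a)`` comes from :func:`bluntfit.geometry.depth_from_contact_radius`.  For
contact confined to the spherical cap (``a < b``) the force reduces exactly to
the Hertz law, and the two branches join continuously (to machine precision)
at the transition ``a = b``.

Unit-modulus convention: every force function is strictly proportional to the
reduced modulus ``E* = E/(1 - nu**2)``, so the shapes can be evaluated once at
``E* = 1`` and rescaled -- the classic one-parameter modulus fit exploits
exactly this linearity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma

from .curves import ForceCurve
from .geometry import (
    ContactRegime,
    IndenterGeometry,
    InvalidGeometryError,
    Material,
    TipFamily,
    contact_radius_from_depth,
    depth_from_contact_radius,
    pyramid_side_factor,
    transition_depth,
    transition_radius,
)

__all__ = [
    "SphereCorrectionCoefficients",
    "force_blunted_cone",
    "force_blunted_pyramid",
    "force_hertz",
    "force_sneddon_cone",
    "force_axisymmetric",
    "force_sphere_corrected",
    "force_large_depth",
    "large_depth_contact_radius",
    "force_from_depth",
    "generate_exact_curve",
]


def force_hertz(h, R: float, mat: Material):
    """Hertz law F = (4/3) E* sqrt(R) h^(3/2) for a parabolic/spherical tip."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    F = (4.0 / 3.0) * mat.E_star * math.sqrt(R) * h**1.5
    return F if F.ndim else float(F)


def force_sneddon_cone(h, theta: float, mat: Material):
    """Sneddon's perfect-cone law F = (2/pi) E* tan(theta) h**2."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    F = (2.0 / math.pi) * mat.E_star * math.tan(theta) * h**2
    return F if F.ndim else float(F)


def force_axisymmetric(h, B: float, n: float, mat: Material):
    """Sneddon's general power-law-profile solution.

    For an axisymmetric rigid profile ``f(r) = B r**n`` (n > 0),

        F = 2 E* (n/(n+1)) * [G / (sqrt(pi) B)]**(1/n) * h**(1 + 1/n),
        G = Gamma(n/2 + 1/2) / Gamma(n/2 + 1).

    ``n = 1`` with ``B = 1/tan(theta)`` reproduces the cone law and ``n = 2``
    with ``B = 1/(2R)`` the Hertz law, exactly.  The force exponent is
    ``m = 1 + 1/n``.
    """
    if not n > 0:
        raise ValueError("shape exponent n must be positive")
    if not B > 0:
        raise ValueError("profile coefficient B must be positive")
    h = np.asarray(h, dtype=float)
    G = _gamma(n / 2 + 0.5) / _gamma(n / 2 + 1.0)
    F = (
        2.0 * mat.E_star * (n / (n + 1.0))
        * (G / (math.sqrt(math.pi) * B)) ** (1.0 / n)
        * h ** (1.0 + 1.0 / n)
    )
    return F if F.ndim else float(F)


def _force_blunted(a, geom: IndenterGeometry, mat: Material, s: float):
    a = np.asarray(a, dtype=float)
    b = transition_radius(geom)
    if np.any(a < b * (1.0 - 1e-12)):
        raise ValueError("blunted force law is valid only for a >= b")
    a = np.maximum(a, b)
    R, t = geom.R, math.tan(geom.theta)
    h = depth_from_contact_radius(a, geom)
    wedge = math.pi / 2 - np.arcsin(np.clip(b / a, -1.0, 1.0))
    root = np.sqrt(np.maximum(a * a - b * b, 0.0))
    F = 2.0 * mat.E_star * (
        a * h
        - s * a * a / (2.0 * t) * wedge
        - a**3 / (3.0 * R)
        + root * (s * b / (2.0 * t) + (a * a - b * b) / (3.0 * R))
    )
    return F if F.ndim else float(F)


def force_blunted_cone(a, geom: IndenterGeometry, mat: Material):
    """Exact sphero-conical force at contact radius a >= b.

        F = 2 E* [ a h - (a**2 / 2 tan(theta)) (pi/2 - arcsin(b/a)) - a**3/(3R)
                   + sqrt(a**2 - b**2) ( b/(2 tan(theta)) + (a**2 - b**2)/(3R) ) ]

    with h = h(a) from the matching depth relation.  At ``a = b`` this equals
    the Hertz force at the transition depth; for ``a >> b`` it tends to
    Sneddon's cone law.
    """
    if geom.family is not TipFamily.SPHERO_CONICAL:
        raise InvalidGeometryError("force_blunted_cone requires a sphero_conical geometry")
    return _force_blunted(a, geom, mat, s=1.0)


def force_blunted_pyramid(a, geom: IndenterGeometry, mat: Material):
    """Exact blunted k-sided regular pyramid force at contact radius a >= b.

    Identical in structure to the blunted cone with every conical
    ``1/tan(theta)`` term multiplied by the side factor ``(k/pi) sin(pi/k)``;
    converges to :func:`force_blunted_cone` as ``k -> inf``.
    """
    if geom.family is not TipFamily.BLUNTED_PYRAMID:
        raise InvalidGeometryError("force_blunted_pyramid requires a blunted_pyramid geometry")
    return _force_blunted(a, geom, mat, s=pyramid_side_factor(geom.k))


@dataclass(frozen=True)
class SphereCorrectionCoefficients:
    """Polynomial depth-correction constants of the extended spherical model.

    Defaults are the published three-term (N = 3, valid for h < R) values.
    """

    c1: float = 1.014
    c2: float = -0.09059
    c3: float = -0.09431


def force_sphere_corrected(
    h,
    R: float,
    mat: Material,
    coeff: SphereCorrectionCoefficients = SphereCorrectionCoefficients(),
):
    """Depth-corrected spherical-indenter force, F = (4/3) E* sqrt(R) h^(3/2) Z.

    The correction polynomial

        Z = c1 + (3/4) c2 (h/R)**(1/2) + (1/2) c3 (h/R)**(3/2)

    captures the deviation of a true sphere from the parabolic (Hertz)
    approximation for depths up to the radius; Z -> c1 as h -> 0 and Z < 1
    near h = R, which is why a naive Hertz fit underestimates the modulus
    there.  A warning is emitted for h >= R (outside the stated validity).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("indentation depth must be non-negative")
    if np.any(h >= R):
        warnings.warn(
            "depth-corrected spherical model evaluated at h >= R (outside its "
            "stated validity h < R)",
            stacklevel=2,
        )
    x = np.sqrt(h / R)
    Z = coeff.c1 + 0.75 * coeff.c2 * x + 0.5 * coeff.c3 * x**3
    F = (4.0 / 3.0) * mat.E_star * math.sqrt(R) * h**1.5 * Z
    return F if F.ndim else float(F)


def large_depth_contact_radius(h, geom: IndenterGeometry):
    """Approximate contact radius r_c for deep sphero-conical indentation.

    With the transition depth approximated by h_T ~ R, the deep-contact
    radius of the exact depth relation expands to

        r_c ~ (2/pi) [ h tan(theta) + R (1 - tan(theta)/2) ].
    """
    h = np.asarray(h, dtype=float)
    t = math.tan(geom.theta)
    rc = (2.0 / math.pi) * (h * t + geom.R * (1.0 - t / 2.0))
    return rc if rc.ndim else float(rc)


def force_large_depth(h, geom: IndenterGeometry, mat: Material):
    """Large-depth (h > 3R) closed-form approximation of the blunted cone.

    Integrating the contact stiffness S = 2 E* r_c(h) with the deep-contact
    radius of :func:`large_depth_contact_radius` gives

        F = (2/pi) E* [ tan(theta) h**2 + (2 - tan(theta)) R h ],

    which is monotone in h, reduces to Sneddon's cone law as R -> 0 or
    h/R -> inf, and agrees with the exact blunted-cone model to ~0.5% at the
    h = 3R boundary (~1% at h = 10R).  A warning is emitted for h <= 3R,
    where the shallow-depth models should be used instead.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 3.0 * geom.R):
        warnings.warn(
            "large-depth approximation evaluated at h <= 3R (outside its "
            "stated validity h > 3R)",
            stacklevel=2,
        )
    t = math.tan(geom.theta)
    F = (2.0 / math.pi) * mat.E_star * (t * h**2 + (2.0 - t) * geom.R * h)
    return F if F.ndim else float(F)


def force_from_depth(h, geom: IndenterGeometry, mat: Material):
    """Piecewise-exact force at depth(s) h for any supported tip family.

    Blunted families use Hertz below the transition depth and the exact
    blunted law above it (inverting the depth relation numerically); spheres
    use Hertz; perfect cones use Sneddon.
    """
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any(h_arr < 0):
        raise ValueError("indentation depth must be non-negative")
    if geom.family is TipFamily.SPHERE:
        F = force_hertz(h_arr, geom.R, mat)
    elif geom.family is TipFamily.PERFECT_CONE:
        F = force_sneddon_cone(h_arr, geom.theta, mat)
    else:
        h_T = transition_depth(geom)
        blunt = (
            force_blunted_cone
            if geom.family is TipFamily.SPHERO_CONICAL
            else force_blunted_pyramid
        )
        F = np.empty_like(h_arr)
        cap = h_arr <= h_T
        F[cap] = force_hertz(h_arr[cap], geom.R, mat)
        for i in np.nonzero(~cap)[0]:
            state = contact_radius_from_depth(float(h_arr[i]), geom)
            F[i] = blunt(state.a, geom, mat)
    return F if np.ndim(h) else float(F[0])


def generate_exact_curve(
    geom: IndenterGeometry,
    mat: Material,
    a_range: tuple[float, float] | None = None,
    h_range: tuple[float, float] | None = None,
    n_points: int = 200,
) -> ForceCurve:
    """Sample a noiseless force-indentation curve on a uniform grid.

    Exactly one of ``a_range`` (contact-radius interval, meters) or
    ``h_range`` (depth interval, meters) must be given; sampling is uniform
    in that variable.  The returned curve is strictly increasing in both
    columns and continuous across the cap/body transition.
    """
    if (a_range is None) == (h_range is None):
        raise ValueError("specify exactly one of a_range or h_range")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    if a_range is not None:
        if not geom.is_blunted:
            raise InvalidGeometryError("a_range sampling requires a blunted geometry")
        a_lo, a_hi = a_range
        if not 0 <= a_lo < a_hi:
            raise ValueError("invalid contact-radius interval")
        a = np.linspace(a_lo, a_hi, n_points)
        b = transition_radius(geom)
        h = np.where(
            a < b, a * a / geom.R, depth_from_contact_radius(np.maximum(a, b), geom)
        )
    else:
        h_lo, h_hi = h_range
        if not 0 <= h_lo < h_hi:
            raise ValueError("invalid depth interval")
        h = np.linspace(h_lo, h_hi, n_points)
    F = force_from_depth(h, geom, mat)
    meta = {
        "tip_family": geom.family.value,
        "E_Pa": mat.E,
        "poisson": mat.nu,
        "noise_sigma_N": 0.0,
    }
    if geom.R is not None:
        meta["tip_radius_m"] = geom.R
    if geom.theta is not None:
        meta["half_angle_deg"] = math.degrees(geom.theta)
    if geom.k is not None:
        meta["pyramid_sides"] = geom.k
    return ForceCurve(h=np.asarray(h, dtype=float), F=np.asarray(F, dtype=float), metadata=meta)
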