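"""Indenter geometry, material parameters and the depth <-> contact-radius map.

An AFM tip is modelled as one of four axisymmetric (or effectively
axisymmetric) rigid shapes pressed into an elastic half-space:

* ``sphero_conical`` -- a cone of half-angle ``theta`` whose apex is replaced
  by a spherical cap of radius ``R`` merging tangentially with the cone body.
* ``blunted_pyramid`` -- a regular ``k``-sided pyramid with the same kind of
  spherical cap.
* ``perfect_cone`` -- the sharp-tip idealisation (Sneddon's model).
* ``sphere`` -- a spherical/parabolic tip (Hertzian contact).

For the blunted families the cap meets the body at the transition radius
``b = R cos(theta)``; the corresponding transition depth is ``h_T = b**2 / R``
(the depth at which the Hertzian contact radius ``a = sqrt(R h)`` reaches
``b``).  Below ``h_T`` the contact is purely spherical; above it the contact
annulus extends onto the conical (or pyramidal) body and depth and contact
radius are linked by a transcendental relation that must be inverted
numerically.

All quantities are strict SI (meters, radians) internally; degree-valued
angles are accepted only at construction time via ``theta_deg``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TipFamily",
    "IndenterGeometry",
    "Material",
    "ContactState",
    "ContactRegime",
    "InvalidGeometryError",
    "pyramid_side_factor",
    "transition_radius",
    "transition_depth",
    "depth_from_contact_radius",
    "contact_radius_from_depth",
]


class InvalidGeometryError(ValueError):
    """Raised when an operation is applied to an unsupported tip family."""


class TipFamily(str, enum.Enum):
    SPHERO_CONICAL = "sphero_conical"
    BLUNTED_PYRAMID = "blunted_pyramid"
    PERFECT_CONE = "perfect_cone"
    SPHERE = "sphere"


class ContactRegime(str, enum.Enum):
    SPHERICAL_CAP = "spherical_cap"  # a < b, Hertzian cap contact
    BLUNTED = "blunted"              # a >= b, contact extends onto the body


_BLUNTED = (TipFamily.SPHERO_CONICAL, TipFamily.BLUNTED_PYRAMID)


@dataclass(frozen=True)
class IndenterGeometry:
    """Rigid-tip geometry.

    Parameters
    ----------
    family : TipFamily or str
        Tip shape family.
    R : float, optional
        Apex radius of curvature in meters.  Required for every family with a
        spherical cap (all except ``perfect_cone``).
    theta : float, optional
        Cone/pyramid half-angle in radians, measured so that a *larger* theta
        is a *blunter* tip (``tan(theta)`` multiplies ``h**2`` in Sneddon's
        cone law).  Required for conical/pyramidal families.  Use
        ``theta_deg`` to pass degrees instead.
    theta_deg : float, optional
        Half-angle in degrees; mutually exclusive with ``theta``.
    k : int, optional
        Side count of the pyramid (>= 3); only for ``blunted_pyramid``.
    """

    family: TipFamily
    R: float | None = None
    theta: float | None = None
    k: int | None = None
    theta_deg: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", TipFamily(self.family))
        if self.theta_deg is not None:
            if self.theta is not None:
                raise ValueError("pass either theta (radians) or theta_deg, not both")
            object.__setattr__(self, "theta", math.radians(self.theta_deg))
        needs_R = self.family is not TipFamily.PERFECT_CONE
        needs_theta = self.family is not TipFamily.SPHERE
        if needs_R:
            if self.R is None or not self.R > 0:
                raise ValueError(f"{self.family.value} geometry requires R > 0")
        if needs_theta:
            if self.theta is None or not 0 < self.theta < math.pi / 2:
                raise ValueError(
                    f"{self.family.value} geometry requires half-angle in (0, pi/2)"
                )
        if self.family is TipFamily.BLUNTED_PYRAMID:
            if self.k is None or int(self.k) < 3:
                raise ValueError("blunted_pyramid requires an integer side count k >= 3")
            object.__setattr__(self, "k", int(self.k))
        elif self.k is not None:
            raise ValueError(f"side count k is only meaningful for blunted_pyramid")

    # -- derived quantities -------------------------------------------------

    @property
    def is_blunted(self) -> bool:
        return self.family in _BLUNTED

    @property
    def b(self) -> float:
        """Transition radius b = R cos(theta) (tangential cap-body merge)."""
        return transition_radius(self)

    @property
    def h_T(self) -> float:
        """Transition depth b**2 / R at which the contact leaves the cap."""
        return transition_depth(self)

    @property
    def side_factor(self) -> float:
        """(k/pi) sin(pi/k) for pyramids, 1.0 for axisymmetric tips."""
        if self.family is TipFamily.BLUNTED_PYRAMID:
            return pyramid_side_factor(self.k)
        return 1.0


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic half-space.

    ``E`` is the Young's modulus in pascals, ``nu`` the Poisson's ratio
    (0.5 for incompressible soft matter).  The reduced modulus
    ``E_star = E / (1 - nu**2)`` is the prefactor common to all the contact
    models here (rigid indenter on an elastic half-space).
    """

    E: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1 < self.nu <= 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5]")

    @property
    def E_star(self) -> float:
        return self.E / (1.0 - self.nu**2)

    @classmethod
    def from_reduced(cls, E_star: float, nu: float = 0.5) -> "Material":
        return cls(E=E_star * (1.0 - nu**2), nu=nu)


@dataclass(frozen=True)
class ContactState:
    """A (contact radius, depth) pair with its regime label."""

    a: float
    h: float
    regime: ContactRegime


def pyramid_side_factor(k: int) -> float:
    """Geometric factor (k/pi) sin(pi/k) of a regular k-sided pyramid.

    Tends to 1 as k -> inf (the pyramid becomes a cone).
    """
    if int(k) < 3:
        raise ValueError("pyramid side count k must be >= 3")
    k = int(k)
    return k / math.pi * math.sin(math.pi / k)


def transition_radius(geom: IndenterGeometry) -> float:
    """Contact radius b = R cos(theta) where the spherical cap meets the body."""
    if not geom.is_blunted:
        raise InvalidGeometryError(
            f"transition radius is undefined for family {geom.family.value!r}"
        )
    return geom.R * math.cos(geom.theta)


def transition_depth(geom: IndenterGeometry) -> float:
    """Depth h_T = b**2 / R = R cos(theta)**2 at which a = b."""
    b = transition_radius(geom)
    return b * b / geom.R


def depth_from_contact_radius(a, geom: IndenterGeometry):
    """Indentation depth h(a) for a blunted tip in the a >= b regime.

    Implements the blunted-cone depth relation

        h = (a/R) * (a - sqrt(a**2 - b**2))
            + s * (a/tan(theta)) * (pi/2 - arcsin(b/a))

    where ``s = (k/pi) sin(pi/k)`` for pyramids and 1 for cones.  At the
    transition ``a = b`` both correction terms vanish analytically and
    ``h = b**2/R``, matching the Hertzian cap relation ``a = sqrt(R h)``; h is
    strictly increasing in a.

    Accepts scalars or arrays; raises for any ``a < b`` (use the Hertzian
    relation there instead).
    """
    if not geom.is_blunted:
        raise InvalidGeometryError(
            f"depth_from_contact_radius requires a blunted family, got {geom.family.value!r}"
        )
    a = np.asarray(a, dtype=float)
    b = transition_radius(geom)
    if np.any(a < b * (1.0 - 1e-12)):
        raise ValueError("contact radius below the transition radius b: spherical-cap "
                         "regime, use a = sqrt(R h)")
    a = np.maximum(a, b)
    s = geom.side_factor
    root = np.sqrt(np.maximum(a * a - b * b, 0.0))
    h = (a / geom.R) * (a - root) + s * (a / math.tan(geom.theta)) * (
        math.pi / 2 - np.arcsin(np.clip(b / a, -1.0, 1.0))
    )
    return h if h.ndim else float(h)


def contact_radius_from_depth(
    h: float,
    geom: IndenterGeometry,
    rtol: float = 1e-12,
    max_expansions: int = 200,
) -> ContactState:
    """Invert h(a) for a blunted tip.

    For ``h <= h_T`` the contact is on the spherical cap and ``a = sqrt(R h)``
    in closed form.  Above the transition the monotone relation is solved by
    Brent's method on a bracket ``[b, a_hi]`` grown geometrically until the
    residual changes sign.
    """
    if h < 0:
        raise ValueError("indentation depth must be non-negative")
    b = transition_radius(geom)
    h_T = transition_depth(geom)
    if h <= h_T:
        return ContactState(a=math.sqrt(geom.R * h), h=h, regime=ContactRegime.SPHERICAL_CAP)

    # solve in units of b so the absolute tolerance is scale-free
    def residual(alpha: float) -> float:
        return depth_from_contact_radius(alpha * b, geom) - h

    alpha_hi = 2.0
    for _ in range(max_expansions):
        if residual(alpha_hi) >= 0.0:
            break
        alpha_hi *= 2.0
    else:  # pragma: no cover - pathological geometry guard
        raise RuntimeError("contact-radius bracket expansion did not converge")
    alpha = brentq(residual, 1.0, alpha_hi, xtol=rtol, rtol=rtol, maxiter=200)
    return ContactState(a=float(alpha * b), h=h, regime=ContactRegime.BLUNTED)
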