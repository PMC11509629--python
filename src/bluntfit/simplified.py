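"""Simplified power-law modulus estimator for blunted tips at shallow depth.

The exact blunted-cone/pyramid models never give force as an explicit
function of depth, which is what makes them awkward for routine AFM data
processing.  The simplification interpolates Sneddon's general axisymmetric
solution between its two closed-form anchors -- sphere (shape exponent
``n = 2``) at vanishing depth and cone (``n = 1``) at large depth -- by
replacing the depth-dependent profile coefficient ``B**(1/n)`` with

    B**(1/n) ~ (2R)**(1/n - 1) * tan(theta)**(n - 2) / f(n),   f(n) = n**(2 - n),

which is dimensionally consistent for every n and exact at both anchors
(f(1) = f(2) = 1).  A measured curve is then fitted to the trivial power law
``F = c h**m``; the shape exponent follows from the fitted slope,
``n = 1/(m - 1)``, and the prefactor is linear in the reduced modulus:

    c = 2 E* (n/(n+1)) (2R)**(1-1/n) (n tan(theta))**(2-n)
        * [Gamma(n/2 + 1/2) / (sqrt(pi) Gamma(n/2 + 1))]**(1/n)

so E follows by linear inversion.  The estimator is validated for maximum
depths below ~3R; beyond that it degrades gracefully (percent-level bias).

The X-ratio ``X = A E* / c`` compares a prefactor ``A`` fitted on known
reduced-modulus data with the theoretical ``c``; X = 1 means the simplified
prefactor is exact for that geometry and fit window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gamma as _gamma

from .geometry import IndenterGeometry, Material

__all__ = [
    "DegenerateExponentError",
    "ModulusEstimate",
    "correction_factor",
    "shape_exponent",
    "simplified_prefactor",
    "modulus_from_powerlaw",
    "x_ratio",
]

#: guard width around m = 1 below which n = 1/(m-1) is numerically meaningless
M_EPSILON = 1e-6


class DegenerateExponentError(ValueError):
    """Fitted exponent m <= 1 + eps: flat-punch-like data, n undefined."""


@dataclass(frozen=True)
class ModulusEstimate:
    """A recovered Young's modulus with its method label and diagnostics."""

    E: float
    method: str
    r_squared: float | None = None
    x_ratio: float | None = None
    domain_ratio: float | None = None  # h_max / R

    @property
    def E_kPa(self) -> float:
        return self.E / 1e3


def correction_factor(n: float) -> float:
    """Dimensionless interpolation factor f(n) = n**(2 - n), f(1) = f(2) = 1."""
    if not n > 0:
        raise ValueError("shape exponent n must be positive")
    return n ** (2.0 - n)


def shape_exponent(m: float) -> float:
    """Shape exponent n = 1/(m - 1) from a fitted force exponent m."""
    if not m > 1.0 + M_EPSILON:
        raise DegenerateExponentError(
            f"fitted exponent m = {m:.6g} is at or below 1: constant-contact-area "
            "(flat-punch-like) data, shape exponent n = 1/(m-1) is undefined"
        )
    return 1.0 / (m - 1.0)


def simplified_prefactor(mat: Material, geom: IndenterGeometry, n: float) -> float:
    """Theoretical power-law prefactor c for a blunted tip of shape exponent n.

    Units are N / m**(1 + 1/n), so that ``c * h**(1 + 1/n)`` is in newtons for
    any n.  Strictly proportional to ``E* = E/(1 - nu**2)``; reduces exactly
    to the Sneddon cone prefactor at n = 1 and to the Hertz prefactor at
    n = 2.
    """
    if not n > 0:
        raise ValueError("shape exponent n must be positive")
    R, theta = geom.R, geom.theta
    if R is None or theta is None:
        raise ValueError("simplified prefactor requires a geometry with R and theta")
    G = _gamma(n / 2 + 0.5) / _gamma(n / 2 + 1.0)
    return (
        2.0 * mat.E_star * (n / (n + 1.0))
        * (2.0 * R) ** (1.0 - 1.0 / n)
        * (n * math.tan(theta)) ** (2.0 - n)
        * (G / math.sqrt(math.pi)) ** (1.0 / n)
    )


def modulus_from_powerlaw(
    c: float,
    m: float,
    geom: IndenterGeometry,
    nu: float = 0.5,
    r_squared: float | None = None,
    h_max: float | None = None,
) -> ModulusEstimate:
    """Invert the simplified prefactor for the Young's modulus.

    Given a fitted ``F = c h**m`` (SI), computes ``n = 1/(m-1)`` and solves
    the linear relation ``c = E* * c_unit(n, R, theta)`` for ``E*``, returning
    ``E = E* (1 - nu**2)``.
    """
    n = shape_exponent(m)
    c_unit = simplified_prefactor(Material.from_reduced(1.0, nu=0.0), geom, n)
    E_star = c / c_unit
    if not E_star > 0:
        raise ValueError("non-positive prefactor: cannot recover a modulus")
    return ModulusEstimate(
        E=E_star * (1.0 - nu**2),
        method="simplified_blunt",
        r_squared=r_squared,
        domain_ratio=(h_max / geom.R) if (h_max is not None and geom.R) else None,
    )


def x_ratio(A: float, m: float, geom: IndenterGeometry, true_E_star: float = 1.0) -> float:
    """Accuracy diagnostic X = A E* / c for a fit on known-modulus data.

    ``A`` is the prefactor fitted on reduced data ``y = F / E*``; ``c`` is the
    theoretical simplified prefactor at the same geometry and the fitted
    exponent's ``n``.  X = 1 means the simplified estimator would recover the
    true reduced modulus exactly; X - 1 is its relative error.  Because both
    A E* and c scale linearly with E*, X does not depend on ``true_E_star``.
    """
    n = shape_exponent(m)
    c = simplified_prefactor(Material.from_reduced(true_E_star, nu=0.0), geom, n)
    return A * true_E_star / c
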