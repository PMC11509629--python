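"""Functional fitting surface over the sklearn-style estimators.

These helpers operate on :class:`~bluntfit.curves.ForceCurve` objects and
return plain :class:`FitResult` records; they are thin wrappers over
:mod:`bluntfit.estimators`, which hold the actual numerics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curves import ForceCurve
from .estimators import (
    ClassicModulusFit,
    ModulusEstimator,
    PowerLawForceFit,
    select_method,
)
from .geometry import IndenterGeometry

__all__ = ["FitResult", "fit_power_law", "fit_classic", "estimate_modulus", "select_method"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a curve fit.

    ``c``/``m``/``n`` are the power-law parameters (nan for the classic
    route, which has no explicit exponent); ``E`` is in pascals and is None
    for a plain power-law fit with no geometry attached.
    """

    method: str
    c: float
    m: float
    n: float
    E: float | None
    r_squared: float
    residual_norm: float
    n_points: int
    converged: bool

    @property
    def E_kPa(self) -> float | None:
        return None if self.E is None else self.E / 1e3


def fit_power_law(curve: ForceCurve) -> FitResult:
    """Fit F = c h**m by unweighted nonlinear least squares ("Fit 2")."""
    est = PowerLawForceFit().fit(curve.h, curve.F)
    return FitResult(
        method="power_law",
        c=est.prefactor_,
        m=est.exponent_,
        n=est.shape_exponent_,
        E=None,
        r_squared=est.r_squared_,
        residual_norm=est.residual_norm_,
        n_points=est.n_points_,
        converged=est.converged_,
    )


def fit_classic(curve: ForceCurve, geom: IndenterGeometry, nu: float = 0.5) -> FitResult:
    """One-parameter modulus fit of the piecewise exact model ("Fit 1")."""
    est = ClassicModulusFit(geometry=geom, poisson=nu).fit(curve.h, curve.F)
    return FitResult(
        method="classic_blunt",
        c=float("nan"),
        m=float("nan"),
        n=float("nan"),
        E=est.young_modulus_,
        r_squared=est.r_squared_,
        residual_norm=est.residual_norm_,
        n_points=est.n_points_,
        converged=est.converged_,
    )


def estimate_modulus(
    curve: ForceCurve,
    geom: IndenterGeometry,
    nu: float = 0.5,
    method: str = "auto",
) -> FitResult:
    """Full pipeline: fit the curve and recover E by the requested method."""
    est = ModulusEstimator(geometry=geom, poisson=nu, method=method).fit(curve.h, curve.F)
    return FitResult(
        method=est.method_,
        c=est.prefactor_,
        m=est.exponent_,
        n=est.shape_exponent_,
        E=est.young_modulus_,
        r_squared=est.r_squared_,
        residual_norm=float("nan"),
        n_points=est.n_points_,
        converged=True,
    )
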