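"""scikit-learn style estimators for force-curve fitting.

Two fit routes are provided, mirroring common AFM practice:

* :class:`ClassicModulusFit` ("Fit 1") -- one-parameter least squares of the
  piecewise exact contact model (Hertz below the transition depth, blunted
  cone/pyramid above).  Because force is linear in the reduced modulus, the
  solution is a closed-form projection -- exact to machine precision on
  noiseless model data.
* :class:`PowerLawForceFit` ("Fit 2") -- unweighted nonlinear least squares of
  the empirical power law ``F = c h**m``, initialised from a log-log ordinary
  regression.  Combined with the simplified blunted-tip prefactor it yields
  the modulus without any root solving (:class:`ModulusEstimator`).

Estimators follow the sklearn contract: hyperparameters in ``__init__``,
``fit(X, y)`` with ``X`` a column of indentation depths (meters) and ``y``
forces (newtons), fitted attributes with trailing underscores, and
``predict`` for the fitted force law.  They compose with sklearn pipelines
and model selection.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from . import simplified
from .contact import force_from_depth, large_depth_contact_radius
from .geometry import IndenterGeometry, Material, TipFamily
from .simplified import modulus_from_powerlaw, shape_exponent

__all__ = [
    "FitConvergenceError",
    "PowerLawForceFit",
    "ClassicModulusFit",
    "ModulusEstimator",
    "select_method",
    "METHOD_LABELS",
]

MIN_POINTS = 5

#: canonical method labels of the selection flowchart
METHOD_LABELS = (
    "hertz",
    "sneddon_cone",
    "simplified_blunt",
    "large_depth",
    "classic_blunt",
)


class FitConvergenceError(RuntimeError):
    """The nonlinear least-squares fit failed to converge."""


def select_method(h_max: float, geom: IndenterGeometry) -> str:
    """Pick the recommended fit method from the depth-to-radius ratio.

    Decision thresholds (checked in this precedence order):

    * ``h_max / R < 0.1``  -> ``hertz`` (fixed m = 3/2; tip is effectively
      parabolic at such shallow depth),
    * ``h_max < 3 R``      -> ``simplified_blunt`` (free m, simplified
      prefactor; the validated shallow-depth regime),
    * ``h_max / R > 10``   -> ``sneddon_cone`` (fixed m = 2; apex radius
      negligible),
    * otherwise            -> ``large_depth`` (3R < h_max <= 10R; deep-contact
      closed form).
    """
    if not h_max > 0:
        raise ValueError("h_max must be positive")
    if geom.R is None or not geom.R > 0:
        raise ValueError("method selection requires a tip radius R")
    ratio = h_max / geom.R
    if ratio < 0.1:
        return "hertz"
    if ratio < 3.0:
        return "simplified_blunt"
    if ratio > 10.0:
        return "sneddon_cone"
    return "large_depth"


def _column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1-D array or a single-column 2-D array of depths")
    return X


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


class PowerLawForceFit(RegressorMixin, BaseEstimator):
    """Unweighted least-squares fit of the power law F = c h**m.

    Parameters
    ----------
    min_points : int, default 5
        Minimum number of samples accepted by :meth:`fit`.
    xtol : float, default 1e-12
        Relative parameter-change convergence tolerance passed to the
        Levenberg-Marquardt solver.

    Attributes
    ----------
    prefactor_ : float
        Fitted c (N / m**m on force data; called A when the data are F/E*).
    exponent_ : float
        Fitted m.
    shape_exponent_ : float or nan
        n = 1/(m - 1); nan when m is degenerate (m <= 1 + eps).
    r_squared_ : float
        1 - SS_res/SS_tot on the untransformed data.
    residual_norm_ : float
        Euclidean norm of the force residuals (newtons).
    n_points_ : int
    converged_ : bool
    """

    def __init__(self, min_points: int = MIN_POINTS, xtol: float = 1e-12):
        self.min_points = min_points
        self.xtol = xtol

    def fit(self, X, y):
        h = _column(X)
        F = np.asarray(y, dtype=float)
        if F.shape != h.shape:
            raise ValueError("X and y must have matching lengths")
        if h.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} points, got {h.size}")
        if np.any(h <= 0):
            raise ValueError("power-law fit requires strictly positive depths "
                             "(baseline-corrected curve, contact point at origin)")
        # noise may push individual forces below zero near the contact point;
        # only the log-log initialisation needs positive values
        pos = F > 0
        if pos.sum() < max(2, h.size // 4):
            raise ValueError("too few positive-force points: curve does not look "
                             "baseline-corrected")
        slope, intercept = np.polyfit(np.log(h[pos]), np.log(F[pos]), 1)
        p0 = (math.exp(intercept), slope)
        try:
            popt, _ = curve_fit(
                lambda hh, c, m: c * hh**m,
                h, F, p0=p0, method="lm",
                xtol=self.xtol, ftol=self.xtol, maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(f"power-law fit did not converge: {exc}") from exc
        self.prefactor_, self.exponent_ = float(popt[0]), float(popt[1])
        try:
            self.shape_exponent_ = shape_exponent(self.exponent_)
        except simplified.DegenerateExponentError:
            self.shape_exponent_ = float("nan")
        F_hat = self.prefactor_ * h**self.exponent_
        self.r_squared_ = _r_squared(F, F_hat)
        self.residual_norm_ = float(np.linalg.norm(F - F_hat))
        self.n_points_ = int(h.size)
        self.converged_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        h = _column(X)
        return self.prefactor_ * h**self.exponent_


class ClassicModulusFit(RegressorMixin, BaseEstimator):
    """One-parameter modulus fit of the piecewise exact contact model.

    The model force is linear in the reduced modulus E*, so the least-squares
    solution is the projection

        E*_hat = sum(F_i g_i) / sum(g_i**2),

    where ``g_i`` is the exact model force at unit reduced modulus.  On
    noiseless self-generated data this recovers the generating modulus to
    machine precision.

    Parameters
    ----------
    geometry : IndenterGeometry
    poisson : float, default 0.5

    Attributes
    ----------
    young_modulus_ : float   E in pascals
    r_squared_ : float
    residual_norm_ : float
    n_points_ : int
    """

    def __init__(self, geometry: IndenterGeometry = None, poisson: float = 0.5):
        self.geometry = geometry
        self.poisson = poisson

    def fit(self, X, y):
        if self.geometry is None:
            raise ValueError("ClassicModulusFit requires a geometry")
        h = _column(X)
        F = np.asarray(y, dtype=float)
        if F.shape != h.shape:
            raise ValueError("X and y must have matching lengths")
        if h.size < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points, got {h.size}")
        if np.any(h < 0):
            raise ValueError("negative depths: curve is not baseline-corrected")
        geom = self.geometry
        if geom.family is TipFamily.SPHERE and float(np.max(h)) >= geom.R:
            warnings.warn("h_max >= R: outside the Hertzian validity of a spherical tip",
                          stacklevel=2)
        unit = Material.from_reduced(1.0, nu=0.0)
        g = np.asarray(force_from_depth(h, geom, unit), dtype=float)
        denom = float(np.sum(g * g))
        if denom == 0.0:
            raise ValueError("degenerate curve: model force identically zero")
        E_star = float(np.sum(F * g)) / denom
        if not E_star > 0:
            raise ValueError("non-positive fitted modulus")
        self.reduced_modulus_ = E_star
        self.young_modulus_ = E_star * (1.0 - self.poisson**2)
        F_hat = E_star * g
        self.r_squared_ = _r_squared(F, F_hat)
        self.residual_norm_ = float(np.linalg.norm(F - F_hat))
        self.n_points_ = int(h.size)
        self.converged_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        h = _column(X)
        unit = Material.from_reduced(1.0, nu=0.0)
        return self.reduced_modulus_ * np.asarray(force_from_depth(h, self.geometry, unit))


class ModulusEstimator(RegressorMixin, BaseEstimator):
    """Front-end estimator implementing the method-selection flowchart.

    ``method='auto'`` dispatches on ``h_max / R`` (see :func:`select_method`);
    explicit methods force a route:

    * ``hertz``            fixed m = 3/2, c -> E via the Hertz prefactor
    * ``sneddon_cone``     fixed m = 2,   c -> E via the cone prefactor
    * ``simplified_blunt`` free (c, m) -> E via the simplified prefactor
    * ``large_depth``      free (c, m) -> E via the deep-contact stiffness
      identity E* = m c h_max**(m-1) / (2 r_c(h_max))
    * ``classic_blunt``    delegate to :class:`ClassicModulusFit`

    Attributes
    ----------
    young_modulus_ : float   E in pascals
    method_ : str            the route actually used
    prefactor_, exponent_, shape_exponent_, r_squared_ : floats
    """

    def __init__(
        self,
        geometry: IndenterGeometry = None,
        poisson: float = 0.5,
        method: str = "auto",
    ):
        self.geometry = geometry
        self.poisson = poisson
        self.method = method

    def _fit_fixed_exponent(self, h, F, m, c_unit):
        """LS prefactor at fixed exponent; E* from the known unit prefactor."""
        basis = h**m
        c = float(np.sum(F * basis)) / float(np.sum(basis**2))
        self.prefactor_, self.exponent_ = c, float(m)
        self.r_squared_ = _r_squared(F, c * basis)
        return c / c_unit

    def fit(self, X, y):
        if self.geometry is None:
            raise ValueError("ModulusEstimator requires a geometry")
        geom = self.geometry
        h = _column(X)
        F = np.asarray(y, dtype=float)
        method = self.method
        if method == "auto":
            method = select_method(float(np.max(h)), geom)
        if method not in METHOD_LABELS:
            raise ValueError(f"unknown method {method!r}; choose from {METHOD_LABELS}")
        nu = self.poisson
        one = Material.from_reduced(1.0, nu=0.0)

        if method == "classic_blunt":
            sub = ClassicModulusFit(geometry=geom, poisson=nu).fit(h, F)
            E_star = sub.reduced_modulus_
            self.prefactor_ = self.exponent_ = self.shape_exponent_ = float("nan")
            self.r_squared_ = sub.r_squared_
        elif method == "hertz":
            E_star = self._fit_fixed_exponent(
                h, F, 1.5, (4.0 / 3.0) * math.sqrt(geom.R)
            )
            self.shape_exponent_ = 2.0
        elif method == "sneddon_cone":
            E_star = self._fit_fixed_exponent(
                h, F, 2.0, (2.0 / math.pi) * math.tan(geom.theta)
            )
            self.shape_exponent_ = 1.0
        else:
            power = PowerLawForceFit().fit(h, F)
            self.prefactor_ = power.prefactor_
            self.exponent_ = power.exponent_
            self.shape_exponent_ = power.shape_exponent_
            self.r_squared_ = power.r_squared_
            if method == "simplified_blunt":
                est = modulus_from_powerlaw(
                    power.prefactor_, power.exponent_, geom, nu=nu,
                    r_squared=power.r_squared_, h_max=float(np.max(h)),
                )
                E_star = est.E / (1.0 - nu**2)
            else:  # large_depth
                h_max = float(np.max(h))
                rc = large_depth_contact_radius(h_max, geom)
                S = power.exponent_ * power.prefactor_ * h_max ** (power.exponent_ - 1.0)
                E_star = S / (2.0 * rc)
        if not E_star > 0:
            raise ValueError("non-positive fitted modulus")
        self.reduced_modulus_ = float(E_star)
        self.young_modulus_ = float(E_star * (1.0 - nu**2))
        self.method_ = method
        self.n_points_ = int(h.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        h = _column(X)
        if self.method_ == "classic_blunt":
            unit = Material.from_reduced(1.0, nu=0.0)
            return self.reduced_modulus_ * np.asarray(
                force_from_depth(h, self.geometry, unit)
            )
        return self.prefactor_ * h**self.exponent_
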