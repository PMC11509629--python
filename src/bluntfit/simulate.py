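"""Synthetic force-curve generator.

Emulates the simulation protocol used to validate the estimators: an elastic
half-space of Young's modulus E = 20 kPa and Poisson's ratio 0.5, indented by
sphero-conical or blunted-pyramidal tips (R = 0.1-0.2 um, theta = 35 deg)
mounted on a 0.1 N/m cantilever, with i.i.d. zero-mean Gaussian noise added
to the force channel.  The noise magnitude defaults to 2% of each curve's
maximum force, which reproduces the published scatter of recovered moduli
(SD of a few hundred Pa at E = 20 kPa over 30 replicates); it is
configurable, including an equivalent deflection-space mode.

Everything is deterministic under a fixed seed: the same config produces
byte-identical curves (and files).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contact import generate_exact_curve
from .curves import ForceCurve, write_curve
from .geometry import IndenterGeometry, Material, TipFamily

__all__ = ["SimulationConfig", "simulate_curves", "make_fixture_suite"]

#: cantilever spring constant of the emulated protocol, N/m
DEFAULT_SPRING_CONSTANT = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one batch of synthetic curves.

    ``noise_sigma`` is interpreted according to ``noise_mode``:

    * ``"fraction"`` (default): fraction of the curve's maximum force,
    * ``"absolute"``: newtons,
    * ``"deflection"``: meters of cantilever deflection; converted to force
      noise through ``spring_constant`` (mathematically equivalent to
      absolute force noise of ``spring_constant * noise_sigma``).
    """

    geom: IndenterGeometry
    E: float = 20e3
    nu: float = 0.5
    h_max: float = 300e-9
    n_points: int = 200
    noise_sigma: float = 0.02
    noise_mode: str = "fraction"
    spring_constant: float = DEFAULT_SPRING_CONSTANT
    seed: int = 0
    n_curves: int = 1

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_mode not in ("fraction", "absolute", "deflection"):
            raise ValueError("noise_mode must be fraction, absolute or deflection")
        if self.h_max <= 0 or self.n_points < 2 or self.n_curves < 1:
            raise ValueError("invalid simulation domain")


def _noise_sd_newtons(cfg: SimulationConfig, F: np.ndarray) -> float:
    if cfg.noise_mode == "fraction":
        return cfg.noise_sigma * float(np.max(F))
    if cfg.noise_mode == "deflection":
        return cfg.spring_constant * cfg.noise_sigma
    return cfg.noise_sigma


def simulate_curves(cfg: SimulationConfig) -> list[ForceCurve]:
    """Generate ``cfg.n_curves`` noisy curves from the exact forward model.

    The depth grid is uniform on ``[h_max/n_points, h_max]`` (the zero-depth
    point is excluded so log-log fit initialisation stays defined).  Noise is
    i.i.d. Gaussian on force, independent between curves, drawn from a
    generator seeded with ``cfg.seed``.
    """
    mat = Material(E=cfg.E, nu=cfg.nu)
    base = generate_exact_curve(
        cfg.geom, mat,
        h_range=(cfg.h_max / cfg.n_points, cfg.h_max),
        n_points=cfg.n_points,
    )
    sd = _noise_sd_newtons(cfg, base.F)
    rng = np.random.default_rng(cfg.seed)
    curves = []
    for i in range(cfg.n_curves):
        F = base.F + rng.normal(0.0, sd, size=base.F.shape) if sd > 0 else base.F.copy()
        meta = dict(base.metadata)
        meta.update(
            noise_sigma_N=sd,
            noise_mode=cfg.noise_mode,
            spring_constant_N_per_m=cfg.spring_constant,
            seed=cfg.seed,
            replicate=i,
        )
        curves.append(ForceCurve(h=base.h.copy(), F=F, metadata=meta))
    return curves


# ---------------------------------------------------------------------------
# standard fixture suite

_MLCT_25_20 = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=20e-9, theta_deg=25.0)
_MLCT_25_50 = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=50e-9, theta_deg=25.0)
_MLCT_35_20 = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=20e-9, theta_deg=35.0)
_MLCT_35_50 = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=50e-9, theta_deg=35.0)
_SIM_CONE = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=200e-9, theta_deg=35.0)
_SIM_PYR = IndenterGeometry(TipFamily.BLUNTED_PYRAMID, R=200e-9, theta_deg=35.0, k=4)

#: damaged-tip reference: near-linear power law from a worn/contaminated apex
DAMAGED_TIP_C = 0.0367  # N * m**-1.295
DAMAGED_TIP_M = 1.295


def _exact_blunted_segment(geom, amax_over_b, n_points=200):
    """Noiseless reduced-force (E* = 1 Pa) curve over b <= a <= amax_over_b*b."""
    b = geom.b
    return generate_exact_curve(
        geom, Material.from_reduced(1.0, nu=0.0),
        a_range=(b, amax_over_b * b), n_points=n_points,
    )


def make_fixture_suite(outdir, seed: int = 0) -> dict:
    """Write the standard test-fixture curve set; returns (and saves) a manifest.

    The suite contains four noiseless reduced-modulus curves on blunted
    segments (the validation geometries), four noisy single curves at
    E = 20 kPa, two 30-curve batches (sphero-conical and 4-sided pyramid) and
    one damaged-tip-like near-linear curve.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    def record(name, curve, params):
        write_curve(outdir / name, curve)
        manifest["files"][name] = params

    # noiseless blunted-segment curves at unit reduced modulus
    for name, geom, span in [
        ("exact_25deg_R20nm.txt", _MLCT_25_20, 1.25),
        ("exact_25deg_R50nm.txt", _MLCT_25_50, 1.25),
        ("exact_35deg_R20nm.txt", _MLCT_35_20, 1.5),
        ("exact_35deg_R50nm.txt", _MLCT_35_50, 1.5),
    ]:
        curve = _exact_blunted_segment(geom, span)
        record(name, curve, {
            "kind": "exact_segment", "R_m": geom.R,
            "theta_deg": math.degrees(geom.theta), "a_max_over_b": span,
        })

    # noisy single curves, E = 20 kPa
    for i, (R, h_max) in enumerate([(100e-9, 100e-9), (100e-9, 200e-9),
                                    (200e-9, 200e-9), (200e-9, 300e-9)]):
        geom = IndenterGeometry(TipFamily.SPHERO_CONICAL, R=R, theta_deg=35.0)
        cfg = SimulationConfig(geom=geom, h_max=h_max, seed=seed + 10 + i)
        curve = simulate_curves(cfg)[0]
        record(f"noisy_R{int(R*1e9)}nm_h{int(h_max*1e9)}nm.txt", curve, {
            "kind": "noisy", "R_m": R, "theta_deg": 35.0, "h_max_m": h_max,
            "E_Pa": cfg.E, "nu": cfg.nu, "noise_sigma": cfg.noise_sigma,
            "seed": cfg.seed,
        })

    # 30-curve batches
    for label, geom in [("cone", _SIM_CONE), ("pyramid_k4", _SIM_PYR)]:
        cfg = SimulationConfig(geom=geom, n_curves=30,
                               seed=seed + (100 if label == "cone" else 200))
        for i, curve in enumerate(simulate_curves(cfg)):
            record(f"batch_{label}_{i:02d}.txt", curve, {
                "kind": "batch", "batch": label, "replicate": i,
                "R_m": geom.R, "theta_deg": 35.0, "k": geom.k,
                "E_Pa": cfg.E, "nu": cfg.nu, "h_max_m": cfg.h_max,
                "noise_sigma": cfg.noise_sigma, "seed": cfg.seed,
            })

    # damaged-tip-like curve: F = c h**m with m ~ 1.295, mild noise
    rng = np.random.default_rng(seed + 999)
    h = np.linspace(1000e-9 / 200, 1000e-9, 200)
    F = DAMAGED_TIP_C * h**DAMAGED_TIP_M
    F = F + rng.normal(0.0, 0.005 * F.max(), size=F.shape)
    curve = ForceCurve(h=h, F=F, metadata={
        "kind": "synthetic_damaged_tip", "c_SI": DAMAGED_TIP_C, "m": DAMAGED_TIP_M,
        "seed": seed + 999,
    })
    record("damaged_tip.txt", curve, {
        "kind": "damaged_tip", "c_SI": DAMAGED_TIP_C, "m": DAMAGED_TIP_M,
        "seed": seed + 999,
    })

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
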