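"""Inverse problems: terminal TI fitting and distribution-shape estimation.

Two estimation tasks close the modeling loop:

1. :func:`fit_terminal_ti` recovers the deviatoric TI parameters of a
   "pure" tissue from a uniaxial force--displacement curve, with the
   bulk modulus held fixed (soft tissue is nearly incompressible and
   uniaxial data carry no volumetric information).
2. :func:`estimate_shape_parameters` recovers the two shape parameters
   of the constrained asymmetric sigmoid that grades a transition, by
   matching the normalized axial strain profile of the graded chain at
   the largest applied stretch to a measured (molecular-strain) profile.

Both use a seeded differential-evolution global search followed by a
Nelder--Mead polish; all randomness is controlled by explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .chain_sim import ChainGeometry, chain_equilibrium, fiducial_strains, uniaxial_response
from .distributions import DistSpec, solve_asymmetric
from .fgm_grading import TerminalFit, generate_fgm
from .ti_core import TIParams

__all__ = [
    "FDCurve",
    "StrainProfile",
    "FitReport",
    "ShapeEstimate",
    "fit_terminal_ti",
    "estimate_shape_parameters",
    "DEFAULT_BULK_MODULUS",
]

DEFAULT_BULK_MODULUS = 1.464e8  # Pa, fixed in all terminal fits


@dataclass(frozen=True)
class FDCurve:
    """A uniaxial force--displacement record.

    ``displacements`` (mm, strictly increasing from 0) and ``forces``
    (N, zero at zero displacement), with the reference gauge length
    (mm) and cross-section area (mm^2) that convert them to stretch and
    nominal stress.
    """

    displacements: np.ndarray
    forces: np.ndarray
    gauge_length: float
    area: float

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacements and forces must be equal-length vectors")
        if d[0] != 0.0 or f[0] != 0.0:
            raise ValueError("curve must start at zero displacement and zero force")
        if np.any(np.diff(d) <= 0):
            raise ValueError("displacements must be strictly increasing")
        if self.gauge_length <= 0 or self.area <= 0:
            raise ValueError("gauge length and area must be positive")
        object.__setattr__(self, "displacements", d)
        object.__setattr__(self, "forces", f)

    @property
    def stretches(self) -> np.ndarray:
        return 1.0 + self.displacements / self.gauge_length

    def predicted_forces(self, p: TIParams) -> np.ndarray:
        """Forward model: nominal stress x reference area (N, with
        stress in Pa, area in mm^2, forces scaled consistently)."""
        return np.array(
            [uniaxial_response(p, s) * self.area * 1e-6 for s in self.stretches]
        )


@dataclass(frozen=True)
class StrainProfile:
    """Normalized strain at fiducial points over a sweep of load steps.

    ``strains`` has shape (n_fiducials, n_steps); values are normalized
    so the largest entry of the final (maximum-load) column is 1.
    """

    fiducials: np.ndarray
    load_steps: np.ndarray      # applied engineering strains per step
    strains: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fiducials, dtype=float)
        s = np.asarray(self.load_steps, dtype=float)
        e = np.asarray(self.strains, dtype=float)
        if e.shape != (len(f), len(s)):
            raise ValueError("strain matrix must be (n_fiducials, n_steps)")
        if np.any(e < -1e-12) or np.any(e > 1.0 + 1e-12):
            raise ValueError("normalized strains must lie in [0, 1]")
        if abs(e[:, -1].max() - 1.0) > 1e-9:
            raise ValueError("profile must be normalized: max strain at top step = 1")
        object.__setattr__(self, "fiducials", f)
        object.__setattr__(self, "load_steps", s)
        object.__setattr__(self, "strains", e)


@dataclass
class FitReport:
    fit: TerminalFit
    r_squared: float
    max_rel_force_error: float
    residual: float


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


DEFAULT_TI_BOUNDS = {
    "C1": (1e1, 1e8),
    "C3": (1e0, 1e6),
    "C4": (1.0, 100.0),
    "lambda_star": (1.001, 1.4),
    "C5": (1e3, 1e9),
}


def fit_terminal_ti(
    curve: FDCurve,
    K: float = DEFAULT_BULK_MODULUS,
    C2: float = 0.0,
    bounds: dict | None = None,
    seed: int = 0,
    maxiter: int = 200,
    popsize: int = 20,
) -> FitReport:
    """Fit ``{C1, C3, C4, lambda_star, C5}`` to a force--displacement
    curve (C6 from C0 continuity; K and C2 held fixed).

    Squared force residuals, normalized by the peak force, are
    minimized by seeded differential evolution over log-scaled
    stiffness coefficients, then polished by Nelder--Mead.  Parameter
    identifiability is limited (C3 and C4 trade off on toe-region
    data), so the fit is judged in response space: the report carries
    R^2 and the maximum force error relative to the peak force.
    """
    if len(curve.forces) <= 3:
        raise ValueError("need more than 3 points to fit the TI model")
    b = dict(DEFAULT_TI_BOUNDS)
    if bounds:
        b.update(bounds)
    f_obs = curve.forces
    f_scale = float(np.max(np.abs(f_obs)))
    if f_scale <= 0:
        raise ValueError("curve carries no load")

    def unpack(x) -> TIParams:
        c1, c3, c5 = 10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[4]
        return TIParams.from_fit(c1, C2, c3, x[2], c5, x[3], K)

    def objective(x) -> float:
        try:
            pred = curve.predicted_forces(unpack(x))
        except (ValueError, OverflowError):
            return 1e12
        r = (pred - f_obs) / f_scale
        return float(r @ r)

    de_bounds = [
        (math.log10(b["C1"][0]), math.log10(b["C1"][1])),
        (math.log10(b["C3"][0]), math.log10(b["C3"][1])),
        b["C4"],
        b["lambda_star"],
        (math.log10(b["C5"][0]), math.log10(b["C5"][1])),
    ]
    result = differential_evolution(
        objective, de_bounds, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=1e-12, polish=False, init="sobol",
    )
    polish = minimize(
        objective, result.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000},
    )
    x = polish.x if polish.fun <= result.fun else result.x
    params = unpack(x)
    pred = curve.predicted_forces(params)
    lam_max = float(curve.stretches.max())
    return FitReport(
        fit=TerminalFit(params=params, lambda_max=lam_max),
        r_squared=_r_squared(f_obs, pred),
        max_rel_force_error=float(np.max(np.abs(pred - f_obs)) / f_scale),
        residual=float(min(polish.fun, result.fun)),
    )


@dataclass
class ShapeEstimate:
    p: tuple[float, float]
    residual: float
    spec: DistSpec
    identifiable: bool = True
    message: str = ""


def _forward_profile_top_step(
    p: Sequence[float],
    geom: ChainGeometry,
    terminals: tuple[TerminalFit, TerminalFit],
    max_strain: float,
) -> np.ndarray:
    """Normalized fiducial strain profile at the maximum load step for a
    candidate shape-parameter pair."""
    spec = DistSpec("asymmetric_sigmoid", tuple(p), (0.0, geom.total_length))
    edges = np.concatenate([[0.0], np.cumsum(geom.layer_lengths)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    coords = centers.copy()
    coords[0], coords[-1] = 0.0, geom.total_length  # terminal layers anchor phi at 0/1
    stack = generate_fgm(terminals[0], terminals[1], geom.n_layers, spec, coords=coords)
    state = chain_equilibrium(geom, stack, 1.0 + max_strain)
    return fiducial_strains(state, geom, normalize=True)


def estimate_shape_parameters(
    profile_exp: StrainProfile,
    geom: ChainGeometry,
    terminals: tuple[TerminalFit, TerminalFit],
    bounds: Sequence[tuple[float, float]] = ((-0.45, 0.45), (0.1, 5.0)),
    seed: int = 0,
    maxiter: int = 60,
    popsize: int = 12,
) -> ShapeEstimate:
    """Estimate the asymmetric-sigmoid shape parameters ``(p1, p2)``
    from a normalized experimental strain profile.

    For each candidate p the forward pipeline runs: solve the sigmoid
    smoothness system, grade the terminals across the chain layers,
    solve the chain equilibrium at the maximum load step, normalize the
    fiducial strains, and score the squared residual against the
    measured profile.  Only the top load step enters the objective —
    there the fibers are extending and molecular strain tracks
    macroscopic strain linearly, so the normalized profiles are
    comparable.  Infeasible candidates are penalized, not fatal.
    """
    target = profile_exp.strains[:, -1]
    max_strain = float(profile_exp.load_steps[-1])

    n_fail = 0

    def objective(x) -> float:
        nonlocal n_fail
        try:
            sim = _forward_profile_top_step(x, geom, terminals, max_strain)
        except (ValueError, RuntimeError):
            n_fail += 1
            return 1e6
        r = sim - target
        return float(r @ r)

    result = differential_evolution(
        objective, list(bounds), seed=seed, maxiter=maxiter, popsize=popsize,
        tol=1e-14, polish=False, init="latinhypercube",
    )
    polish = minimize(
        objective, result.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-16, "maxiter": 2000},
    )
    x, fun = (polish.x, polish.fun) if polish.fun <= result.fun else (result.x, result.fun)
    if fun >= 1e6:
        raise RuntimeError("all candidate shape parameters were infeasible")

    # identifiability probe: a flat objective (homogeneous chain) cannot
    # pin down the shape parameters
    probes = [objective(np.clip(x + d, [b[0] for b in bounds], [b[1] for b in bounds]))
              for d in ((0.1, 0.0), (-0.1, 0.0), (0.0, 0.3), (0.0, -0.3))]
    spread = max(probes) - fun
    identifiable = bool(spread > 1e-10)
    spec = DistSpec("asymmetric_sigmoid", (float(x[0]), float(x[1])),
                    (0.0, geom.total_length))
    return ShapeEstimate(
        p=(float(x[0]), float(x[1])),
        residual=float(fun),
        spec=spec,
        identifiable=identifiable,
        message="" if identifiable else
        "objective locally flat in p: profile carries no grading signal",
    )
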