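"""Functionally graded interpolation of TI parameters across a transition.

Given terminal (pure-tissue) TI fits on either side of a transition
region, a constituent distribution function phi and a monotone
interpolant psi, this module builds a stack of per-layer TI parameter
sets whose grading stiffness follows phi in the large-stretch regime.

The linear parameters C1, C2, C3, C5 (and K) blend linearly under phi;
the critical stretch lambda* and the discontinuity index f blend under
psi; each layer's toe exponent C4 is then recovered as the unique
positive root of

    g(C4) = f C3 C4 exp(C4 (lambda* - 1)) - C5 = 0

and C6 follows from C0 continuity.  Terminal fits whose experiment
never reached the linear fiber regime (lambda_max < lambda*) carry an
ill-determined C5, which is replaced by the slope-continuity value
before grading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .ti_core import (
    TIParams,
    c1_continuity_C5,
    c6_from_c0,
    discontinuity_index,
    grading_stiffness,
)

__all__ = [
    "TerminalFit",
    "GradedStack",
    "interpolate_scalar",
    "solve_C4",
    "generate_fgm",
    "grading_stiffness_profile",
    "case_study",
    "fiber_slope_jump",
]


@dataclass(frozen=True)
class TerminalFit:
    """A terminal ("pure" tissue) TI fit plus fitting metadata.

    ``lambda_max`` is the largest deviatoric fiber stretch reached in
    the underlying experiment; when it falls short of ``lambda_star``
    the fitted ``C5`` never influenced the fit and is recomputed from
    slope continuity before grading.  ``is_isotropic`` marks a terminal
    with no fiber contribution (C3 = C5 = 0), for which f and lambda*
    are conventionally 1.
    """

    params: TIParams
    lambda_max: float = math.inf
    is_isotropic: bool = False

    def __post_init__(self) -> None:
        if self.lambda_max < 1:
            raise ValueError("lambda_max must be >= 1")
        if self.is_isotropic and (self.params.C3 != 0 or self.params.C5 != 0):
            raise ValueError("isotropic terminal requires C3 = C5 = 0")


@dataclass
class GradedStack:
    """Ordered transition layers t = 1..T with interpolated TI parameters."""

    coords: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    layers: list[TIParams]
    f: np.ndarray

    @property
    def T(self) -> int:
        return len(self.layers)

    def to_frame(self):
        """Flat per-layer table (pandas DataFrame)."""
        import pandas as pd

        c = np.atleast_2d(np.asarray(self.coords, dtype=float).T).T
        rows = []
        for t, p in enumerate(self.layers):
            row = {"t": t + 1}
            for j in range(c.shape[1]):
                row[f"X{j + 1}"] = c[t, j]
            row.update(
                phi=self.phi[t], psi=self.psi[t],
                C1=p.C1, C2=p.C2, C3=p.C3, C4=p.C4, C5=p.C5, C6=p.C6,
                lambda_star=p.lambda_star, K=p.K, f=self.f[t],
            )
            rows.append(row)
        return pd.DataFrame(rows)


def interpolate_scalar(v1: float, vT: float, frac: float) -> float:
    """Linear blend ``v1 + (vT - v1) * frac`` with ``frac`` in [0, 1]."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction {frac} outside [0, 1]")
    return v1 + (vT - v1) * frac


def _g(C4: float, f_t: float, C3_t: float, lambda_star_t: float, C5_t: float) -> float:
    return f_t * C3_t * C4 * math.exp(C4 * (lambda_star_t - 1.0)) - C5_t


def solve_C4(
    f_t: float, C3_t: float, C5_t: float, lambda_star_t: float,
    rtol: float = 1e-12,
) -> float:
    """Unique positive root of ``g(C4) = f C3 C4 e^{C4 (lambda*-1)} - C5``.

    ``g`` is strictly increasing in C4 for lambda* >= 1, so a bracketing
    solve is safe; the bracket is expanded geometrically, solved by
    Brent bisection and polished by Newton.  Closed form
    ``C4 = C5 / (f C3)`` when lambda* = 1.
    """
    if f_t <= 0 or C3_t <= 0 or C5_t <= 0 or lambda_star_t < 1:
        raise ValueError(
            "solve_C4 requires f, C3, C5 > 0 and lambda_star >= 1 "
            f"(got f={f_t}, C3={C3_t}, C5={C5_t}, lambda_star={lambda_star_t})"
        )
    if lambda_star_t == 1.0:
        return C5_t / (f_t * C3_t)

    lo, hi = 1e-12, 1.0
    while _g(hi, f_t, C3_t, lambda_star_t, C5_t) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket the C4 root")
    c4 = brentq(_g, lo, hi, args=(f_t, C3_t, lambda_star_t, C5_t),
                xtol=1e-15, rtol=8.9e-16)
    # Newton polish
    for _ in range(3):
        e = math.exp(c4 * (lambda_star_t - 1.0))
        g = f_t * C3_t * c4 * e - C5_t
        dg = f_t * C3_t * e * (1.0 + c4 * (lambda_star_t - 1.0))
        step = g / dg
        c4 -= step
        if abs(step) <= rtol * abs(c4):
            break
    return c4


def _terminal_f_and_c5(
    term: TerminalFit,
) -> tuple[float, float, float]:
    """Resolve (f, C5, lambda_star) for one terminal per the interpolation law."""
    p = term.params
    if term.is_isotropic:
        return 1.0, 0.0, 1.0
    if term.lambda_max < p.lambda_star:
        # experiment never straightened the fibers: C5 ill-determined,
        # replace with the slope-continuity value (f = 1)
        return 1.0, c1_continuity_C5(p), p.lambda_star
    return discontinuity_index(p), p.C5, p.lambda_star


def _layer_params(
    c1: float, c2: float, c3: float, c5: float, ls: float, f: float, K: float,
    ratio_hint: float,
) -> tuple[TIParams, float]:
    """Assemble one layer: solve C4, derive C6."""
    if c3 > 0 and c5 > 0:
        c4 = solve_C4(f, c3, c5, ls)
    else:
        # isotropic endpoint layer: the root equation degenerates but its
        # phi -> 0 limit is well defined through the terminal C5/C3 ratio
        c4 = solve_C4(f, 1.0, ratio_hint, ls)
    p = TIParams(c1, c2, c3, c4, c5, 0.0, ls, K)
    return p.with_c0_continuity(), c4


def generate_fgm(
    term1: TerminalFit,
    termT: TerminalFit,
    T: int,
    phi_fn: Callable | Sequence[float],
    psi_fn: Callable | Sequence[float] | None = None,
    coords: np.ndarray | None = None,
) -> GradedStack:
    """Build a graded stack of T layers between two terminal fits.

    ``phi_fn``/``psi_fn`` are callables evaluated on ``coords`` (e.g. a
    :class:`~tigrade.distributions.DistSpec`) or explicit per-layer
    value sequences.  ``psi_fn=None`` means psi = phi (valid only when
    phi is monotone on the sampled coords).  ``coords`` defaults to T
    uniformly spaced points on [0, 1], ordered from the material-1 side
    to the material-T side.
    """
    if T < 2:
        raise ValueError("need at least the two terminal layers (T >= 2)")
    if coords is None:
        coords = np.linspace(0.0, 1.0, T)
    coords = np.asarray(coords, dtype=float)
    if len(coords) != T:
        raise ValueError("coords must supply one entry per layer")

    phi = np.asarray(phi_fn(coords) if callable(phi_fn) else phi_fn, dtype=float)
    if phi.shape != (T,):
        raise ValueError("phi must evaluate to one value per layer")
    if callable(phi_fn):
        # a distribution function must anchor the terminals at 0 and 1;
        # explicit per-layer fractions are taken at face value
        if abs(phi[0]) > 1e-9 or abs(phi[-1] - 1.0) > 1e-9:
            raise ValueError(
                f"distribution must satisfy phi = 0 and 1 at the terminals "
                f"(got {phi[0]:.3g}, {phi[-1]:.3g})"
            )
        phi = phi.copy()
        phi[0], phi[-1] = 0.0, 1.0
    elif np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("phi values must lie in [0, 1]")

    if psi_fn is None:
        psi = phi.copy()
    else:
        psi = np.asarray(psi_fn(coords) if callable(psi_fn) else psi_fn, dtype=float)
    if np.any(np.diff(psi) < -1e-12):
        raise ValueError("psi must be monotone non-decreasing on the layer coords")

    p1, pT = term1.params, termT.params
    f1, C5_1, ls1 = _terminal_f_and_c5(term1)
    fT, C5_T, lsT = _terminal_f_and_c5(termT)

    # isotropic-terminal convention: f and lambda* graded under phi
    lam_frac = phi if (term1.is_isotropic or termT.is_isotropic) else psi
    f_frac = lam_frac

    # phi -> 0 / 1 limit of the C4 root equation for degenerate endpoints
    if termT.is_isotropic:
        ratio = C5_1 / p1.C3 if p1.C3 > 0 else 1.0
    else:
        ratio = C5_T / pT.C3 if pT.C3 > 0 else 1.0

    layers: list[TIParams] = []
    f_vals = np.empty(T)
    for t in range(T):
        ph, ps = phi[t], f_frac[t]
        c1 = interpolate_scalar(p1.C1, pT.C1, ph)
        c2 = interpolate_scalar(p1.C2, pT.C2, ph)
        c3 = interpolate_scalar(p1.C3, pT.C3, ph)
        c5 = interpolate_scalar(C5_1, C5_T, ph)
        K = interpolate_scalar(p1.K, pT.K, ph)
        ls = interpolate_scalar(ls1, lsT, lam_frac[t])
        f_t = interpolate_scalar(f1, fT, ps)
        try:
            layer, _ = _layer_params(c1, c2, c3, c5, ls, f_t, K, ratio)
        except (ValueError, RuntimeError) as e:
            raise RuntimeError(f"layer {t + 1}/{T}: {e}") from e
        layers.append(layer)
        f_vals[t] = f_t

    return GradedStack(coords=coords, phi=phi, psi=psi, layers=layers, f=f_vals)


def grading_stiffness_profile(stack: GradedStack, lambda_t: float) -> np.ndarray:
    """Per-layer grading stiffness kg (Pa) at a common fiber stretch."""
    return np.array(
        [grading_stiffness(p, lambda_t, mode="analytic") for p in stack.layers]
    )


def fiber_slope_jump(p: TIParams) -> float:
    """Signed jump in the fiber-response slope at lambda*:
    exponential-side slope minus C5.  Zero under C1 continuity."""
    return p.C3 * p.C4 * math.exp(p.C4 * (p.lambda_star - 1.0)) - p.C5


def case_study(
    variant: int,
    term1: TerminalFit,
    termT: TerminalFit,
    T: int,
    phi_fn: Callable | Sequence[float],
    coords: np.ndarray | None = None,
) -> GradedStack:
    """The three unit-cell grading strategies compared in the transition
    study.

    1. All parameters except C5 blended individually under phi; C5 from
       slope continuity on the blended parameters (over-stiffens
       mid-transition layers).
    2. All seven parameters blended individually under phi (amplifies
       the slope discontinuity at lambda*).
    3. The full interpolation law (psi = phi), which keeps layer
       responses inside the terminal envelope.
    """
    if variant == 3:
        return generate_fgm(term1, termT, T, phi_fn, psi_fn=None, coords=coords)
    if variant not in (1, 2):
        raise ValueError("variant must be 1, 2 or 3")

    if coords is None:
        coords = np.linspace(0.0, 1.0, T)
    coords = np.asarray(coords, dtype=float)
    phi = np.asarray(phi_fn(coords) if callable(phi_fn) else phi_fn, dtype=float)
    p1, pT = term1.params, termT.params

    layers: list[TIParams] = []
    f_vals = np.empty(T)
    for t in range(T):
        ph = float(phi[t])
        c1 = interpolate_scalar(p1.C1, pT.C1, ph)
        c2 = interpolate_scalar(p1.C2, pT.C2, ph)
        c3 = interpolate_scalar(p1.C3, pT.C3, ph)
        c4 = interpolate_scalar(p1.C4, pT.C4, ph)
        ls = interpolate_scalar(p1.lambda_star, pT.lambda_star, ph)
        K = interpolate_scalar(p1.K, pT.K, ph)
        if variant == 1:
            probe = TIParams(c1, c2, c3, c4, 0.0, 0.0, ls, K)
            c5 = c1_continuity_C5(probe)
        else:
            c5 = interpolate_scalar(p1.C5, pT.C5, ph)
        layer = TIParams(c1, c2, c3, c4, c5, 0.0, ls, K).with_c0_continuity()
        layers.append(layer)
        f_vals[t] = discontinuity_index(layer)

    return GradedStack(coords=coords, phi=phi, psi=phi.copy(), layers=layers, f=f_vals)
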