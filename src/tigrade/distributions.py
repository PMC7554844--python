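"""Constituent distribution functions for functionally graded transitions.

A distribution function phi maps transition-region coordinates to a
constituent fraction in [0, 1] (0 = pure material 1, 1 = pure material
T) and drives the layer-wise blending of TI parameters.  Families:

``linear``
    Plain ramp in the normalized through-transition coordinate.
``symmetric_sigmoid``
    Piecewise power sigmoid, value 0.5 at the transition midpoint;
    exponents ``(p5, p6)`` control the steepness of each half.
``tanh_modified``
    Saturating tanh-like profile in the transverse coordinate X1,
    used where the constituent fraction also varies across the sample.
``bidirectional``
    Clamped product of ``tanh_modified(X1)`` and
    ``symmetric_sigmoid(X2)``.
``asymmetric_sigmoid``
    Two-piece generalization of the symmetric sigmoid whose crossover
    point ``p1`` may sit off-center; the remaining coefficients are
    solved from five smoothness constraints (endpoint anchoring at 0
    and 1, value 0.5 and matching first derivative at the crossover).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, root
from scipy.stats import qmc

__all__ = [
    "DistSpec",
    "AsymmetricShape",
    "normalize_coord",
    "symmetric_sigmoid",
    "tanh_modified",
    "bidirectional",
    "asymmetric_sigmoid",
    "solve_asymmetric",
    "fit_distribution",
    "FitResult",
]

FAMILIES = (
    "linear",
    "symmetric_sigmoid",
    "tanh_modified",
    "bidirectional",
    "asymmetric_sigmoid",
)


def normalize_coord(X2t, X2_1: float, X2_T: float):
    """Map a through-transition coordinate onto [-0.5, 0.5].

    ``(X2t - X2_1)/(X2_T - X2_1) - 1/2``, clamped to the interval.
    """
    if X2_T == X2_1:
        raise ValueError("degenerate span: X2_T must differ from X2_1")
    x = (np.asarray(X2t, dtype=float) - X2_1) / (X2_T - X2_1) - 0.5
    return np.clip(x, -0.5, 0.5)


def symmetric_sigmoid(xbar, p5: float, p6: float):
    """Symmetric piecewise-power sigmoid on the normalized coordinate.

    ``0.5 (1 + 2 xbar)^p5`` on [-0.5, 0] and ``1 - 0.5 (1 - 2 xbar)^p6``
    on [0, 0.5]; equals 0.5 at the midpoint for any exponents.
    """
    if p5 <= 0 or p6 <= 0:
        raise ValueError("sigmoid exponents must be positive")
    xbar = np.asarray(xbar, dtype=float)
    lo = 0.5 * np.power(np.clip(1.0 + 2.0 * xbar, 0.0, None), p5)
    hi = 1.0 - 0.5 * np.power(np.clip(1.0 - 2.0 * xbar, 0.0, None), p6)
    out = np.where(xbar <= 0.0, lo, hi)
    return out if out.ndim else float(out)


def tanh_modified(X1t, p1: float, p2: float, p3: float, p4: float):
    """Modified tanh profile ``p1 (e^u - e^-u) / (e^u - e^-u + p4)`` with
    ``u = p2 (X1 - p3)``.

    Saturates to ``p1`` for large X1 and vanishes at ``X1 = p3``.
    Computed in overflow-safe shifted form; the output is *not* clamped
    here (clamping belongs to the bidirectional wrapper).
    """
    if p2 <= 0 or p4 <= 0:
        raise ValueError("p2 and p4 must be positive")
    u = p2 * (np.asarray(X1t, dtype=float) - p3)
    # divide through by e^{|u|} so neither exponential can overflow:
    #   u >= 0: (1 - e^{-2u}) / (1 - e^{-2u} + p4 e^{-u})
    #   u <  0: (e^{2u} - 1) / (e^{2u} - 1 + p4 e^{u})
    with np.errstate(invalid="ignore"):
        pos = u >= 0
        e1 = np.exp(-np.abs(u))
        e2 = e1 * e1
        num = np.where(pos, 1.0 - e2, e2 - 1.0)
        den = num + p4 * e1
    if np.any(np.abs(den) < 1e-12):
        raise ZeroDivisionError("tanh_modified denominator within 1e-12 of zero")
    out = p1 * num / den
    return out if out.ndim else float(out)


def bidirectional(X1t, X2t, p: Sequence[float], domain: tuple[float, float]):
    """Clamped product ``clip(tanh_modified(X1) * symmetric_sigmoid(X2bar), 0, 1)``.

    ``p = (p1, p2, p3, p4, p5, p6)``; ``domain`` holds the X2 span used
    for coordinate normalization.  The clamp is applied after the
    product, so either factor may individually exceed [0, 1].
    """
    p1, p2, p3, p4, p5, p6 = p
    xbar = normalize_coord(X2t, *domain)
    prod = tanh_modified(X1t, p1, p2, p3, p4) * symmetric_sigmoid(xbar, p5, p6)
    out = np.clip(prod, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# asymmetric sigmoid (crossover off-center), five smoothness constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsymmetricShape:
    """Solved coefficients of the two-piece asymmetric sigmoid.

    Lower branch ``phi11 + phi12 (1 + 2 xbar)^w`` on [-0.5, p1], upper
    branch ``phi21 + phi22 (1 - 2 xbar)^p2`` on [p1, 0.5].
    """

    p1: float
    p2: float
    w: float
    phi11: float
    phi12: float
    phi21: float
    phi22: float

    def __call__(self, xbar):
        xbar = np.asarray(xbar, dtype=float)
        lo = self.phi11 + self.phi12 * np.power(
            np.clip(1.0 + 2.0 * xbar, 0.0, None), self.w
        )
        hi = self.phi21 + self.phi22 * np.power(
            np.clip(1.0 - 2.0 * xbar, 0.0, None), self.p2
        )
        out = np.where(xbar <= self.p1, lo, hi)
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def residuals(self) -> np.ndarray:
        """The five smoothness constraints evaluated at the solution."""
        return _asym_residuals(
            np.array([self.w, self.phi11, self.phi12, self.phi21, self.phi22]),
            self.p1,
            self.p2,
        )


def _asym_residuals(u: np.ndarray, p1: float, p2: float) -> np.ndarray:
    w, f11, f12, f21, f22 = u
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lo_at = lambda x: f11 + f12 * (1.0 + 2.0 * x) ** w
        hi_at = lambda x: f21 + f22 * (1.0 - 2.0 * x) ** p2
        dlo = 2.0 * w * f12 * (1.0 + 2.0 * p1) ** (w - 1.0)
        dhi = -2.0 * p2 * f22 * (1.0 - 2.0 * p1) ** (p2 - 1.0)
        res = np.array(
            [
                lo_at(-0.5),          # phi(-0.5) = 0
                hi_at(0.5) - 1.0,     # phi(+0.5) = 1
                lo_at(p1) - 0.5,      # lower branch hits 0.5 at the crossover
                hi_at(p1) - 0.5,      # upper branch hits 0.5 at the crossover
                dlo - dhi,            # slopes match at the crossover
            ]
        )
    # trial iterates with w <= 0 make the endpoint term blow up; feed the
    # solver a large finite residual instead
    return np.where(np.isfinite(res), res, 1e6)


def solve_asymmetric(p1: float, p2: float) -> AsymmetricShape:
    """Solve the five-constraint smoothness system for the asymmetric
    sigmoid with crossover ``p1`` and upper exponent ``p2``.

    Unknowns ``(w, phi11, phi12, phi21, phi22)`` are found by a damped
    Newton iteration (scipy's hybrid solver) on the analytic residuals;
    all residuals are required below 1e-8 absolute.
    """
    if not (-0.5 < p1 < 0.5):
        raise ValueError(f"crossover p1 = {p1} must lie strictly inside (-0.5, 0.5)")
    if p2 <= 0:
        raise ValueError("upper exponent p2 must be positive")

    # last-resort start: eliminate the slope constraint by hand, which
    # pins w up to the remaining value conditions
    w_slope = p2 * (1.0 + 2.0 * p1) / (1.0 - 2.0 * p1)
    guesses = [
        np.array([p2, 0.0, 0.5, 1.0, -0.5]),
        np.array([1.0, 0.0, 0.5, 1.0, -0.5]),
        np.array([2.0 * p2, 0.0, 0.25, 1.0, -0.5]),
        np.array([w_slope, 0.0, 0.5 / (1.0 + 2.0 * p1) ** min(w_slope, 300.0),
                  1.0, -0.5 / (1.0 - 2.0 * p1) ** p2]),
    ]
    for u0 in guesses:
        sol = root(_asym_residuals, u0, args=(p1, p2), method="hybr", tol=1e-12)
        if sol.success and np.max(np.abs(_asym_residuals(sol.x, p1, p2))) <= 1e-8:
            w, f11, f12, f21, f22 = sol.x
            if w > 0:
                return AsymmetricShape(p1, p2, w, f11, f12, f21, f22)
    raise RuntimeError(
        f"smoothness system infeasible or Newton failed for p1={p1}, p2={p2}"
    )


def asymmetric_sigmoid(xbar, p1: float, p2: float):
    """Evaluate the constrained asymmetric sigmoid (solves the
    smoothness system on the fly)."""
    return solve_asymmetric(p1, p2)(xbar)


# ---------------------------------------------------------------------------
# DistSpec wrapper
# ---------------------------------------------------------------------------

@dataclass
class DistSpec:
    """A distribution-function family with shape parameters and domain.

    ``domain`` is the through-transition X2 span ``(X2_1, X2_T)``; the
    bidirectional family also consumes the raw transverse coordinate X1.
    Evaluations are clamped to [0, 1].
    """

    family: str
    p: tuple[float, ...] = ()
    domain: tuple[float, float] = (0.0, 1.0)
    _shape: AsymmetricShape | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.p = tuple(float(v) for v in self.p)
        if self.family == "asymmetric_sigmoid":
            self._shape = solve_asymmetric(*self.p)

    @property
    def derived(self) -> dict | None:
        if self._shape is None:
            return None
        s = self._shape
        return {
            "w": s.w,
            "phi11": s.phi11,
            "phi12": s.phi12,
            "phi21": s.phi21,
            "phi22": s.phi22,
        }

    def __call__(self, coords):
        """Evaluate phi at coordinates.

        ``coords`` is an (n,) array of X2 values, or an (n, 2) array of
        (X1, X2) pairs for the bidirectional family (other families
        ignore X1).  Scalars are accepted.
        """
        c = np.asarray(coords, dtype=float)
        scalar = c.ndim == 0
        if c.ndim <= 1 and self.family == "bidirectional":
            raise ValueError("bidirectional family needs (X1, X2) coordinate pairs")
        if c.ndim == 2:
            X1, X2 = c[:, 0], c[:, 1]
        else:
            X1, X2 = None, np.atleast_1d(c)

        if self.family == "bidirectional":
            out = bidirectional(X1, X2, self.p, self.domain)
        else:
            xbar = normalize_coord(X2, *self.domain)
            if self.family == "linear":
                out = xbar + 0.5
            elif self.family == "symmetric_sigmoid":
                out = symmetric_sigmoid(xbar, *self.p)
            elif self.family == "tanh_modified":
                out = tanh_modified(X1 if X1 is not None else X2, *self.p)
            else:  # asymmetric_sigmoid
                out = self._shape(xbar)
        out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else np.asarray(out)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "p": list(self.p),
            "domain": list(self.domain),
            "derived": self.derived,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistSpec":
        return cls(family=d["family"], p=tuple(d["p"]), domain=tuple(d["domain"]))


# ---------------------------------------------------------------------------
# fitting to intensity data
# ---------------------------------------------------------------------------

_PARAM_BOUNDS = {
    "symmetric_sigmoid": [(0.1, 10.0), (0.1, 10.0)],
    "asymmetric_sigmoid": [(-0.45, 0.45), (0.1, 10.0)],
    "tanh_modified": [(0.2, 3.0), (0.1, 20.0), (-2.0, 2.0), (0.05, 10.0)],
    "bidirectional": [
        (0.2, 3.0), (0.1, 20.0), (-2.0, 2.0), (0.05, 10.0),
        (0.1, 10.0), (0.1, 10.0),
    ],
    "linear": [],
}


@dataclass
class FitResult:
    spec: DistSpec
    residual: float
    degenerate: bool = False
    message: str = ""


def fit_distribution(
    grid,
    family: str,
    p0: Sequence[float] | None = None,
    seed: int | None = None,
    n_starts: int = 8,
    domain: tuple[float, float] | None = None,
) -> FitResult:
    """Least-squares fit of a distribution family to intensity data.

    ``grid`` provides ``coords`` (n,) or (n, 2) and ``intensity`` (n,)
    in [0, 1] (an :class:`~tigrade.synthetic_fixtures.IntensityGrid` or
    any object with those attributes).  Derivative-free Nelder--Mead
    simplex from ``n_starts`` seeded Latin-hypercube starts (plus the
    user ``p0`` when given); the best start wins.
    """
    coords = np.asarray(grid.coords, dtype=float)
    y = np.asarray(grid.intensity, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("intensities must lie in [0, 1]")
    bounds = _PARAM_BOUNDS[family]
    if len(y) < max(len(bounds), 1):
        raise ValueError("need at least as many data points as parameters")
    if domain is not None:
        dom = (float(domain[0]), float(domain[1]))
    else:
        # default: the sampled X2 extent defines the transition span
        x2 = coords[:, -1] if coords.ndim == 2 else coords
        dom = (float(x2.min()), float(x2.max()))

    def sse(p) -> float:
        try:
            spec = DistSpec(family, tuple(p), dom)
            r = spec(coords) - y
            return float(r @ r)
        except (ValueError, RuntimeError, ZeroDivisionError):
            return 1e30

    if family == "linear":
        res = sse(())
        return FitResult(DistSpec("linear", (), dom), res)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(n=n_starts)]
    if p0 is not None:
        starts.insert(0, np.asarray(p0, dtype=float))

    best_p, best_r = None, np.inf
    for s in starts:
        out = minimize(sse, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        if out.fun < best_r:
            best_p, best_r = out.x, float(out.fun)
    if best_p is None or not np.isfinite(best_r) or best_r >= 1e30:
        raise RuntimeError(f"all {len(starts)} simplex starts failed for {family}")

    spec = DistSpec(family, tuple(best_p), dom)
    # flat data cannot identify shape parameters: flag rather than fail
    degenerate = float(np.ptp(y)) < 1e-3
    msg = "degenerate fit: intensity data nearly constant" if degenerate else ""
    return FitResult(spec, best_r, degenerate, msg)
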