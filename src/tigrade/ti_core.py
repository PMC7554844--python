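"""Transversely isotropic (TI) hyperelastic constitutive model.

Implements the Weiss-type TI law widely used for ligament, tendon and
heart-valve tissue: a Mooney--Rivlin isotropic matrix, a multi-regime
fiber response (inactive in compression, exponential toe region while
collagen uncrimps, linear once fibers are straightened), and a
logarithmic volumetric term.  The deviatoric response is characterized
by seven parameters ``C1, C2, C3, C4, C5, C6, lambda_star`` plus the
bulk modulus ``K``.

The module also provides the two quantities that drive functional
grading of this law across a tissue transition region:

* the *discontinuity index* ``f = C5 / (C3 C4 exp(C4 (lambda* - 1)))``,
  which measures the slope mismatch between the exponential and linear
  fiber regimes at the critical stretch (``f = 1`` means C1 continuity);
* the *grading stiffness* ``kg``, the rate of change of the
  fiber-direction traction stress with deviatoric fiber stretch,
  evaluated on the incompressible uniaxial-along-fiber path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expi

__all__ = [
    "TIParams",
    "Kinematics",
    "InvalidKinematicsError",
    "deviatoric_invariants",
    "fiber_stress_term",
    "fiber_energy",
    "strain_energy",
    "cauchy_stress",
    "c1_continuity_C5",
    "c6_from_c0",
    "discontinuity_index",
    "grading_stiffness",
    "gamma1",
    "gamma2",
]


class InvalidKinematicsError(ValueError):
    """Raised for non-finite or non-invertible deformation gradients."""


@dataclass(frozen=True)
class TIParams:
    """The seven deviatoric TI coefficients plus the bulk modulus.

    Parameters
    ----------
    C1, C2 : float
        Mooney--Rivlin matrix stiffnesses (Pa).
    C3 : float
        Fiber toe-region scale (Pa).
    C4 : float
        Fiber toe-region exponent (dimensionless).
    C5 : float
        Straightened-fiber modulus (Pa).
    C6 : float
        Linear-regime offset (Pa); normally set by :func:`c6_from_c0`
        so the two fiber branches agree at ``lambda_star``.
    lambda_star : float
        Critical deviatoric fiber stretch at which fibers transition
        from uncrimping to linear extension (dimensionless, >= 1).
    K : float
        Bulk modulus (Pa).
    name : str, optional
        Free-text material label.
    """

    C1: float
    C2: float
    C3: float
    C4: float
    C5: float
    C6: float
    lambda_star: float
    K: float
    name: str = ""

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (self.C1, self.C2, self.C3, self.C4, self.C5,
                      self.C6, self.lambda_star, self.K)
        ):
            raise ValueError("TIParams fields must be finite")
        if self.C1 < 0 or self.C2 < 0 or self.C3 < 0 or self.C5 < 0:
            raise ValueError("stiffness coefficients must be non-negative")
        if self.C4 <= 0:
            raise ValueError("C4 must be positive")
        if self.lambda_star < 1:
            raise ValueError("lambda_star must be >= 1")
        if self.K <= 0:
            raise ValueError("bulk modulus K must be positive")

    def with_c0_continuity(self) -> "TIParams":
        """Return a copy whose ``C6`` enforces C0 continuity at ``lambda_star``."""
        return replace(self, C6=c6_from_c0(self))

    @classmethod
    def from_fit(
        cls,
        C1: float,
        C2: float,
        C3: float,
        C4: float,
        C5: float,
        lambda_star: float,
        K: float,
        name: str = "",
    ) -> "TIParams":
        """Build from a fitted parameter row, deriving ``C6`` from C0 continuity."""
        p = cls(C1, C2, C3, C4, C5, 0.0, lambda_star, K, name=name)
        return p.with_c0_continuity()


@dataclass(frozen=True)
class Kinematics:
    """Deformation gradient plus reference fiber direction.

    Derived quantities (deviatoric invariants, fiber stretch, deformed
    fiber direction) are computed on demand.
    """

    F: np.ndarray
    a0: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        a0 = np.asarray(self.a0, dtype=float)
        if F.shape != (3, 3) or not np.all(np.isfinite(F)):
            raise InvalidKinematicsError("F must be a finite 3x3 matrix")
        if a0.shape != (3,) or abs(np.linalg.norm(a0) - 1.0) > 1e-12:
            raise ValueError("a0 must be a unit 3-vector (|a0| = 1 within 1e-12)")
        if np.linalg.det(F) <= 0:
            raise InvalidKinematicsError("det F must be positive")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "a0", a0)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy--Green tensor F^T F."""
        return self.F.T @ self.F

    @property
    def B(self) -> np.ndarray:
        """Left Cauchy--Green tensor F F^T."""
        return self.F @ self.F.T

    @property
    def I1t(self) -> float:
        return float(self.J ** (-2.0 / 3.0) * np.trace(self.C))

    @property
    def I2t(self) -> float:
        Ct = self.J ** (-2.0 / 3.0) * self.C
        return float(0.5 * (np.trace(Ct) ** 2 - np.trace(Ct @ Ct)))

    @property
    def I4t(self) -> float:
        return float(self.J ** (-2.0 / 3.0) * self.a0 @ self.C @ self.a0)

    @property
    def lambda_t(self) -> float:
        """Deviatoric fiber stretch, sqrt(I4t)."""
        return math.sqrt(self.I4t)

    @property
    def fiber_stretch(self) -> float:
        """Total fiber stretch |F a0| (affine kinematics)."""
        return float(np.linalg.norm(self.F @ self.a0))

    @property
    def a(self) -> np.ndarray:
        """Deformed unit fiber direction, F a0 / |F a0|."""
        v = self.F @ self.a0
        return v / np.linalg.norm(v)


def deviatoric_invariants(kin: Kinematics) -> tuple[float, float, float, float]:
    """Return ``(I1t, I2t, I4t, lambda_t)`` for a kinematic state."""
    return kin.I1t, kin.I2t, kin.I4t, kin.lambda_t


# ---------------------------------------------------------------------------
# fiber response
# ---------------------------------------------------------------------------

def fiber_stress_term(lambda_t: float, p: TIParams) -> float:
    """Fiber stress measure ``lambda_t * dF2/dlambda_t`` (Pa).

    Three regimes: zero in compression (``lambda_t <= 1``), exponential
    while fibers uncrimp (``1 < lambda_t < lambda_star``), linear once
    straightened (``lambda_t > lambda_star``).  A stretch exactly at 1
    uses the zero branch and exactly at ``lambda_star`` the exponential
    branch; with ``C6`` from C0 continuity the boundary values coincide.
    """
    if lambda_t <= 0:
        raise ValueError("lambda_t must be positive")
    if lambda_t <= 1.0:
        return 0.0
    if lambda_t <= p.lambda_star:
        return p.C3 * (math.exp(p.C4 * (lambda_t - 1.0)) - 1.0)
    return p.C5 * lambda_t + p.C6


def fiber_energy(lambda_t: float, p: TIParams) -> float:
    """Fiber strain energy F2 (Pa), i.e. the integral of
    ``fiber_stress_term(s)/s`` from 1 to ``lambda_t``.

    The exponential branch integrates to an exponential-integral (Ei)
    term; the linear branch is elementary.
    """
    if lambda_t <= 1.0:
        return 0.0

    C3, C4, C5, C6, ls = p.C3, p.C4, p.C5, p.C6, p.lambda_star

    def exp_branch(lo: float, hi: float) -> float:
        # int C3 (e^{C4(s-1)} - 1)/s ds = C3 e^{-C4} [Ei(C4 s)] - C3 ln s
        return float(
            C3 * math.exp(-C4) * (expi(C4 * hi) - expi(C4 * lo))
            - C3 * math.log(hi / lo)
        )

    if lambda_t < ls:
        return exp_branch(1.0, lambda_t)
    w = exp_branch(1.0, ls)
    # int (C5 s + C6)/s ds = C5 (s - ls) + C6 ln(s/ls)
    return w + C5 * (lambda_t - ls) + C6 * math.log(lambda_t / ls)


def strain_energy(kin: Kinematics, p: TIParams) -> float:
    """Total strain energy density W (Pa): matrix + fiber + volumetric."""
    i1, i2, _, lt = deviatoric_invariants(kin)
    w = p.C1 * (i1 - 3.0) + p.C2 * (i2 - 3.0) + fiber_energy(lt, p)
    return w + 0.5 * p.K * math.log(kin.J) ** 2


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------

def cauchy_stress(kin: Kinematics, p: TIParams) -> np.ndarray:
    """Cauchy stress tensor (Pa) for the compressible TI law.

    Hydrostatic pressure comes from the volumetric term,
    ``p_hyd = K ln(J) / J``; the deviatoric part combines the
    Mooney--Rivlin matrix and the active fiber contribution along the
    deformed fiber direction.
    """
    J = kin.J
    Bt = J ** (-2.0 / 3.0) * kin.B
    i1, i2, i4, lt = deviatoric_invariants(kin)
    a = kin.a

    W1 = p.C1
    W2 = p.C2
    fib = fiber_stress_term(lt, p)      # = 2 * W4 * I4t
    W4I4 = 0.5 * fib

    eye = np.eye(3)
    dev = (
        (W1 + W2 * i1) * Bt
        - W2 * (Bt @ Bt)
        + W4I4 * np.outer(a, a)
        - (W1 * i1 + 2.0 * W2 * i2 + W4I4) / 3.0 * eye
    )
    p_hyd = p.K * math.log(J) / J
    sig = p_hyd * eye + (2.0 / J) * dev
    return 0.5 * (sig + sig.T)


# ---------------------------------------------------------------------------
# continuity relations and grading quantities
# ---------------------------------------------------------------------------

def c1_continuity_C5(p: TIParams) -> float:
    """``C5`` that makes the fiber-regime slope continuous at ``lambda_star``:
    ``C5 = C3 C4 exp(C4 (lambda* - 1))``."""
    if p.C3 <= 0 or p.C4 <= 0:
        raise ValueError("C3 and C4 must be positive for the continuity relation")
    return p.C3 * p.C4 * math.exp(p.C4 * (p.lambda_star - 1.0))


def c6_from_c0(p: TIParams) -> float:
    """``C6`` enforcing value (C0) continuity of the fiber regimes at
    ``lambda_star``: ``C6 = C3 (exp(C4 (lambda*-1)) - 1) - C5 lambda*``."""
    return p.C3 * (math.exp(p.C4 * (p.lambda_star - 1.0)) - 1.0) - p.C5 * p.lambda_star


def discontinuity_index(p: TIParams) -> float:
    """Slope-mismatch index ``f = C5 / (C3 C4 exp(C4 (lambda*-1)))``.

    ``f = 1`` corresponds to C1 (slope) continuity at the exponential--
    linear interface.  Undefined for materials with no fiber toe region.
    """
    if p.C3 == 0 or p.C4 == 0:
        raise ValueError(
            "discontinuity index undefined for C3 = 0 or C4 = 0 "
            "(isotropic terminal: use the f = 1, lambda* = 1 convention)"
        )
    return p.C5 / (p.C3 * p.C4 * math.exp(p.C4 * (p.lambda_star - 1.0)))


def gamma1(lambda_t: float) -> float:
    """Matrix C1 weight in the grading stiffness on the incompressible
    uniaxial-along-fiber path: ``(8/3) lt + (4/3) / lt^2``."""
    return 8.0 / 3.0 * lambda_t + 4.0 / 3.0 / lambda_t ** 2


def gamma2(lambda_t: float) -> float:
    """Matrix C2 weight: ``4/3 + (8/3) / lt^3``."""
    return 4.0 / 3.0 + 8.0 / 3.0 / lambda_t ** 3


def _fiber_slope(lambda_t: float, p: TIParams) -> float:
    """d/dlt of fiber_stress_term; boundary ties broken toward the lower regime."""
    if lambda_t <= 1.0:
        return 0.0
    if lambda_t <= p.lambda_star:
        return p.C3 * p.C4 * math.exp(p.C4 * (lambda_t - 1.0))
    return p.C5


def _axial_traction_uniaxial(lambda_t: float, p: TIParams) -> float:
    """a^T sigma a on the incompressible uniaxial path (J = 1, fiber axial)."""
    F = np.diag([lambda_t, lambda_t ** -0.5, lambda_t ** -0.5])
    kin = Kinematics(F=F, a0=np.array([1.0, 0.0, 0.0]))
    sig = cauchy_stress(kin, p)
    return float(sig[0, 0])


def grading_stiffness(
    p: TIParams,
    lambda_t: float,
    mode: str = "analytic",
    h: float = 1e-5,
) -> float:
    """Grading stiffness ``kg = d(a^T sigma a)/d lambda_t`` (Pa).

    Evaluated on the incompressible uniaxial-stretch-along-fiber path
    (J = 1, transverse stretches ``lambda_t**-0.5``), consistent with
    the near-incompressibility of hydrated soft tissue.

    ``mode='analytic'`` assembles the closed form
    ``kg = C1 g1(lt) + C2 g2(lt) + (2/3) d(lt dF2/dlt)/dlt``;
    ``mode='finite_difference'`` centrally differences the axial
    traction stress (the independent oracle).
    """
    if lambda_t <= 0:
        raise ValueError("lambda_t must be positive")
    if mode == "analytic":
        return (
            p.C1 * gamma1(lambda_t)
            + p.C2 * gamma2(lambda_t)
            + 2.0 / 3.0 * _fiber_slope(lambda_t, p)
        )
    if mode == "finite_difference":
        for b in (1.0, p.lambda_star):
            if abs(lambda_t - b) < h:
                import warnings

                warnings.warn(
                    f"finite-difference stencil straddles the regime boundary "
                    f"at lambda_t = {b}; result may be inaccurate",
                    RuntimeWarning,
                    stacklevel=2,
                )
        lo = max(lambda_t - h, 1e-6)
        hi = lambda_t + h
        return (
            _axial_traction_uniaxial(hi, p) - _axial_traction_uniaxial(lo, p)
        ) / (hi - lo)
    raise ValueError(f"unknown mode {mode!r}")
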