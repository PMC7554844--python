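"""1-D graded-chain tension mechanics and fiber-orientation utilities.

A graded transition specimen under uniaxial tension is represented as a
serial chain of incompressible TI unit cells: every layer carries the
same nominal (first Piola) axial force, and the layer stretches must
add up to the applied overall stretch.  This captures the quantity the
transition studies actually compare — the axial strain profile along
the specimen centerline at a set of fiducial points — without lateral
coupling between layers.

Also here: the affine fiber-kinematics update (``lambda a = F a0``) and
nearest-neighbor mapping of measured fiber orientations onto element
centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .fgm_grading import GradedStack
from .ti_core import TIParams, fiber_stress_term

__all__ = [
    "ChainGeometry",
    "ChainState",
    "OrientationField",
    "uniaxial_response",
    "chain_equilibrium",
    "fiducial_strains",
    "affine_fiber_update",
    "map_orientations",
]


# ---------------------------------------------------------------------------
# unit-cell response
# ---------------------------------------------------------------------------

def uniaxial_response(p: TIParams, stretch: float) -> float:
    """Nominal (first Piola) axial stress (Pa) of an incompressible TI
    unit cell stretched along its fiber.

    Strict incompressibility: ``F = diag(l, l^-1/2, l^-1/2)``, J = 1,
    with the hydrostatic pressure eliminated by the traction-free
    lateral faces.  The Cauchy axial stress reduces to

        sigma = 2 (l^2 - 1/l)(C1 + C2 / l) + lt dF2/dlt,

    and the nominal stress is sigma / l.
    """
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    lam = float(stretch)
    sigma = 2.0 * (lam**2 - 1.0 / lam) * (p.C1 + p.C2 / lam) + fiber_stress_term(lam, p)
    return sigma / lam


# ---------------------------------------------------------------------------
# chain geometry and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainGeometry:
    """Reference geometry of a serial chain of layers.

    ``layer_lengths`` (mm) and ``layer_areas`` (mm^2) per layer,
    ``fiducials`` — axial reference coordinates (mm) of tracked points,
    measured from the material-1 end.
    """

    layer_lengths: np.ndarray
    layer_areas: np.ndarray
    fiducials: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.layer_lengths, dtype=float)
        A = np.asarray(self.layer_areas, dtype=float)
        f = np.asarray(self.fiducials, dtype=float)
        if np.any(L <= 0) or np.any(A <= 0):
            raise ValueError("layer lengths and areas must be positive")
        if L.shape != A.shape:
            raise ValueError("lengths and areas must have the same layer count")
        if np.any(f < 0) or np.any(f > L.sum()):
            raise ValueError("fiducials must lie within the chain span")
        object.__setattr__(self, "layer_lengths", L)
        object.__setattr__(self, "layer_areas", A)
        object.__setattr__(self, "fiducials", f)

    @property
    def n_layers(self) -> int:
        return len(self.layer_lengths)

    @property
    def total_length(self) -> float:
        return float(self.layer_lengths.sum())

    @classmethod
    def uniform(
        cls, n_layers: int, total_length: float = 10.0, area: float = 1.0,
        n_fiducials: int = 10,
    ) -> "ChainGeometry":
        """Equal-length, equal-area layers with evenly spread fiducials."""
        L = np.full(n_layers, total_length / n_layers)
        A = np.full(n_layers, area)
        fid = np.linspace(0.0, total_length, n_fiducials + 2)[1:-1]
        return cls(L, A, fid)

    @classmethod
    def ct_pm_tapered(
        cls, n_layers: int, total_length: float = 2.7,
        area_1: float = 0.6, area_T: float = 3.0, n_fiducials: int = 10,
    ) -> "ChainGeometry":
        """Chordae-to-papillary-muscle preset: the thin chordae end
        (material 1) widens toward the muscle end, so geometric and
        material stiffness pull in opposite directions."""
        L = np.full(n_layers, total_length / n_layers)
        A = np.linspace(area_1, area_T, n_layers)
        fid = np.linspace(0.0, total_length, n_fiducials + 2)[1:-1]
        return cls(L, A, fid)


@dataclass(frozen=True)
class ChainState:
    """Converged equilibrium of a chain at one applied stretch."""

    applied_stretch: float
    axial_force: float
    layer_stretches: np.ndarray

    def elongation_residual(self, geom: ChainGeometry) -> float:
        L = geom.layer_lengths
        return float(
            abs(L @ self.layer_stretches - self.applied_stretch * L.sum())
            / (self.applied_stretch * L.sum())
        )


def _invert_uniaxial(p: TIParams, nominal: float, hi: float) -> float:
    """Stretch at which the unit cell carries the given nominal stress
    (monotone inversion by bracketing on [1, hi], expanding if needed)."""
    if nominal <= 0.0:
        return 1.0
    for _ in range(60):
        if uniaxial_response(p, hi) >= nominal:
            break
        hi = 1.0 + 1.5 * (hi - 1.0)
    else:
        raise RuntimeError("failed to bracket the layer stretch")
    return brentq(lambda s: uniaxial_response(p, s) - nominal, 1.0, hi,
                  xtol=1e-14, rtol=8.9e-16)


def chain_equilibrium(
    geom: ChainGeometry,
    stack: GradedStack | Sequence[TIParams],
    applied_stretch: float,
) -> ChainState:
    """Solve the serial force balance of a graded chain.

    Finds the axial force N such that, with every layer stretched to
    carry nominal stress ``N / A_t``, the summed layer elongations
    reproduce ``applied_stretch``.  Both maps are strictly monotone, so
    the outer solve brackets N and uses Brent's method; the inner
    per-layer inversion brackets the stretch.
    """
    layers = stack.layers if isinstance(stack, GradedStack) else list(stack)
    if len(layers) != geom.n_layers:
        raise ValueError(
            f"stack has {len(layers)} layers but geometry has {geom.n_layers}"
        )
    if applied_stretch < 1.0:
        raise ValueError("applied_stretch must be >= 1")
    L, A = geom.layer_lengths, geom.layer_areas
    target = applied_stretch * L.sum()

    if applied_stretch == 1.0:
        return ChainState(1.0, 0.0, np.ones(geom.n_layers))

    # every other layer stretches at least to 1, so layer i can never
    # exceed 1 + (applied - 1) * L_total / L_i; this caps the inner
    # inversion brackets and yields a rigorous force upper bound
    caps = (1.0 + (applied_stretch - 1.0) * L.sum() / L) * 1.001
    N_hi = min(
        uniaxial_response(p, c) * a for p, a, c in zip(layers, A, caps)
    )

    # force units: stress (Pa) x area (mm^2); internally consistent
    def elong(N: float) -> float:
        s = np.array(
            [_invert_uniaxial(p, N / a, c) for p, a, c in zip(layers, A, caps)]
        )
        return float(L @ s) - target

    N = brentq(elong, 0.0, N_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)

    stretches = np.array(
        [_invert_uniaxial(p, N / a, c) for p, a, c in zip(layers, A, caps)]
    )
    state = ChainState(applied_stretch, float(N), stretches)
    if state.elongation_residual(geom) > 1e-8:
        raise RuntimeError(
            f"chain solver did not converge: elongation residual "
            f"{state.elongation_residual(geom):.3e}"
        )
    return state


def fiducial_strains(
    state: ChainState,
    geom: ChainGeometry,
    normalize: bool = False,
    norm_value: float | None = None,
) -> np.ndarray:
    """Engineering strain at each fiducial (the strain of its layer).

    With ``normalize=True`` the strains are divided by their maximum
    (or by ``norm_value`` when profiles from several load steps share a
    common normalization).
    """
    edges = np.concatenate([[0.0], np.cumsum(geom.layer_lengths)])
    idx = np.searchsorted(edges, geom.fiducials, side="right") - 1
    idx = np.clip(idx, 0, geom.n_layers - 1)
    eps = state.layer_stretches[idx] - 1.0
    if normalize:
        m = norm_value if norm_value is not None else float(np.max(np.abs(eps)))
        if m > 0:
            eps = eps / m
    return eps


# ---------------------------------------------------------------------------
# fiber orientation
# ---------------------------------------------------------------------------

def affine_fiber_update(F: np.ndarray, a0: np.ndarray) -> tuple[np.ndarray, float]:
    """Affine fiber kinematics: the reference direction convects with
    the deformation, ``lambda a = F a0``.

    Returns the deformed unit direction and the fiber stretch.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    if abs(np.linalg.norm(a0) - 1.0) > 1e-10:
        raise ValueError("a0 must be a unit vector")
    if abs(np.linalg.det(F)) < 1e-300:
        raise ValueError("singular deformation gradient")
    v = F @ a0
    lam = float(np.linalg.norm(v))
    return v / lam, lam


@dataclass(frozen=True)
class OrientationField:
    """Sampled in-plane fiber orientations at (X1, X2) points."""

    points: np.ndarray      # (n, 2)
    vectors: np.ndarray     # (n, 2) unit in-plane fiber directions

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        vec = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(pts) == 0:
            raise ValueError("orientation field must contain at least one sample")
        if pts.shape != vec.shape or pts.shape[1] != 2:
            raise ValueError("points and vectors must be (n, 2) arrays")
        norms = np.linalg.norm(vec, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("orientation vectors must be unit length")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "vectors", vec)


def map_orientations(field: OrientationField, targets: np.ndarray) -> np.ndarray:
    """Assign each target point the orientation of its nearest sample
    (Euclidean, in-plane; KD-tree accelerated).

    Distance ties resolve to the lowest sample index, matching a
    brute-force argmin scan.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    tree = cKDTree(field.points)
    k = min(len(field.points), 4)
    d, idx = tree.query(targets, k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    # exact-distance ties resolve to the lowest sample index
    best = np.empty(len(targets), dtype=int)
    for i in range(len(targets)):
        tied = idx[i][d[i] == d[i][0]]
        best[i] = tied.min()
    return field.vectors[best]
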