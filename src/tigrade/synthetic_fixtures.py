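"""Seeded generators for synthetic experimental inputs.

Every input the inverse problems consume can be produced here with a
known ground truth: collagen-intensity grids over a transition region,
normalized fiducial strain profiles from the graded-chain forward
model, uniaxial force--displacement curves, and in-plane fiber
orientation fields.  These emulate the statistical structure of
XRD-derived datasets (intensity fraction in [0, 1], molecular strain
at ~10 fiducials over a 0--10% stretch sweep, tension curves) without
any diffraction physics; they exist so the whole pipeline is testable
offline and so recovery tests have exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_sim import ChainGeometry, chain_equilibrium, fiducial_strains
from .distributions import DistSpec
from .fgm_grading import TerminalFit, generate_fgm
from .inverse_est import FDCurve, StrainProfile, _forward_profile_top_step
from .presets import material
from .ti_core import TIParams

__all__ = [
    "FixtureConfig",
    "IntensityGrid",
    "make_intensity_grid",
    "make_strain_profile",
    "make_fd_curve",
    "make_orientation_field",
    "terminal_pair",
]


@dataclass(frozen=True)
class IntensityGrid:
    """Normalized collagen-intensity samples over transition coordinates."""

    coords: np.ndarray      # (n,) X2 or (n, 2) (X1, X2)
    intensity: np.ndarray   # (n,) in [0, 1]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the experimental setting the generators emulate:
    10 fiducials over a 0--10% stretch sweep in 2% steps, intensity
    noise sd 0.05, 1% multiplicative strain noise, 1% relative force
    noise, and the porcine tricuspid-valve (TV) terminal fits.
    """

    seed: int
    intensity_sd: float = 0.05
    strain_sd: float = 0.01          # multiplicative
    force_sd: float = 0.01           # relative
    n_grid: int = 200
    n_layers: int = 10
    n_fiducials: int = 10
    max_strain: float = 0.10
    strain_step: float = 0.02
    geometry: str = "uniform"        # or "ct_pm_tapered"
    preset: str = "TV"               # or "MV"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for v in (self.intensity_sd, self.strain_sd, self.force_sd):
            if v < 0:
                raise ValueError("noise levels must be non-negative")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)

    def chain_geometry(self) -> ChainGeometry:
        if self.geometry == "uniform":
            return ChainGeometry.uniform(
                self.n_layers, n_fiducials=self.n_fiducials
            )
        if self.geometry == "ct_pm_tapered":
            return ChainGeometry.ct_pm_tapered(
                self.n_layers, n_fiducials=self.n_fiducials
            )
        raise ValueError(f"unknown geometry preset {self.geometry!r}")


def terminal_pair(preset: str, pair: str = "CT_PM") -> tuple[TerminalFit, TerminalFit]:
    """Terminal fits for a valve (TV or MV) transition, material-1 side
    first.  ``pair`` is ``"CT_PM"`` or ``"CT_LL"`` (chordae end first)."""
    first, second = pair.split("_")
    return (
        TerminalFit(material(f"{preset}_{first}")),
        TerminalFit(material(f"{preset}_{second}")),
    )


def make_intensity_grid(config: FixtureConfig, true_dist: DistSpec) -> IntensityGrid:
    """Sample phi_true on a seeded coordinate grid and add clamped
    Gaussian intensity noise."""
    rng = config.rng(salt=1)
    lo, hi = true_dist.domain
    if true_dist.family == "bidirectional":
        coords = np.column_stack(
            [rng.uniform(-1.0, 1.0, config.n_grid),
             rng.uniform(lo, hi, config.n_grid)]
        )
    else:
        coords = rng.uniform(lo, hi, config.n_grid)
    clean = np.asarray(true_dist(coords), dtype=float)
    noisy = np.clip(clean + rng.normal(0.0, config.intensity_sd, clean.shape), 0.0, 1.0) \
        if config.intensity_sd > 0 else clean
    return IntensityGrid(coords=coords, intensity=noisy)


def make_strain_profile(
    config: FixtureConfig,
    true_p: tuple[float, float],
    terminals: tuple[TerminalFit, TerminalFit] | None = None,
) -> StrainProfile:
    """Run the forward graded-chain pipeline for known shape parameters
    and emit a (noisy, max-normalized) fiducial strain profile.

    Steps 0 to ``max_strain`` in ``strain_step`` increments; the top
    step reproduces the profile the shape-parameter estimator consumes.
    """
    geom = config.chain_geometry()
    if terminals is None:
        terminals = terminal_pair(config.preset, "CT_PM")
    steps = np.arange(0.0, config.max_strain + 1e-12, config.strain_step)

    spec = DistSpec("asymmetric_sigmoid", tuple(true_p), (0.0, geom.total_length))
    edges = np.concatenate([[0.0], np.cumsum(geom.layer_lengths)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    coords = centers.copy()
    coords[0], coords[-1] = 0.0, geom.total_length
    stack = generate_fgm(terminals[0], terminals[1], geom.n_layers, spec, coords=coords)

    raw = np.zeros((len(geom.fiducials), len(steps)))
    for j, eps in enumerate(steps):
        if eps == 0.0:
            continue
        state = chain_equilibrium(geom, stack, 1.0 + eps)
        raw[:, j] = fiducial_strains(state, geom, normalize=False)

    if config.strain_sd > 0:
        rng = config.rng(salt=2)
        raw = raw * (1.0 + rng.normal(0.0, config.strain_sd, raw.shape))
        raw = np.abs(raw)
        raw[:, steps == 0.0] = 0.0
    m = raw[:, -1].max()
    return StrainProfile(fiducials=geom.fiducials, load_steps=steps, strains=raw / m)


def make_fd_curve(
    config: FixtureConfig,
    true_params: TIParams,
    n_points: int = 30,
    max_stretch: float = 1.15,
    gauge_length: float = 10.0,
    area: float = 1.0,
) -> FDCurve:
    """Uniaxial force--displacement curve from the unit-cell forward
    model with relative Gaussian noise (the zero point stays exact)."""
    from .chain_sim import uniaxial_response

    stretches = np.linspace(1.0, max_stretch, n_points)
    disp = (stretches - 1.0) * gauge_length
    forces = np.array(
        [uniaxial_response(true_params, s) * area * 1e-6 for s in stretches]
    )
    if config.force_sd > 0:
        rng = config.rng(salt=3)
        noise = 1.0 + rng.normal(0.0, config.force_sd, forces.shape)
        forces = forces * noise
        forces[0] = 0.0
    return FDCurve(displacements=disp, forces=forces,
                   gauge_length=gauge_length, area=area)


def make_orientation_field(
    config: FixtureConfig,
    true_dist: DistSpec,
    n_points: int = 100,
    angular_sd_deg: float = 5.0,
) -> "OrientationField":
    """In-plane fiber orientation samples across a transition.

    The fiber angle rotates from 0 deg (along the load axis, pure
    chordae side, phi = 0) to 90 deg (transverse, leaflet side,
    phi = 1), with wrapped-normal angular noise.
    """
    from .chain_sim import OrientationField

    rng = config.rng(salt=4)
    lo, hi = true_dist.domain
    x2 = np.sort(rng.uniform(lo, hi, n_points))
    x1 = rng.uniform(-0.5, 0.5, n_points)
    coords = np.column_stack([x1, x2]) if true_dist.family == "bidirectional" else x2
    phi = np.asarray(true_dist(coords), dtype=float)
    angles = phi * (np.pi / 2.0)
    if angular_sd_deg > 0:
        angles = angles + rng.normal(0.0, np.deg2rad(angular_sd_deg), n_points)
    vec = np.column_stack([np.cos(angles), np.sin(angles)])
    pts = np.column_stack([x1, x2])
    return OrientationField(points=pts, vectors=vec)
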