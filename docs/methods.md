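# Methods

## Constitutive model

Each material point obeys a decoupled transversely isotropic (TI)
hyperelastic law of the Weiss type: a Mooney–Rivlin isotropic matrix
`C1 (Ĩ1 − 3) + C2 (Ĩ2 − 3)` over the deviatoric invariants, a
single-fiber-family energy F2(λ̃) in the deviatoric fiber stretch
λ̃ = √Ĩ4, and the volumetric term `U = (K/2)(ln J)²`. The fiber
measure λ̃ ∂F2/∂λ̃ is zero for λ̃ ≤ 1 (crimped fibers carry no
compressive load), exponential `C3 (e^{C4(λ̃−1)} − 1)` while fibers
uncrimp, and linear `C5 λ̃ + C6` beyond the critical stretch λ*. C6 is
always derived from value continuity at λ*
(`C6 = C3 (e^{C4(λ*−1)} − 1) − C5 λ*`); C5 is an independent fitting
parameter unless slope continuity is requested, in which case
`C5 = C3 C4 e^{C4(λ*−1)}`. The package never overwrites a
user-supplied C5 silently — the slope-continuity value is applied only
where the grading algorithm's uncrimped-terminal rule demands it (see
below), and both conventions are exposed as plain functions.

Cauchy stress follows from the standard deviatoric push-forward with
hydrostatic pressure `p = K ln J / J`. The fiber energy integrates the
exponential branch to an exponential-integral (Ei) term, which lets the
stress/energy consistency check run at tight tolerance without
numerical quadrature.

Parameters and units: C1, C2, C3, C5, C6 and K in Pa; C4, λ̃ and λ*
dimensionless. The shipped valve-tissue presets (tricuspid and mitral
chordae tendinae / leaflet / papillary muscle) all use
K = 1.464 × 10⁸ Pa and C2 = 0; K is large against the deviatoric
coefficients, so the response is nearly incompressible.

## Grading stiffness

The grading metric is k_g = ∂(aᵀσa)/∂λ̃, the rate of change of the
fiber-direction traction with deviatoric fiber stretch. The general
definition leaves the deformation path unspecified; we evaluate it on
the incompressible uniaxial-stretch-along-fiber path
(F = diag(λ̃, λ̃^−½, λ̃^−½), J = 1), consistent with the near-
incompressibility assumption and with the uniaxial experiments the
terminal fits come from. On that path the matrix weights have closed
forms

    γ1(λ̃) = (8/3) λ̃ + (4/3) λ̃⁻²,   γ2(λ̃) = 4/3 + (8/3) λ̃⁻³,

(both equal to 4 at λ̃ = 1) and
`k_g = C1 γ1 + C2 γ2 + (2/3) d(λ̃ ∂F2/∂λ̃)/dλ̃`, which reduces to
(2/3) C5 in the straightened-fiber regime of a fiber-dominated tissue.
A finite-difference mode differences aᵀσa computed from the full
stress tensor on the same path and serves as the independent oracle;
the two agree to 1e-4 relative away from the regime boundaries. At a
boundary the analytic mode takes the lower regime's one-sided
derivative; the finite-difference mode warns when its stencil
straddles a boundary.

## The interpolation law

A graded stack of T layers between terminal fits θ₁ and θ_T is built
as follows. C1, C2, C3, C5 and K blend linearly under the constituent
fraction φ(t) (φ = 0 at the material-1 terminal, 1 at the material-T
terminal); λ* and the discontinuity index
f = C5 / (C3 C4 e^{C4(λ*−1)}) blend under a monotone ψ(t) (default
ψ ≡ φ, with a monotonicity check on the sampled coordinates); each
layer's C4 is the unique positive root of
`g(C4) = f C3 C4 e^{C4(λ*−1)} − C5` (g is strictly increasing for
λ* ≥ 1, so the solve is a bracketed Brent iteration with a Newton
polish; closed form C4 = C5/(f C3) when λ* = 1); C6 then follows from
value continuity. This ordering makes the layer-1 and layer-T
parameters reproduce the terminals exactly and keeps every layer's f
inside the terminal interval, which bounds the slope discontinuity at
the exponential–linear interface across the whole stack.

Two special cases:

* **Uncrimped terminal** — if a terminal's experiment never reached
  λ* (lambda_max < λ*), its fitted C5 never influenced the data and is
  replaced by the slope-continuity value with f := 1 before grading.
* **Isotropic terminal** — a terminal with no fiber phase (C3 = C5 = 0)
  has undefined f and λ*; both are set to 1 and graded under φ. At the
  isotropic endpoint layer the C4 root equation degenerates
  (C3 = C5 = 0), but its limit as φ → 0 is well defined because C3 and
  C5 vanish proportionally; the implementation solves the limit
  equation with the anisotropic terminal's C5/C3 ratio.

K is graded linearly under φ; the shipped presets share one K, making
this a no-op, but the choice keeps the volumetric response graded
consistently if a user supplies unequal bulk moduli.

The three-way case study (`case_study`) contrasts the full law
(variant 3) with slope-continuous C5 reconstruction on blended
parameters (variant 1) and fully independent per-parameter blending
(variant 2). With the tricuspid chordae/leaflet terminals and any
monotone φ, variant 3's layer tension responses stay inside the
terminal envelope on λ ∈ [1, 1.3] while variant 1 escapes it and
variant 2's fiber-slope jump at λ* exceeds variant 3's by orders of
magnitude; these are asserted as properties, not against printed
curves.

## Distribution functions

All families map transition coordinates to a constituent fraction and
are clamped to [0, 1] at the wrapper level. The through-transition
coordinate is normalized to X̄ ∈ [−0.5, 0.5]. The symmetric sigmoid is
the two-sided power law with value ½ at X̄ = 0; the saturating tanh
profile `p1 (e^u − e^{−u})/(e^u − e^{−u} + p4)`, u = p2 (X1 − p3), is
evaluated in a shifted form (numerator and denominator divided by
e^{|u|}) so it never overflows; the bidirectional family is the
clamped *product* of the two — the clamp is applied after the product,
so either factor may individually leave [0, 1]. The tanh profile has a
genuine pole where e^u − e^{−u} = −p4; evaluation within 1e-12 of it
raises rather than returning a meaningless value.

The asymmetric sigmoid has two free parameters: the crossover
coordinate p1 ∈ (−0.5, 0.5) where the function passes through ½, and
the upper-branch exponent p2 > 0. Its five remaining coefficients
(w, φ11, φ12, φ21, φ22) are determined by five smoothness constraints
(endpoints at 0 and 1, both branches at ½ at p1, matching first
derivatives at p1) and solved numerically by a damped Newton (hybrid)
iteration on the analytic residuals from neutral starting points, with
all residuals required below 1e-8. The system also admits a hand
elimination — w = p2 (1+2p1)/(1−2p1), φ11 = 0, φ21 = 1,
φ12 = 0.5/(1+2p1)^w, φ22 = −0.5/(1−2p1)^{p2} — which the tests use as
an independent oracle against the numerical solve, and which supplies
a fallback starting point for extreme shape parameters.

Fitting a family to intensity data uses derivative-free Nelder–Mead
simplex from 8 seeded Latin-hypercube starts over fixed parameter
bounds (the surface is multimodal and a single local simplex is not
reliable); nearly constant data are flagged as a degenerate fit rather
than rejected.

## Chain simulator

The tension response of a graded specimen is modeled as a serial chain
of incompressible uniaxial unit cells: one TI parameter set per layer,
uniform nominal (first Piola) axial force, layer elongations summing
to the applied stretch, no lateral coupling. The unit-cell nominal
stress has the closed form
`[2 (λ² − 1/λ)(C1 + C2/λ) + λ̃ ∂F2/∂λ̃] / λ` (strict
incompressibility, pressure eliminated by traction-free lateral
faces), strictly increasing in λ, so both the inner per-layer
inversion and the outer force balance are monotone bracketed solves.
The bracket uses the rigorous cap λ_i ≤ 1 + (λ̄ − 1) ΣL/L_i (no other
layer can shorten below 1), which also yields a guaranteed force upper
bound; converged states satisfy force uniformity and elongation
consistency to 1e-8 relative.

Fiducial strains are the engineering strains of the layers containing
the fiducial coordinates; "normalized" profiles divide by the maximum
fiducial strain at the top load step, making them invariant to any
uniform scaling of the raw strains (the reason normalized measures are
used at all: molecular and macroscopic strain differ by an unknown
conversion factor). Geometry presets: uniform layers, and a
chordae-to-muscle taper in which the thin, stiff chordae end opposes
the compliant, thick muscle end so geometric and material stiffness
compete. The published specimens' cross-section profiles are unknown,
so absolute strains from the chain are not comparable to experiments —
only normalized profiles are.

This 1-D surrogate reproduces the quantities the transition studies
compare (axial strain localization, tension-response envelopes) but
none of the field effects: no transverse strain maps, no necking
instability of a hard transition, no contact or clamping artifacts.

## Inverse problems

**Terminal fitting.** The deviatoric parameters {C1, C3, C4, λ*, C5}
are fitted to a force–displacement curve with K fixed at
1.464 × 10⁸ Pa (uniaxial data contain no volumetric information) and
C2 = 0 by default. The objective is the sum of squared force
residuals normalized by the peak force, minimized by seeded
differential evolution over log-scaled stiffness coefficients followed
by a Nelder–Mead polish. C3 and C4 trade off strongly when the data
stop in the toe region, and C5/λ* are unidentified if the fibers never
straightened, so goodness of fit is judged in *response space*: R² and
the maximum force error relative to the peak (defined against the peak
because the mandatory first point has zero force).

**Shape estimation.** The asymmetric-sigmoid parameters (p1, p2) are
estimated by embedding the full forward pipeline — smoothness solve,
grading, chain equilibrium, normalization — in a seeded
differential-evolution search scoring the squared residual between
simulated and measured normalized fiducial strains at the maximum load
step only (at peak load the fibers are extending, where molecular
strain tracks macroscopic strain linearly). Infeasible candidates are
penalized, not fatal. A local flatness probe around the optimum flags
non-identifiable cases (e.g. a homogeneous chain, whose normalized
profile is constant for every p).

## Synthetic data

The generators emulate the statistical structure of the experimental
inputs with exact ground truth: intensity grids are φ_true plus
clamped Gaussian noise (sd 0.05 default); strain profiles run the
forward chain pipeline over a 0–10% stretch sweep in 2% steps with 10
fiducials and multiplicative noise (sd 1% default); tension curves
sample the unit-cell model on 30 points to 15% stretch with relative
force noise (sd 1% default); orientation fields rotate linearly in φ
from load-aligned (0°) to transverse (90°) with wrapped-normal angular
noise (sd 5° — no published orientation noise model exists, this is a
typical XRD angular spread). All generators are bit-reproducible under
a fixed seed and exactly invertible at zero noise, which the recovery
tests exploit. What they do *not* emulate: diffraction physics,
registration error between specimen and model frames, spatially
correlated noise, or sample-to-sample property variation — so passing
recovery tests demonstrate the estimators are correct and
well-conditioned on this model class, not that real XRD data are this
benign.

## Numerical choices and problem sizes

* C4 root solve: bracket expansion ×2 from [1e-12, 1], Brent to
  machine tolerance, ≤ 3 Newton polish steps (1e-10 relative).
* Chain solves: Brent on force and stretch to near-machine relative
  tolerance; invariants enforced at 1e-8.
* Default study sizes keep every workflow at desk scale: 8-layer
  grading stacks (as in the unit-cell comparison), 10-layer/10-fiducial
  chains, 61-point stretch grids, differential evolution with
  population ~12–20 and ≤ 200 generations. These reproduce all
  asserted properties; larger sizes change runtimes, not conclusions.
* Regime-boundary ties: λ̃ = 1 belongs to the slack branch, λ̃ = λ*
  to the exponential branch (values coincide under C0 continuity).
* Equality of terminal C4/λ* (which would permit the fully linear
  grading shortcut) is not special-cased: the general algorithm
  reproduces it automatically because the f-interpolation becomes
  degenerate.

## Known limitations

Single fiber family only — strongly orthotropic tissue (myocardium,
arterial wall) is out of scope. No viscoelasticity, active
contraction, damage or growth. The chain surrogate cannot reproduce
2-D/3-D strain fields or the numerical instabilities of hard
transitions in explicit FE. Distribution monotonicity is assumed
through ψ; non-monotone compositions (e.g. bone–tendon junctions)
would need a non-monotone φ with an explicitly supplied monotone ψ.
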