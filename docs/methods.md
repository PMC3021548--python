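# Methods

`polbd` simulates two coarse-grained scenarios for how bacterial DNA
polymerase I (PolI) coordinates its polymerase and 5′-nuclease (flap
endonuclease) activities on a flap-DNA substrate, and computes the
first-passage statistics that discriminate between them.

## Models

### Rigid scenario

The two active sites are held fixed: the polymerase site at the origin, the
5′-nuclease site at (7, 0, 0) nm.  The flap-DNA substrate is a point
particle with the Stokes drag of a 3-nm sphere (γ = 6πηr_D = 5.65×10⁻¹¹ kg/s
at η = 10⁻³ Pa·s), moving by overdamped Langevin dynamics in the sum of two
identical binding wells of depth U₀ and range A = 0.5 nm.  A trajectory
started at the polymerase site ends in *transfer* (entering a small capture
ball around the nuclease site) or *dissociation* (reaching 10 nm from the
origin).  The observables are the splitting probability P_n and the mean
time to either absorption T_d.

### Flexible scenario

The substrate stays put; the 5′-nuclease domain — a sphere of radius
r = 3.5 nm tethered to the polymerase domain by a 16-residue linker — moves.
Its pose is (x, y, θ): centre-of-mass position in the plane and a
counterclockwise rotation angle.  The linker acts as a Gaussian-chain
entropic spring of stiffness K = 3kBT/(Na²) = 8.56 pN/nm (N = 16,
a = 0.3 nm, kBT = 4.11 pN·nm), stretched by

    R(x, y, θ) = √((x − r·cosθ)² + (y − r·sinθ)²),

which is zero at the resting pose (r, 0, 0) and equals d at the active pose
(−r, d, π).  R may never exceed the contour length N·a = 4.8 nm.  A binding
well of depth V₀ (default 18 kBT), radial in the scaled coordinates
((x+r)/A, (y−d)/A, (θ−π)/B) with r·B = A = 0.5 nm, represents the
nuclease–flap interaction at the active pose.  The observable is the mean
transition time T_m from the resting to the active pose.  An optional
external load F_load acts along +x, by default with the lever torque
−F_load·r·sinθ (the force applies at the linker-side surface point and
resists the 0 → π rotation); `load_torque="none"` drops the torque term.

## Integration

Overdamped Langevin dynamics, per coordinate i with drag γ_i:

    γ_i dx_i = F_i(x) dt + √(2 γ_i kBT) dW_i

integrated with a two-stage stochastic Runge–Kutta (Heun) scheme: the drift
is evaluated at the state and at an Euler predictor, and averaged, with the
same Gaussian increment (variance 2 kBT dt/γ_i) in both stages.
Euler–Maruyama is available for cross-checks; the two agree within sampling
error at the default step.  The default dt = 2×10⁻⁵ µs (0.02 ns) is about a
tenth of the stiffest well relaxation time γ/(U₀/A²) at 20 kBT; a guard
(`engine.check_stability`) flags steps above γ/(10·k_max).

Drag coefficients: translational 6πηr, rotational 8πηr³ (Stokes sphere;
γ_rot/(γ_trans·r²) = 4/3 identically).  The rotational drag at r = 3.5 nm is
1.0776×10⁻⁹ kg·nm²/s; a close published variant (1.0766×10⁻⁹) differs by
0.1% and is treated as a transcription slip.  Internal units are nm, pN,
pN·nm and µs, keeping every quantity O(10⁻²–10²).

Production ensembles run in numba-compiled kernels with an inlined
xorshift64*/Box–Muller normal generator (validated by moment and
Kolmogorov–Smirnov tests and about 7× faster inside compiled loops than the
library RNG).  Each replicate draws its own stream seed from a
`numpy.random.SeedSequence` of the master seed, so ensembles are exactly
reproducible and independent of batching.  The generic numpy integrator
(`engine.srk2_step`, `engine.simulate_first_passage`) is the reference
implementation; tests verify the kernels' forces and outcome statistics
against it.

## Constraints as reflecting walls

Two hard constraints apply to the flexible model, both enforced by
rejecting (redrawing the noise of) any step whose end state violates them:

* **Extensibility cap** R ≤ N·a = 4.8 nm — the linker is inextensible past
  its contour length.
* **Rotation range** θ ∈ [−π, π] — the linker cannot wrap around the
  domain, so the active pose at θ = +π is approached counterclockwise only.

The second constraint is a modelling decision this package makes
deliberately: with an unbounded rotation coordinate the angle performs a
free one-dimensional random walk whose first-passage time has a divergent
mean (heavy-tailed arrival times, means that depend on the censoring
horizon).  Finite, single-exponential transition times — which this system
exhibits — require a compact rotational state space.  Physically, rotations
beyond one turn are sterically excluded because the tether would wind
around the domain.

## Binding-well shapes

The per-coordinate forms of the binding wells are not uniquely determined
by the available descriptions, so the wells are pluggable.  Two shapes are
provided with equal depth and equal bottom curvature 2·depth/A²:

* `morse` (rigid default): w(ρ) = depth·[(1 − e^(−ρ/A))² − 1], a
  Morse-style profile with an exponential tail;
* `gaussian` (flexible default): w(ρ) = −depth·e^(−(ρ/A)²), short-ranged.

Escape statistics depend mainly on depth, but the residual shape dependence
is not negligible: at U₀ = 16 kBT the two forms give T_d = 99 µs (morse)
versus 129 µs (gaussian) — a 30% prefactor spread that should be read as
the irreducible form uncertainty of this class of model — while the
splitting probability differs more strongly (P_n(20 kBT) = 0.114 vs 0.047)
because capture at the distant site is controlled by the attractive tail.
The Morse default reproduces the expected P_n ≈ 0.11 and the slow growth of
P_n with U₀; its T_d at 16 kBT sits below the ~133 µs sometimes quoted for
this scenario, which lands between the two forms.  For the flexible model
the well mostly acts as a funnel at the target, T_m is insensitive to both
V₀ (< 25% across 12–24 kBT) and the form, and the short-ranged Gaussian is
the default.

## Deterministic oracles

For the rigid model the splitting probability and the MFPT solve
backward-Kolmogorov boundary-value problems,

    ∇·(w ∇q) = 0,          w = e^(−U/kBT),  q = 1 on capture, 0 at 10 nm,
    D ∇·(w ∇T) = −w,       T = 0 on both absorbing sets,  D = kBT/γ,

discretised by second-order finite volumes.  Both wells lie on the x-axis,
so the 3D problems reduce exactly to the axisymmetric (x, ρ) half-plane;
the flux form uses face-centred conductances w·ρ and the spherical
absorbing surfaces enter through cut cells (Dirichlet value placed at the
true surface distance along each grid axis).  At the default spacing
h = 0.05 nm the solver reproduces the concentric-sphere committor and the
free-diffusion MFPT closed forms to better than 0.05%, and halving h moves
P_n and T_d by under 1%.  BD ensembles agree with the solves within
sampling error, which ties the stochastic engine to an independent
deterministic route.

## First-passage statistics

Ensemble summaries report the splitting probability with a Wilson interval
and the mean FPT with a seeded percentile-bootstrap CI (default 2000
resamples, 90% level; coverage verified at 85–95% over 500 synthetic
ensembles).  Timeouts are excluded from the plain mean with a censoring
warning above 1%; for heavily censored ensembles (large loads) the
censored-exponential MLE — total observed time divided by completions — is
the preferred estimate, justified by the single-exponential shape of the
transition-time distribution, with the distribution-free survival-integral
bound E[T] ≥ ∫₀^τ S(t)dt as fall-back.  Exponential goodness-of-fit uses a
parametric-bootstrap KS test (the rate is estimated from the sample).

Parameter sweeps reuse the same per-replicate noise streams at every grid
point (common random numbers), which cancels most replicate-level noise in
across-grid comparisons; this matters for the shallow minima of T_m over d
(≈ 4% deep) and over K (≈ 2% deep).  Because those basins are flat at the
sub-percent level between adjacent grid points, the raw grid argmin flips
between neighbours from seed to seed even with common random numbers; the
reported minimiser (`flexible_model.basin_minimizer`) is therefore the
vertex of a quadratic fitted through the basin — all grid points within 10%
of the smallest mean — snapped to the nearest grid value, which is stable
across seeds and a more efficient estimator of the same quantity.  Sweep
tables still carry the raw argmin flag.

## Problem sizes and defaults

Replicate counts are not prescribed by the scenario definitions; defaults
are 300 per grid point in the experiment harness (bootstrap CIs make
under-replication visible), 200–400 in the headline recomputations
(`scripts/acceptance.py`), and smaller seeded ensembles in the test suite.
The in-suite Kramers check sweeps 1D barrier heights of 8–11 kBT against
the exact double-integral MFPT and verifies the thermal slope over 8–14 kBT
on the exact values; escape-time sweeps of the rigid landscape use the MFPT
solve, which is the cheaper exact route.  Temperature sweeps (10–50 °C) use
a PCHIP interpolant of a standard water-viscosity table and recompute kBT,
all drags and the entropic K at each temperature; fixed-temperature runs
pin η = 10⁻³ Pa·s.

## What the models do and do not capture

These are strongly coarse-grained models: point/sphere bodies, pluggable
phenomenological wells, no hydrodynamic interactions or shape-dependent
drag, no electrostatics beyond the Debye-scale well range, no chemistry
(the simulation ends at arrival, before cleavage), and no z-motion by
default (enabling it shifts T_m by less than sampling error).  Their
robust outputs are ratios and orders of magnitude — T_m ≪ T_d across the
studied regime, the existence of an optimal tether geometry and stiffness,
exponential load sensitivity — not absolute times beyond the ~30% form
uncertainty discussed above.
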