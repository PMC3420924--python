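# Methods

## Collective variables and reference geometry

Two membrane-embedded protomers are reduced to three collective variables:
the COM separation `r` (nm) and the rotational angles `θa`, `θb` (rad), the
arccosines of the inner products of normalized in-plane projections of
(interface-group COM − bundle COM) and (partner COM − own COM).  Angles are
therefore non-periodic and live on [0, π].  COMs use uniform weights by
default (coarse-grained beads have near-equal masses); per-point masses are
accepted.  `r` is the full 3D COM distance by default with an in-plane
option — both protomers sit in the same bilayer plane, so the two
conventions differ by well under the histogram bin width for any realistic
tilt, and nothing downstream depends on the choice.  The membrane plane is
the plane orthogonal to a user-supplied unit normal (default z).

## Synthetic dynamics

The sampling engine integrates **overdamped Langevin (Brownian) dynamics**
of the CV triplet with the Euler–Maruyama scheme: per CV,
Δx = −(D/kT)·∂U/∂x·Δt + √(2DΔt)·ξ.  Inertia is deliberately absent: CV
dynamics in coarse-grained membranes are diffusive, and only stationary
statistics matter for free-energy recovery.  Units are kcal/mol, nm, rad,
ps throughout the sampling layer.

Defaults (one value per choice, with the reason):

| parameter | default | why |
|---|---|---|
| temperature | 300 K (kT = 0.5962 kcal/mol) | reproduces the K_D→ΔG_X° conversions of the reference table within rounding |
| diffusion constant | 5×10⁻⁴ nm²/ps (rad²/ps) | protein-scale lateral diffusion; only the sampling rate, not the FES, depends on it |
| timestep | 0.005 ps (pipeline) | keeps D·k_eff·Δt/kT ≲ 0.02 for the stiffest umbrella + well curvature; the Euler–Maruyama stationary distribution carries an O(Δt) bias that is measurable at 4× this step (≈0.6 kcal/mol on a 12 kcal/mol well) and negligible here |
| divergence guard | 1 nm (rad) per step | a step this large only occurs when Δt is too big for the forces present |

Seeding: one master seed; per-window seeds are derived as
`master + 7919·(index+1) mod 2³¹`, so windows are independent but the whole
run is reproducible bit-for-bit.

The model potentials are sums of axis-aligned Gaussian wells plus optional
harmonic terms and quartic confining walls, over an explicit rectangular
domain; the exact angle-marginal F(r) is computed by trapezoid quadrature
over a stated angular box, normalized so that F = 0 where U = 0.  The two
presets place a single dimer well at r = 3.7 nm / −12.0 kcal/mol (TM1/H8)
or r = 3.45 nm / −4.8 kcal/mol (TM4/3), flat beyond the monomeric range,
with shallow (0.05 kcal/mol) angular minima near the published Θ locations.
The angular corrugation is kept shallow on purpose: the potential value at
the global minimum and the angle-marginal depth then agree to < 0.05
kcal/mol, so "well depth" is unambiguous.  A deep angular well would split
those two numbers by its binding-entropy term.

## Biasing

Per window: harmonic umbrella ½k(r−r_i)² with k = 2400 kcal/(mol·nm²);
well-tempered metadynamics on (θa, θb) with initial height 0.12 kcal/mol,
σ_M = 0.035 rad, stride 10 ps, bias factor γ = 15; hill heights follow
w = w₀·exp(−V/((γ−1)kT)).  Inside the integrator the bias is accumulated on
a grid (0.01 rad) holding the value and its analytic gradient, with hills
truncated at ±6σ; the analysis-side `metad_bias` does exact direct
summation (matches a brute-force oracle to 10⁻⁹) so the cached grid is an
optimization, not a definition.

Angular walls are quartic, κ·(excess)⁴ with κ = 10⁴ kcal/(mol·rad⁴) by
default.  Note the thermal penetration depth of a quartic wall is
(kT/κ)^¼ ≈ 0.09 rad at the default stiffness, so the *effective* sampled
angular box is slightly wider than the nominal [minθ, maxθ].  This widening
is r-independent and cancels from F(r) after referencing; it does mean the
nominal ‖Ω₀‖ = (maxθ − minθ − σ_M)² is an approximation to the truly
sampled area.  ‖Ω₀‖ is computed as the exact square — a 0.46 rad effective
range gives 0.2116 rad², not the rounded 0.22 sometimes quoted.

Window layout: uniform ladder over the configured r range (48 windows by
default); a diagnostic reports the Σmin histogram overlap of adjacent
windows and warns below 5%.  Extra windows can be inserted by configuration
where the reweighted distribution is insufficiently sampled.

## Reweighting and WHAM

The metadynamics bias distorts the r distribution within each window.
Frame weights ∝ exp(+β[V(θ(t), t) − c(t)]) restore the umbrella-only
ensemble; V is replayed from the hill log on a grid, and the running offset
c(t) is recomputed at every deposition from the evolving bias using the
well-tempered identity F ≈ −γ/(γ−1)·V:

    c(t) = kT · ln[ Σ exp(βγV/(γ−1)) / Σ exp(βV/(γ−1)) ]

(sums over the bias grid).  Constants added to the bias cancel exactly
between V and c.  Time-averaged versus final-bias weighting is not
distinguished by the sources; the running-offset estimator above is used
because it makes weights well defined at every frame time.

Binned WHAM then solves the usual self-consistency equations in log space.
The window free-energy constants are first minimized through the convex
WHAM likelihood (L-BFGS), then polished by direct iteration until the
largest change is < 10⁻⁸ kcal/mol (cap 10⁵ iterations; failure raises with
the residual).  Disconnected window sets (no shared sampled bins) are
rejected.  Bin width is 0.02 nm (0.02 rad for angle grids) — small against
every feature width used.  The first 5% of each window is discarded as
equilibration (configurable).

F(r) is the plain −kT·log of the r histogram, with **no 2πr Jacobian
removal**; the geometric 2πr measure enters only in the K_D integral.  This
keeps the profile convention and the dimerization-constant integral
mutually consistent, and is validated independently by a two-particle
Brownian simulation in a box whose bound fraction matches the mass-action
prediction from K_D.

The angular FES at a fixed r slice reuses the metadynamics weights and
divides out each frame's WHAM-consistent biased density (the umbrella acts
as an external potential), then offsets the surface to min 0.  Local minima
below a threshold are labeled Θ1, Θ2, … in depth order.

## Errors

Moving-block bootstrap over frames within each window, block length = the
integrated autocorrelation time of r (initial-positive-sequence estimator),
with the full reweight+WHAM+reference pipeline re-run per replica
(16 replicas in the pipeline default, 50 in the standalone API).  Profile
errors are per-bin standard deviations across replicas; confidence
intervals on K_D/K_X/ΔG_X° are 2.5/97.5 percentiles across the same
replicas (or Gaussian per-bin perturbations when only standard errors are
available).  These are honest sampling errors of this pipeline; they are
not claimed to coincide with any particular published analytic
error-combination scheme.

## Thermodynamics and kinetics

With the monomeric reference at F = 0 and r_D the largest separation
counted as dimeric (default: the lower edge of the reference range),

    K_D = (‖Ω₀‖/(2π)²) · ∫₀^{r_D} 2πr e^{−βF(r)} dr · 10⁻⁶  [µm²]

by trapezoid quadrature on the profile grid with linear interpolation.  The
(2π)² is the full rotational space of the two protomers, of which only Ω₀
was sampled; this normalization reproduces the reference conversions
(e.g. F_min = −12.0 kcal/mol with an ≈0.1 nm well width gives K_D of order
7 µm², while omitting the factor misses by orders of magnitude).
K_X = (N_L/A)·K_D with N_L/A = 1.65×10⁶ µm⁻² by default, and
ΔG_X° = −RT ln K_X with RT = 0.5962 kcal/mol at 300 K.

Kinetics uses the long-time 2D Smoluchowski capture rate

    k_on = 4π D_C / [ln(4 D_C t / R²) − 2γ_EM]

with D_C the summed protomer diffusion constants, R the contact radius (the
source wording "sum of the protomer ratios" is treated as a typo for
radii), t the experimental diffusion timescale and γ_EM the
Euler–Mascheroni constant; the rate is only defined for
4D_C t/R² > e^{2γ_EM}.  D_C, R and t must be supplied — they are not
derivable from the free-energy calculation, so lifetimes are reported only
when the user provides them.  Dissociation is k_off = k_on/K_D.  Dimer
decay follows mass action d' = k_on m² − k_off d with m = m_tot − 2d
(re-association included; the closed Riccati solution is cross-checked
against numerical integration), and the half-life is the time at which the
density first reaches [D]₀/2 — undefined (and reported as such) when the
equilibrium density sits above that target, which is exactly the
strong-association regime.

## What the synthetic generator does and does not show

The generator reproduces the *statistical structure* the analysis depends
on: diffusive CV dynamics, a deep dimer well with a flat monomeric region,
restrained angular sampling, realistic bias parameters, autocorrelated
frames.  It does not contain bead-level interactions, lipids, solvent
exchange at the interface, CV-dependent diffusion, or hidden slow degrees
of freedom orthogonal to the CVs.  Passing tests therefore demonstrate that
the reweighting/WHAM/conversion machinery is correct and self-consistent —
not that any particular molecular system is converged; on real trajectories
the usual convergence diagnostics (window overlap, hill-height decay,
multiple angular transitions per window) still have to be checked, and the
package logs them per window.

## Problem sizes in the shipped validation studies

The known-potential study uses 12 umbrella windows × 10⁵ steps (combined
and umbrella-only) and a single 10⁶-step run (metadynamics-only) on a 2D
potential, reconstructing F(r) to within 0.5 kcal/mol of quadrature by all
three routes.  The full parameter-recovery study runs the production
defaults (48 windows × 4×10⁵ steps, 16 bootstrap replicas) on the deep
TM1/H8-like preset; these sizes give a bootstrap CI of a few tenths of a
kcal/mol on ΔG_X°, which is the regime where the comparison against the
exact quadrature value is informative.

## Known limitations

* The Euler–Maruyama stationary bias grows with D·k_eff·Δt/kT; users who
  stiffen the umbrellas or raise D should shrink the timestep accordingly
  (the integrator raises only on outright divergence, not on subtle bias).
* Quartic walls at the default stiffness admit ~0.09 rad of thermal
  penetration; ‖Ω₀‖ built from the nominal wall positions is then a few
  tens of percent below the effectively sampled area, a systematic common
  to both the synthetic study and its exact reference but worth remembering
  when quoting absolute K_D values.
* WHAM assumes within-window equilibrium after the discarded equilibration
  fraction; no automated equilibration detection is attempted.
* The angular FES inherits the statistical noise of a single r slice; its
  minima list is meaningful only down to the noise floor (the pipeline
  reports at most the five deepest below 1 kcal/mol).
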