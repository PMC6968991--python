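# Methods

## Model

The simulator integrates the non-dimensional five-field system stated in
the README: logistic stroma killed by acid at strength δ; two
Lotka–Volterra-competing tumour phenotypes with shared growth rate ρ_T,
shared mobility Δ_T and stromal inhibition c_S; acid produced by T_A and
cleared at rate ρ_L, diffusing freely; and non-diffusing matrix degraded
by T_M at rate κ. Matrix obstructs tumour movement as a linear flux
reduction, D(M) = Δ_T (1 − M), vanishing at full matrix density. Stroma
and matrix have no transport terms: their equations are pointwise ODEs
coupled to the neighbours only through the diffusing fields.

Assumptions worth keeping in mind: the two phenotypes are biologically
identical apart from their specialist traits (equal ρ_T, carrying
capacity and Δ_T); tumour cells are acid-resistant; matrix never
regenerates and is not attacked by acid; parameters are constant in time
(no phenotypic evolution). Dimensional inputs can be converted with
`nondimensionalise`; the dimensional system itself is never integrated.

## Parameters

| group | default | meaning |
|---|---|---|
| δ | 12.5 | stromal death per unit rescaled acid (δ > 1 ⇒ acid can clear stroma) |
| ρ_T | 1 | tumour/stroma growth-rate ratio |
| Δ_T | 4×10⁻⁵ | tumour/acid diffusivity ratio |
| ρ_L | 70 | acid turnover rate; sets the acid penetration depth 1/√ρ_L ≈ 0.12 |
| κ | 10 | matrix degradation rate |
| c_S | 1.5 | stromal competition on both phenotypes (c_S > 1 ⇒ stroma blocks establishment) |
| c_M,A, c_A,M | 0–2 | inter-species competition, swept in experiments |

One time unit is 11.57 days, one length unit 2.24 cm (`UnitScales`);
these printed scales are taken as given rather than recomputed from
dimensional rates. Constructors warn (but do not fail) when δ ≤ 1 or
c_S ≤ 1, where downstream stability statements lose their preconditions.

## Initial data and the step convention

Initial interfaces use the compactly supported smoothed step
f(x; σ, ω) (plateau 1, C∞ shoulder of width ω, then 0). Tissue fields
start as 1 − f with σ_tissue = 0.2; tumour and acid fields as f with
σ_tumour = 0.1; ω = 0.1.

Two placements of the shoulder are supported. The default, `"plateau"`,
keeps the plateau up to σ and puts the shoulder on [σ, σ + ω): the
matrix density then rises to 1 only at x = 0.3, and the long-horizon
single-population controls stall at x ≈ 0.31 (acid-producers, blocked
where M = 1) and x ≈ 0.23 (matrix-degraders, blocked by established
stroma). The alternative `"support"` places the entire step, shoulder
included, inside [0, σ); the same controls then stall at ≈ 0.21 / 0.13.
The plateau convention is the default because it reproduces the
reference stall positions (0.3 and 0.2) that anchor the single-population
phenomenology; the choice shifts all interfaces by one ω and nothing
else. Absent populations are represented by presence flags, not by
degenerate step parameters.

## Discretisation and time integration

Space: 200 equi-spaced points on [0, 1] (h = 5×10⁻³) by default. The
flux divergence ∂x(D ∂x u) uses the conservative three-point stencil
with interface coefficients (D_r + D_r±1)/2; for constant D it reduces
to the standard Laplacian, and it is second-order accurate (verified on
a manufactured solution). Zero-flux boundaries reflect ghost values of
both u and D, which preserves the discrete conservation of the pure
diffusion operator exactly (trapezoidal mass of dL/dt ≡ 0).

Time: the method-of-lines system (5 × n unknowns) is advanced by a
variable-order implicit multistep (BDF-type) integrator with rel/abs
tolerances 1×10⁻¹⁰ by default. A conservative Jacobian sparsity pattern
(all five fields coupled at a point; nearest-neighbour coupling for the
diffusing fields and, through D = 1 − M, for the matrix) keeps the
implicit solves cheap. Integration is deterministic; repeated runs are
bit-identical.

Two regularisations address the non-negativity of densities:

- **Negativity guard.** A linear restoring term −λ(u + θ) is added
  wherever a field falls below −θ (λ = 100 by default). The restoring
  form keeps the right-hand side continuous, which the implicit
  integrator needs; hard clipping is deliberately avoided. The small
  engagement deadband θ matters: a kink located exactly at zero lets the
  integrator amplify rounding-level chatter of fields that sit at
  exactly zero (observed growth from 10⁻²³ towards 10⁻¹⁰ within a few
  time units); engaging the guard a hair below zero removes the
  amplification while still restoring genuine undershoots.
- **Extinction floor.** The autocatalytic reaction terms of S, T_A and
  T_M are switched off where the local density is below θ = 10⁻¹²
  (configurable). The continuum solution keeps a population at exactly
  zero beyond a fully obstructing matrix barrier (zero mobility blocks
  all flux), but the linear algebra inside any implicit solver deposits
  rounding-level values there; in regions where the acid has already
  cleared the stroma those seeds would otherwise grow logistically and
  fake an invasion. The floor is orders of magnitude below solver
  tolerance and any meaningful density; its only measurable effect on
  resolved fronts is the generic pulled-front cutoff correction, below
  one percent at θ = 10⁻¹².

Tolerance and resolution sensitivity: relaxing tolerances from 10⁻¹⁰ to
10⁻⁸ changes stall positions and sweep fronts by well under 10⁻³, and
the sweep grid of 100 points changes fronts by under 10⁻², which is why
the sweep-scale drivers default to 10⁻⁸ and the suite's large sweep uses
100 points. The coexistence front speed is the most
discretisation-sensitive quantity (0.0067 at 200 points, 0.0059 at 800):
the front width √(Δ_T/ρ_T) ≈ 0.006 is of the order of one grid cell at
the reference resolution, a property inherited from the underlying
parameter set.

## Steady states and stability

SS0–SS6 are coded in closed form. Two printed-form subtleties: the
coexistence state SS3 has T_A = (1 − c_M,A)/(1 − c_M,A c_A,M) but
T_M = (1 − c_A,M)/(1 − c_M,A c_A,M) (the components differ whenever the
competition is asymmetric; the residual test enforces this), and SS6
degenerates to a one-parameter family exactly at (1, 1). States that
retain matrix (SS0, SS1, SS4) leave M free; they carry a structural zero
eigenvalue because no kinetic term depends on M, so stability is also
reported restricted to the (S, T_A, T_M, L) subspace. Stability is
computed numerically from the analytic Jacobian (eigenvalue real parts
against a zero tolerance of 10⁻⁸); no symbolic eigenvalue algebra is
attempted.

Threshold location bisects the leading non-matrix eigenvalue along a
competition path to 10⁻⁶. On the symmetric path and along c_A,M the SS3
boundary sits exactly at 1, and the SS1 stability onset at c_A,M = 1.
Along c_M,A (with c_A,M = 0.5) the boundary is *not* 1: the
stroma-reinvasion eigenvalue 1 − δ T_A* crosses first, at the root of
δ(1 − c)/(1 − c/2) = 1, i.e. c = 23/24 ≈ 0.9583 at default δ. The
common statement "coexistence is stable iff both c < 1" implicitly
assumes the acid supply δ T_A* stays above 1, which fails on this path.

## Metrics

The front position is by default the rightmost threshold crossing of a
species density at ε = 10⁻², linearly interpolated between grid nodes,
with "either" taking the rightmost of the two species fronts; an absent
population (never reaching ε) is reported as a distinct marker, not as
position 0. An alternative tracker uses the location of the extremal
time-derivative magnitude; both are recorded in sweep tables because
derivative-based edge definitions are ambiguous for stalled or receding
fronts (a threshold is monotone in ε and robust). Tumour mass is the
trapezoidal integral of T_A + T_M; populations with species integral
below 0.1 (strict) are flagged "disregard" in sweep summaries. Speeds
are front displacements per time over a snapshot window; conversions use
the unit scales above (speed × 2.24/11.57 cm/day).

## Experiments

- **Single-population controls**: t_end = 10,000 with one presence flag
  off; report the front time series and stall position.
- **Competition sweep**: one integration per (c_M,A, c_A,M) on a
  configurable grid of [0, 2]², t_end = 50; per-record failures are
  recorded, not fatal. The regime label (coexistence / exclusion /
  bistable / boundary) comes from the steady-state analysis, and at
  desk scale the simulated outcomes match it away from the thresholds
  (|c − 1| ≥ 0.1; exclusion sets in too slowly to complete by t = 50
  closer to the boundary).
- **Snapshot runs** classify outcomes with documented constants:
  extinction = species integral < 10⁻³, halted = front displacement
  < 0.01 over the final 10 time units.
- **Perturbation study** at (1.7, 1.7): multiplicative uniform noise of
  amplitude 10⁻² (seeded, recorded) on the tumour initial fields, or a
  "placed slightly apart" variant seeding the phenotypes in disjoint
  adjacent regions split at σ_tumour − offset. The split form is used
  because a plain translation of one profile ends in competitive
  exclusion of the displaced species rather than the persistent
  parapatric bands the side-by-side seeding produces. Separation is
  declared when the occupied domain contains both a zone with > 95 %
  acid-producer dominance and one with > 95 % degrader dominance.
- **κ sensitivity**: the sweep repeated across matrix-degradation rates,
  summarised by the mean signed front difference between mirrored
  sub-unit pairs (a, b)/(b, a) — the degradation bottleneck makes
  invasion favour degrader-weighted mixtures, and the statistic varies
  with κ.

## What the defaults do and do not show

The default configuration *is* the study condition (Table-defaults
parameters, the stated step geometry, 200-point grid): there is no
separate synthetic-data layer. Perturbation noise is the only stochastic
ingredient and is always seeded. The 1-D domain, equal-phenotype
simplification, absence of matrix regeneration, haptotaxis and acid
attack on ECM mean quantitative front positions and speeds should be
read as model properties, not clinical predictions; in particular the
coexistence front speed at the default parameters is ≈ 0.0067
dimensionless (≈ 0.47 cm/year), about half the matrix-free Fisher limit
2√(Δ_T ρ_T) ≈ 0.0127 (≈ 0.90 cm/year), which the solver reproduces to
0.5 % when started with M ≡ 0. Runs are only meaningful while the front
stays clear of the right boundary (front ≲ 0.9 at default horizons).

## Problem sizes used in the shipped checks

Stall controls: 200 points, t_end = 10,000, tolerance 10⁻⁸. Speed
measurement: 200 points, tolerance 10⁻¹⁰. Sweep: 20×20 on 100 points at
10⁻⁸. Threshold bisections: exact closed-form states, 10⁻⁶ brackets.
Property checks (conservation, convergence order, oracle equivalence,
Jacobian-vs-finite-differences) run on small grids of 17–401 points.
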