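# Methods

`tumoreq` predicts the residual mass of an immune-controlled tumor in its
equilibrium (dormancy) phase, where immune killing exactly balances tumor
proliferation. This note records the models, the numerical choices, and the
limits of what the tests demonstrate.

## Model overview

Two compartments are coupled through scalars only:

* **Tumor compartment.** A size-structured density n(t, z) of tumor cells
  (z = cell volume, μm³) grows at rate V(z) and divides through a kernel
  k(z | z′) with rate a(z). Without immune pressure the population grows like
  e^{λt} with size profile N̄(z), the leading eigenpair of the growth-division
  operator.
* **Immune compartment.** On a disk Ω (radius in mm) the effector-cell
  concentration c(t, x) diffuses (D), drifts up the gradient of a
  chemoattractive potential Φ (strength χ, scaled by tumor mass μ₁), dies at
  rate γ and is recruited at rate μ₁R. The potential solves
  −KΔΦ = σ − ⟨σ⟩ with zero-flux boundary; σ and the killing weight δ are
  centered Gaussians with amplitudes A_σ, A and widths θ_σ, θ.

The tumor feels the immune system only through the size-uniform death rate
μ̄_c = ∫δc dx. The equilibrium is the mass μ₁ for which the stationary immune
field yields μ̄_c = λ. It is computed in two steps ("power-dichotomy"):
inverse power iteration for (λ, N̄), then bisection on μ₁ for the stationary
constraint.

## Size discretization

The size axis [0, R_max] is cut into I uniform cells of width h. By default
unknowns sit at **cell centers** z_i = (i − ½)h and upwind fluxes
F_i = V_{i+1/2} N_i at the right faces; the inflow boundary N(0) = 0 enters as
a ghost value at z = 0, so every row of the operator is a flux-balance row:

    (T_Λ N)_i = F_i − F_{i−1} + h(Λ + a_i) N_i − h² Σ_{j≥i} a_j k(z_i|z_j) N_j.

A node-aligned variant (z_i = ih) and a variant that replaces the first row
with a hard Dirichlet condition N_1 = 0 are available
(`SizeGrid(centered=False)`, `assemble_shifted_operator(boundary="dirichlet")`).
The centered/ghost combination is the default because it is the one whose
first-order error constants agree, case by case and grid by grid, with the
analytic-eigenpair validation tables this solver is checked against; the
Dirichlet row effectively moves the boundary condition from z = 0 to z = h and
roughly triples the profile error constant.

**Division kernels.**

* *Binary (mitosis) kernel*, k(z|z′) = 4δ(2z − z′): two daughters of half the
  mother's volume (the factor 4 = 2 daughters × Jacobian preserves mass). On
  centered grids the Dirac mass is mollified by a Gaussian whose standard
  deviation defaults to **one grid step**: sampling a Gaussian on a uniform
  grid is a midpoint rule, whose error decays like e^{−2π²(w/h)²}, so w = h
  already balances division gain and loss to ~10⁻⁹ while adding a smoothing
  bias of order (w·a/V)² to the profile; this width reproduces the reference
  error tables. On node grids the exact index mapping 2z_i = z_{2i} is used
  instead (`MitosisKernel(mode="direct")`), which is impossible on centered
  grids (2z_i is never a center).
* *Uniform kernel*, k(z|z′) = 2/z′ on [0, z′]: two daughters uniform on
  (0, z′). Some presentations print this kernel as 1/z′, which violates the
  mass-conservation identity ∫z·k(z|z′)dz = z′ (it yields z′/2) and is
  inconsistent with the closed-form eigenpairs used for validation
  (λ = √(a₀V₀) for V constant, a = a₀z; λ = V₀ for V = V₀z, a = a₀zⁿ); the
  implementation uses the mass-conserving two-daughter form throughout.
* *Tabulated kernel*: any callable k(z, z′), truncated to z ≤ z′.

The gain integral uses the plain rectangle rule h·Σ exactly as in the
operator definition; no higher-order quadrature is applied, so the published
first-order error tables are reproducible. (A better rule would raise the
convergence order but change those constants.)

**Shift selection.** The operator is shifted by Λ so that its inverse is
positive and compact-like; the rigorous bound is

    Λ > ‖V‖_∞ / min|V_{j+1/2}| · max_k (h Σ_{j≥k} a_j k(z_k|z_j)) − min_j a_j,

and `choose_shift` uses 1.05× this value. When V vanishes at z = 0 (e.g.
V = V₀z) the velocity ratio blows up like 1/h and would make the fixed shift
uselessly large (the inverse-power convergence factor approaches 1); if the
full bound exceeds 20× the bound with the velocity ratio collapsed to one,
the collapsed value is used. This fallback is outside the hypotheses of the
invertibility bound (which require V bounded below), but the iteration is observed to
remain contractive and the computed eigenvalues converge at first order to
the closed forms.

**Inverse power iteration.** The matrix is factorized once. It is upper
Hessenberg (upper triangle + one subdiagonal), so the dense path uses an
O(I²) unpivoted elimination with a unit lower-bidiagonal L — the diagonal
V_{i+1/2} + h(Λ + a_i) dominates for admissible shifts — and LAPACK
triangular solves; the sparse path (mollified mitosis kernel: a band around
j = 2i) uses SuperLU. Iterates q ← T⁻¹(hN), N ← q/‖q‖₂ start from a
uniform-random positive vector (seeded; the eigenvalue is seed-independent)
and stop when the sup-norm relative change drops below ε (default 10⁻⁶). The
eigenvalue is recovered as λ = Λ − 1/μ with μ = (q·N)/(N·N) the Rayleigh
quotient of the h-rescaled resolvent — the matrix rows carry an overall
factor h, so the resolvent must be rescaled by h for this inversion formula
to hold; the solver does this by solving T q = hN. Defaults: R_max chosen so
the analytic profile at R_max is < 10⁻¹⁰ of its peak (5 in the dimensionless
validation cases, 6·10⁴ μm³ at the biological rates); sign fixed so the
vector sum is positive; converged vectors with negative entries beyond
10⁻⁸ of the peak raise (shift too small), tiny undershoots are clipped.

## Radial field solvers

With centered Gaussian forms, constant influx R and a disk domain, the
stationary problem is radially symmetric, so both PDEs reduce to 1-D radial
finite volumes on M uniform cells (areas 2πr·dr; M = 100 by default — the
drift-free closed-form comparison shows second-order accuracy, ~2·10⁻³
relative at M = 100). The potential equation subtracts the discrete disk
average of σ (making the Neumann problem solvable), pins one unknown, and
re-gauges the solution to zero disk mean. The concentration equation upwinds
the advective flux by the sign of the face drift velocity −μ₁χ∂_rΦ and
imposes C = 0 on the outer boundary through a half-cell diffusive flux; the
resulting tridiagonal system is an M-matrix, so C ≥ 0 without fixes. The
r = 0 face has zero area (regularity). The induced death rate is the
area-weighted quadrature μ̄_c = Σ δ(r_m) C_m · 2πr_m dr.

## Equilibrium search

Φ is computed once. Bisection runs on I(μ₁) = ∫δC_{μ₁} − λ, replacing the
lower end when I < 0, until (μ_b − μ_a)/μ_a < ε_d (default 10⁻⁸, matching
the agreement level of the evolution cross-check). The default bracket
(10⁻¹⁰, 10) mm³ expands geometrically ×10 per side up to 6 times when it
does not straddle the root; μ̄_c(μ₁) is strictly increasing (checked
numerically over every sweep in the tests), so the root is unique. A Newton
variant is deliberately not implemented: it costs extra stationary solves
per step without improving the answer. Masses are reported both as μ₁ (mm³)
and as the equivalent-sphere diameter d = (6μ₁/π)^{1/3} — a reporting
convention, not a model statement.

## Coupled evolution

The time integrator exists to validate the stationary machinery: transport,
division and immune killing on the size axis are stepped explicitly (the
same upwind flux and division quadrature as the eigenproblem), with dt
automatically reduced to satisfy dt ≤ 0.9·h/max V; the stiff immune equation
is stepped by backward Euler (unconditionally stable), reusing the
stationary operator; Φ stays fixed and μ₁(t) scales the drift and the
source. The splitting is first order, but the coupled fixed point of the
scheme is *independent of dt*: at stationarity the size update enforces
L_h n = μ̄_c n and the implicit step enforces the discrete stationary immune
equation — the identical systems the power-dichotomy procedure solves on the
same grids. The observed evolution-vs-prediction discrepancy E_μ1 ~ 10⁻¹⁰ is
therefore limited only by the bisection tolerance and the finite horizon.
Relaxation to equilibrium is an underdamped oscillation with frequency
≈ √(γλ) and damping ≈ γ/2; at the default γ = 0.02/day the tests integrate
to 2500–3000 days to push the residual drift below 10⁻⁵ (quasi-stationarity
is asserted over the last 10% of the horizon before any comparison).
Default initial data: one cell of volume 14137.2 μm³ (sphere of radius
15 μm), no immune cells.

## Sensitivity analysis

The equilibrium mass is treated as a function of eight independent inputs:
log-normal a (meanlog ln 0.12, sdlog 0.2) and R (meanlog ln 2.2·10⁻⁶, sdlog
0.84), uniform A ∈ [2, 57.6], χ ∈ [86.4, 8.64·10⁶], D ∈ [8.64·10⁻⁵, 10⁻³],
A_σ ∈ [5, 6.25]·10⁻¹⁷, γ ∈ [0.02, 1], K ∈ [0.01, 1]. (The cohort model
estimates a correlation between a and R; the sensitivity analysis treats all
eight inputs as independent, sampling the marginals — the Sobol decomposition
assumes independence.)

Because μ₁ is close to log-normal over this space (a distribution not
determined by its moments, hence not gPC-expandable), the surrogate is built
for ln μ₁. Every marginal is mapped through its CDF to the uniform cube —
log-normals truncated at their 0.1%/99.9% quantiles so the cube is bounded —
and a single basis of products of orthonormal Legendre polynomials serves
all inputs: total degree ≤ 5 and at most 2 inputs interacting per term,
giving 321 terms and a 2× oversampled Latin-hypercube design of 642 model
runs. Coefficients come from least squares; the relative leave-one-out error
(hat-matrix identity) is ~0.5% at the defaults. Each design run is a full
stationary solve (drift included), ~5 ms.

Sobol indices are computed on f = exp(surrogate) — exponentiation breaks
polynomial orthogonality, so they cannot be read off the coefficients — by
two-sample pick-freeze Monte Carlo: V̂_i correlates f(A-sample) with f at the
B-sample whose i-th column is frozen to A's; pairs likewise (subtracting the
singles); totals via Ŝ_T(i) = 1 − V̂_{−i}/V̂. Default N = 10⁵ keeps the
full first/second/total set under a minute; the ranking (not the digits) is
the reproducible output, and it is stable across seeds at this N. With the
default form-function widths the ranking reproduces the expected hierarchy:
A by far the most influential total index, then R, γ, a, with χ, D, K, A_σ
negligible, and leading interactions (A,R), (A,γ), (R,γ), (a,A), (a,R).

## Synthetic cohort

The reduced moment model dμ₀/dt = aμ₀, dμ₁/dt = Vμ₀, dc/dt = Rμ₁ has closed
forms (with explicit a → 0 limits) used both for data generation and
fitting. A cohort draws (ln a, ln V, ln R) from a multivariate normal with
SDs (ω_a, ω_V, ω_R) = (0.20, 0.51, 0.84) and corr(ln a, ln R) = 0.8 around
population values (0.12, 816.33, 2.2·10⁻⁶), evaluates the three observation
types on a configurable schedule (the study's exact schedule is not fully
public, so it is config, not code), applies proportional noise
y = f(1 + b_k ε) with b = (0.37, 0.17, 0.18), and left-censors below
per-type limits of quantification (values withheld, interval recorded).

Per-individual recovery is weighted least squares on the log scale
(weights 1/b_k; censored records excluded), with the growth rate identified
from the cell-count series first to seed the optimizer. This deliberately
replaces population-level nonlinear mixed-effects estimation (SAEM), which
requires proprietary tooling and the animal data: the generator reproduces
the *statistical structure* of the study, not its dataset. What the passing
tests show: exact recovery without noise, ~4% median error on a at
study-level noise, and empirical population statistics (ω_a, ρ_aR) within
3 standard errors on 5000 mice. What they do not show: identifiability under
the real study's sparse/sacrifice design, robustness to model misfit, or any
statement about the real mice.

## Units and absolute values

Sizes are μm³, domain lengths mm, times days, masses mm³ (1 mm³ = 10⁹ μm³;
the single conversion constant lives in `fields.MM3_PER_UM3`). The Gaussian
form-function widths θ, θ_σ are not published; the package defaults to
θ = θ_σ = 0.1 domain radii. Absolute equilibrium masses depend strongly on
these widths (and on unit conventions inside R), so they are *not*
reproduction targets; everything validated here — eigenvalues, error
constants and convergence orders, the modal cell diameter, the
evolution-vs-prediction agreement, monotone response directions, and the
sensitivity ranking — is invariant to those unknowns.

## Known limitations

* Node-aligned grids with the direct Dirac mapping conserve cell number only
  to O(h) for concentrated size densities (the index map has no Jacobian);
  the mollified kernel is preferred for production use.
* The collapsed-ratio shift fallback for vanishing growth rates has no
  convergence proof; non-convergence raises with diagnostics.
* The radial reduction assumes centered forms and constant (or radial) R;
  fully 2-D domains and space-structured influx are out of scope.
* The evolution integrator is first order in time and not meant for
  quantitative transient studies, only for equilibrium cross-validation and
  qualitative phenomenology (overshoot growth with tumor aggressiveness).
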