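# Methods

## Model equations and assumptions

The core object is the two-population power-law model of a basic
multicellular unit. Osteoclasts *C* and osteoblasts *B* are produced at
rates α₁C^g₁₁B^g₂₁ and α₂C^g₁₂B^g₂₂ and removed linearly (β₁C, β₂B). The
exponents aggregate net autocrine/paracrine effectiveness rather than any
single ligand (RANKL, OPG, TGF-β are not resolved mechanistically). All
variables and parameters are dimensionless; time is in days. The power
laws require strictly positive populations — g₂₁ < 0 makes the osteoclast
production term singular at B = 0 — so the model describes persistent
cycling about the positive equilibrium, not extinction.

With Γ = g₁₂g₂₁ − (1−g₁₁)(1−g₂₂) ≠ 0 the unique nontrivial steady state is

    C̄ = (β₁/α₁)^((1−g₂₂)/Γ) · (β₂/α₂)^(g₂₁/Γ)
    B̄ = (β₁/α₁)^(g₁₂/Γ)    · (β₂/α₂)^((1−g₁₁)/Γ)

verified by a property test (relative residual of the right-hand side
below 1e−9 across randomly sampled valid parameter sets). At the steady
state the Jacobian diagonal reduces to β₁(g₁₁−1) and β₂(g₂₂−1), so the
trace criterion Ψ = β₁(g₁₁−1) + β₂(g₂₂−1) governs stability. For the
parameter family studied here the eigenvalues are a complex-conjugate
pair, hence the maximum real part equals Ψ/2 exactly; the stability report
exposes both the trace form and the eigenvalue real part, and the
published surface samples (−0.00145, 0.0002) are the *eigenvalue* values.
Regime classification uses |max Re λ| ≤ 1e−10 as the periodic band — the
periodic case is an exact cancellation (Ψ = 0 to rounding), so a tight
band avoids mislabeling nearby damped/unstable parameter sets.

The tumor couples through burden-proportional exponent perturbations
(e₁₁ = g₁₁(1+r₁₁T/L_T), e₂₁ = g₂₁(1+r₂₁T/L_T), e₁₂ = g₁₂/(1+r₁₂T/L_T),
e₂₂ = g₂₂ − r₂₂T/L_T) and itself follows Gompertz growth independent of
bone loss. At T = 0 the Gompertz rate is defined as 0 (its continuous
limit), and the logarithm is evaluated with T floored at 1e−12 so that
treated runs can decay asymptotically toward extinction.

Treatment is a step forcing: for t ≥ t_start the osteoblast removal
coefficient becomes β₂ − v₁ and the Gompertz constant γ_T − v₂. The
placement of v₁ on the removal rate (with the configuration constraint
v₁ < β₂) reproduces the intended qualitative outcomes with the published
intensities: v₁ = .001 keeps removal positive while promoting osteoblast
accumulation; v₂ = .008 > γ_T = .005 drives superexponential tumor decay.
A consequence worth noting: with the forcing held on, the recovered
tumor-free system runs at Ψ' = β₁(g₁₁−1) − (β₂−v₁) = +0.001, so the
recovered cycles are very slowly growing rather than exactly periodic.
The test suite exploits this as a cross-check — the measured per-cycle
amplitude growth matches exp(Ψ'R/2) from linear theory within 5% — rather
than asserting strict amplitude constancy, which this parameter set
cannot deliver.

## Bone mass

dz/dt = −k₁·max(0, C−C_ref) + k₂·max(0, B−B_ref). Reference levels default
to the *tumor-free* nontrivial steady state even when a tumor is present:
with tumor-modified references the damped myeloma case would show no net
bone loss, contradicting the osteolytic phenotype; with tumor-free
references the mean drift is negative and bone mass declines to zero, as
observed. References are configurable. z is clamped at zero (dz/dt set to
max(0, dz/dt) when z ≤ 0): bone mass is a physical quantity and the
depleted state is absorbing while drift stays negative.

The conventional tie k₁ = rR, k₂ = r (R the cycle period) is implemented
operationally in `calibrate_bone_weights`: R is estimated from refined
peak times and r is set by matching the bone-mass oscillation amplitude,
which is linear in r along the ray (R, 1); the quadrature uses one full
cycle at the end of the run so any small net drift does not inflate the
measured amplitude. Note that the cycle family of the periodic regime is
amplitude-dependent: the period measured for the standard +10-unit
perturbation is ≈274 days, which does not coincide with the ratio of the
published weights (k₁/k₂ ≈ 117); the published weights are therefore
treated as data, and calibration is validated by a round trip
(calibrate → simulate → re-calibrate, recovery within 5%) plus the
independent property that the published weights hold the mean bone mass
at 100 ± 5 over 1000 days.

## Numerical integration

Adaptive explicit Runge–Kutta (scipy `solve_ivp`, RK45) with rtol 1e−8,
atol 1e−10, sampled on a uniform grid of 1 sample/day by default. The
system is smooth and non-stiff at the studied parameters; the tolerances
are tight enough for reliable peak detection. Populations are clipped at
1e−12 inside the power laws as a positivity floor. Treated runs are
integrated piecewise with a restart at t_start, so the forcing
discontinuity is never stepped across. Runs used by the tests range from
1000 days (normal/periodic scenarios) to 2500–3000 days: the myeloma
scenarios use 3000 days because the damped/unstable amplitude trends are
properties of the post-growth regime (T ≈ L_T), which a 1000-day window
does not reach — over the first ~1000 days the quasi-steady state itself
drifts as the tumor grows and transient amplitudes rise in both regimes.

Oscillation metrics locate strict local extrema on the sampled grid
(with a ≥ on the trailing side so that tied flanking samples and plateau
entries are kept), refine them by a three-point parabola, and measure
amplitudes as half peak-to-trough excursions, which detrends the drifting
baseline of the tumor runs. The amplitude trend is classified by
log-linear regression across cycles with a 2% total-change band for
"constant". Signals with fewer than three peaks report no oscillation
rather than raising.

## Spatial extension

Method of lines on Ω = [0,1]: uniform closed grid (101 nodes by default),
second-order central differences, Neumann boundaries by ghost-node
reflection (f₋₁ = f₁), and the same adaptive solver on the stacked system
— no operator splitting, since at the published σ = 1e−6 diffusion is
weak and the stacked system remains non-stiff. The discrete Laplacian
conserves the trapezoidal-quadrature integral of any field exactly (the
plain node sum is conserved only up to the half-weight end cells, which
is the natural quadrature for a closed grid). Grid convergence was
measured at second order (Richardson ratios 3.4–3.6 on the smooth
remodeling scenario). With spatially uniform initial data the field stays
uniform and every node reproduces the 0-D trajectory to better than 1e−6
relative; the strict (≤1e−8) no-flux check applies to boundary-compatible
initial data — Gaussian-bump initial conditions are not themselves
flux-free at the ends, and at σ = 1e−6 that imprint decays only slowly.

Initial heterogeneity is modeled as Gaussian bumps on a constant
baseline. The published profiles are drawn but not parameterized, so the
registered defaults (three bumps of amplitude 10, width 0.05, centers
0.2/0.5/0.8 for osteoclast elevations; a single amplitude-1, width-0.1
bump at x = 1 for the tumor seed) are flagged `approximate`. A Gaussian
tumor seed is strictly positive everywhere, which matters: Gompertz
dynamics amplify any positive tail, so the tumor eventually reaches
capacity throughout the domain — the left side after roughly 2000–2500
days at γ_T = .004 — whereas an exactly-zero field would never be
invaded at these diffusivities. The untreated spatial myeloma scenario
therefore runs 3000 days.

`bone_mass_field` re-derives z from stored (C, B) fields by cubic time
interpolation; its accuracy is bounded by the trajectory's sampling
density (4+ samples/day reproduces the jointly-integrated z to ~1e−4
absolute on a 100-unit scale), and the jointly integrated z from
`simulate_pde` is the primary path.

## Scenario registry

Every number in a registered scenario is either a printed caption value
or flagged `approximate` with its default documented here: initial bone
mass z₀ = 100 (the stated normalized value), run lengths as above, bump
geometry as above. The two γ_T values in circulation (.005 for the 0-D
myeloma runs, .004 for the spatial ones) are stored with their respective
scenarios and deliberately not harmonized. The (r₁₁, r₂₂) sweep defaults
to [0, 0.03] × [0, 0.4] at 61×61, bracketing both published sample points
and the damped/unstable boundary, whose r₂₂ = 0.2 crossing is at
r₁₁ = 0.02/1.1 ≈ 0.0182.

## Known limitations

No mechanistic signaling pathways, pharmacokinetics, parameter fitting,
delays or stochasticity; one space dimension with idealized geometry; σ
represents local stochastic variability, not cell migration, so no
advection or chemotaxis. The analytic period/amplitude constants of the
bone-mass equation are replaced by numerical estimation (see above). The
synthetic scenarios emulate the published parameter sets, not measured
murine or clinical data: passing tests demonstrate faithful reproduction
of the model's dynamics, not validation against biology.
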