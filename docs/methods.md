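# Methods

This note documents the model, the numerical procedures, the design
choices made where the design was genuinely open, and the known
limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Individual model

The consumer is described by one state variable, body mass *s* (g),
and interacts with the environment through one variable, resource
density *R* (mg/L). Rates follow a net-production dynamic energy
budget: maintenance `T (s/s_rT)^P` is paid out of assimilated intake
`σ M (s/s_rI)^Q R/(R+H)` before anything else; the surplus Ω, when
positive, is split between somatic growth (fraction κ(s)) and
reproduction (1−κ(s)); when negative it is charged as starvation
mortality `−Ω/s` rather than shrinkage. κ is the cubic smoothstep
`1 − 3L² + 2L³`, `L = (s−s_j)/(s_m−s_j)`, i.e. C¹ at both ends of the
adult size range. There is no reserve compartment and no temperature
dependence.

The reference mass s_r is the rotation point of both power laws; with
s_r = s_j (the default) raising an exponent benefits adults and costs
juveniles, a juvenile–adult trade-off. The optional separate reference
masses s_rI, s_rT keep this structure per process.

Parameters and defaults (units: g, mg/L, day): R_max = 30, δ = 0.01,
Q = P = 1, M = 0.1, T = 0.01, μ_c = 0.0015, μ_j = μ_a = 0, σ = 0.5,
H = 3, s_b = 0.1, s_j = s_r = 1, s_m = 10. The constant χ (default 1)
converts total ingestion (g/day) to resource depletion (mg L⁻¹ day⁻¹);
it is the unit bridge between consumer mass and resource density that
the rate equations leave implicit. All per-capita quantities, the
equilibrium resource density, R0 and every evolutionary output are
independent of χ — it rescales only the population birth rate and
absolute biomasses. This is asserted in tests rather than assumed.

## Life-history integration

At fixed R the individual system

    ds/da = g,  dF/da = −μF,  dB/da = bF,  dΘ/da = IF

is integrated with an adaptive Runge–Kutta (RK45) scheme, rel_tol 1e-8
/ abs_tol 1e-10, alongside three bookkeeping integrals (∫sF da, ∫gF da,
∫μsF da) used for stage biomasses and stationarity checks. Maturation
is an exact event (root of s−s_j), so the stage switch in mortality
happens at the precise age. Integration stops when survivorship falls
below 1e-9 — with μ_c = 0.0015/day that is a ≈1.4·10⁴-day horizon,
long enough that halving the cutoff moves R0 by less than 1e-6
relative (tested) — with a hard age cap of 1e5 days as backstop.

When growth freezes (event |g| < 1e-12·s: either Ω → 0 for P > Q, or
κ → 0 near s_m), the remaining life has constant rates and the tails
of B, Θ and the bookkeeping integrals are added in closed form
(rate·F/μ, the full exponential tail). For P > Q at moderate mortality
the approach to the asymptotic size is fast enough that the event
fires within the lifespan only at low μ_c; otherwise the integration
simply runs to the survivorship cutoff. The approach to s_m itself is
algebraic (κ ≈ 3u² near s_m), so realized terminal sizes sit a percent
or two below the hard maximum even at abundant food; tests treat
"reaches s_m" with a 5% tolerance for this reason. An individual that
cannot grow at birth (R ≤ MRD(s_b)) short-circuits to a closed-form
trajectory with R0 = 0.

## Ecological equilibrium

R0(R) is strictly increasing, so R̃ is the unique root of R0 = 1 on
(0, R_max), found by Brent with xtol 1e-10 after a sign-checked
bracket (warm-started from neighboring solves during sweeps and trait
iterations). The birth rate follows from the resource balance
b̃ = δ(R_max−R̃)/(χ·Θ∞). Stage biomasses, the maturation flux
b̃F(a_j)s_j and the reproduction (newborn-mass) flux b̃s_b are read off
the already-solved trajectory; no re-integration. If R0(R_max) ≤ 1 an
extinction marker is returned instead of an error so parameter sweeps
can cross non-viability boundaries.

Stationarity bookkeeping (tested): s_b + ∫gF da = ∫μsF da to 1e-6
relative, and the resource-balance residual is below 1e-10·G(R̃).

## Cohort (EBT) simulation

The size distribution is a set of cohorts (density, mean mass, age,
lineage). Within a closure window of Δt_c = 1 day, cohort masses and
densities and the resource follow the model ODEs, integrated with
fixed-step RK4 (step ≤ 0.5 day; the dynamics' fastest rates are
~0.05/day, and halving both steps moves long-run outputs by far less
than 0.5%, tested). Newborns produced during the window accumulate in
a per-lineage boundary accumulator and are inserted as one cohort at
(s_b, age 0) when the window closes — a first-order variant of the
classical EBT internalization. Cohorts are dropped below a density of
1e-12 times the initial total; the cohort cap is 20,000 (at the
default mortality ~14,000 cohorts are alive simultaneously under
these settings, so a smaller cap would abort routine runs).

Dynamic stability of an equilibrium is decided by simulation — a 1%
density perturbation either decays or grows into a limit cycle — not
by spectral analysis of the linearized PSPM; this reproduces the
stable/cyclic classification qualitatively and is the package's
stated approximation. A time series is called cyclic when the relative
peak-to-trough resource amplitude after the transient exceeds 1%;
periods come from mean resource-peak spacing and envelopes are min/max
per recorded series. For Q > P the cycle's resource *maxima* coincide
with the MRD of newborns: newborns are then the worst competitors and
can only grow in the brief window when the resource rises above their
break-even density. (The minima lie far below it.)

Invasion experiments run a two-lineage EBT (shared resource, different
exponents). The mutant enters as one newborn cohort carrying 1e-6 of
resident biomass, by default at a resource maximum of the resident
attractor (configurable; for equilibria the phase is irrelevant). The
outcome is classified from the exponential growth rate of the mutant
biomass share fitted over the final third of the run — the first two
thirds are discarded because a lineage founded by a single newborn
cohort needs about two generations to reach its stationary age
structure. In this one-dimensional environment sustained coexistence
is not expected, so a rate within ±1e-5/day is reported as neutral
and a significantly positive rate as invasion-and-replacement.

## Adaptive dynamics

Invasion fitness is mutant R0 at the resident's R̃. Selection
gradients are central finite differences with step 1e-4 in exponent
units (halving the step moves the gradient by ~3e-6 relative, tested;
variational ODEs would be the exact alternative and the design is
replaceable). Because of the finite-difference noise floor, singular
points are verified against a gradient tolerance of 1e-4 — far looser
than the bracketing tolerance 1e-10 used for the underlying scalar
root solves, and deliberately a separate numerics knob.

A one-trait CSS is a Brent root of the gradient over the resident
trait (each evaluation re-solves the resident equilibrium).
Classification: evolutionary stability from the mutant curvature of
R0 (step 1e-2; |curvature| ≤ 1e-6 is reported as degenerate),
convergence stability from the gradient slope across residents, plus
a direct check that R̃ is locally minimized at the point — the
environment is one-dimensional and R0 is increasing in R, so singular
points are resource-density minimizers and ESS and convergence
stability coincide.

The joint CSS of (Q, P) is a simultaneous root of both gradients,
solved by damped Newton with a forward-difference Jacobian (step 1e-3,
step cap 0.1, backtracking halving): the two evolutionary isoclines
lie almost on top of each other, which makes alternating one-trait
relaxation ill-conditioned but leaves the 2-D Newton well-behaved.
Isoclines and parameter sweeps are continuations: each grid point
warm-starts from its neighbor, with a fallback rescan on failure. The
second-order geometry exactly at the joint point has a near-neutral
direction along Q = P, so the package reports per-trait curvature
diagnostics and does not assert a two-dimensional attractivity
classification.

With separate reference masses s_rI ≠ s_rT the located joint singular
points move off the Q = P diagonal (and for larger separations the
gradients lose their interior root altogether): displacing a rotation
point from s_j gives a trait change a direct benefit or cost for
*every* body size — the same degeneracy that causes runaway selection
when s_r = s_b — so exact exponent equality is a property of the
common-rotation-point trade-off, not of the model per se. The package
therefore asserts exponent equality only for common reference masses,
while the algebraic part (MRD size-independence at Q = P) holds for
any reference masses and is tested as such.

The reproductive-scaling diagnostic regresses log(s_b·b(R̃,s)) on
log(s) over the central 96% of the realized adult size range (the
endpoints are excluded because the flux vanishes at s_j); with the
step-allocation variant (all adult production to reproduction) and
Q = P = 1 the exponent is exactly 1, an internal oracle.

## RMA regression and the synthetic dataset

The comparative module fits a reduced major axis line — slope
sign(r)·sd_y/sd_x, symmetric in the axes — of metabolic scaling
exponents against x = log10(l_mat/l_egg), with a 95% CI from the
standard RMA slope error |b|√((1−r²)/(n−2)) and Student-t quantiles
(bootstrap resampling available as an option; the two agree on
generated data, tested). Flagged records are excluded on request
(intended for outliers like leptocephalus-larva species whose egg size
does not measure their juvenile size range). Temperature correction of
exponents is not implemented; inputs are assumed already corrected.

The synthetic generator emulates the structure of a teleost dataset:
41 species, predictor uniform on log10-ratio 1.5–3.2, exponent
= 1.05 − 0.1·x plus Gaussian noise of sd 0.08 (values chosen to put
exponents in the empirically typical 0.7–0.95 band with a negative
dependence on the juvenile size range), egg diameters 0.8–2 mm. It is
deterministic given a seed. It does not emulate phylogenetic
correlation, heteroscedastic measurement error, or predictor error —
so passing calibration tests say nothing about those features of real
data.

One statistical point matters for interpreting the calibration test:
the generator puts noise on the response only, so the population value
of the RMA slope is sign(β)·√(β² + σ²/σ_x²) ≈ −0.191, not the
generating β = −0.1 (RMA estimates the standardized major axis of the
joint distribution; it recovers β itself only when both variables
carry proportional error). CI coverage is therefore asserted against
the estimator's own population value, where the measured coverage is
≈96% at nominal 95%; asserting coverage of β would fail by
construction, not by implementation error.

## Problem sizes used in tests

The test suite scales the analyses down to keep the suite fast while
preserving the qualitative structure: the isocline crossing
uses 9 grid points on P ∈ [1.0, 1.4]; the mortality and size-range
responses use 3-point grids (the responses are strictly monotone, so
direction is decidable); the cycle analysis uses one 30,000-day run
(20,000-day transient, two full cycle periods retained) plus a
6,000-day run for the stable case; invasion checks use a dynamically
stable resident so that 6,000–12,000 days suffice. All are the
package's own choices of problem size.

## Known limitations

- No individual variation in growth, no reserves, no shrinkage under
  starvation; the environment is a single resource.
- Stability classification is simulation-based; very weakly unstable
  equilibria near the cycle onset can be misclassified within the
  chosen simulation horizon.
- EBT accuracy is first-order in the closure interval Δt_c; the
  boundary-cohort treatment pools a window's newborns at exactly s_b.
- Equilibrium quantities assume R0 is monotone in R (true for this
  model); the solver reports, but does not continue through, multiple
  sign changes.
- EBT numerical settings and invasion protocols are recorded
  configuration defaults of this package, chosen for accuracy and
  runtime; other implementations of the same model may differ.
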