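# Methods

This note documents the models, the numerical machinery, the synthetic-data
world, and the design choices behind `thymocross`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The crosstalk model and its assumptions

The core model couples five compartments — DN, DP and CD4 single-positive
(SP4) thymocytes with cortical and medullary thymic epithelial cells — by
ordinary differential equations with two constant delays (see the README for
the equations). Modeling assumptions:

* **Minimal interaction structure.** Influxes and per-capita rates are at
  most linear in the state, so the system is at most quadratic. Every
  interaction coefficient is a *marginal* (net) rate: μ₁ absorbs
  cTEC-induced DN death, DN→DP commitment and proliferation inhibition
  together; population counts cannot separate these.
* **Delays as lumped mechanism.** The delayed cTEC action on DP cells (τ₂)
  stands for the multi-day sequence of positive-selection interactions; the
  delayed DP suppression of mTECs (τₘ) for the indirect (cytokine-mediated)
  inhibition. Delays enter as constants, not distributed kernels.
* **Irradiation as a state jump plus a dying pool.** At t = 0 each
  compartment drops to a surviving fraction p·n_tot(0); the killed
  fraction decays exponentially at rate ω and is *observed* (it is counted
  by flow cytometry) but does not interact. History before t = 0 is the
  constant pre-irradiation level, so lagged terms read baseline values
  until the lag crosses zero — a genuine discontinuity of the right-hand
  side at t = τ₂ and t = τₘ.
* **No spatial structure and no molecular species**; B cells, dendritic
  cells and endothelial contributions are absorbed into the constant terms.

The detailed topology resolves DN into DN1–DN4 with per-stage net self-rates
δ_DNi and cTEC-dependent transition coefficients μ_DNi. The stage-transition
term appears with a **minus** sign in the donor stage (flux out of stage i
equals flux into stage i+1); the printed source form of the donor term for
stages 2–4 carries a plus sign, which breaks inter-stage flux conservation
and is treated as a typo — `verbatim=True` reproduces the printed sign for
comparison.

Four alternative topologies replace exactly one equation each: M1 removes
the mTEC logistic term (death rate μ_m instead), M2 drives mTECs by DN cells
directly, M3 lets cTECs *promote* DP growth (with the printed plus sign and
no delay), M4 adds a delayed DP suppression of cTECs (γ_c); M4 with γ_c = 0
is exactly the reference model, a nesting the tests verify at trajectory
level.

## DDE integration

scipy has no delay-differential solver, so the stepper is hand-built
(numba-compiled) but reuses scipy's `RK45` Dormand–Prince tableau and
quartic dense-output coefficients verbatim as class attributes — no
hand-typed constants. Method of steps:

* the step size is capped at the smallest positive delay, so every lag
  query falls in already-completed steps or the constant history;
* lagged values are evaluated from the stored per-step dense polynomials;
* steps are forced to land on the propagated discontinuity times
  k₁τ₂ + k₂τₘ (k₁+k₂ ≤ 3 by default), and the first stage is re-evaluated
  at every step start (no FSAL reuse) because the lagged *value* jumps when
  a lag crosses the t = 0 state jump;
* default tolerances are rtol 1e-8, atol 1e-2 cells (populations span
  1e3–1e8 cells); estimation uses rtol 1e-6 for speed.

Error control mirrors scipy's RMS-scaled estimator. Local tolerances
amplify along growing trajectories, so "tolerance-converged" is asserted as
a relative global bound (halving tolerances moves counts by < 1e-5
relative), not as an absolute-cells bound. The integrator is cross-checked
against an independent fixed-step Heun method-of-steps oracle (step 1e-4
day) to < 1e-3 relative over [0, 50] days.

Steady states are roots of the undelayed right-hand side (delays are
irrelevant at equilibrium), found by damped Newton with analytic Jacobians;
the merit norm max|f_i|/max(|x_i|, 1) is a per-capita residual rate
(convergence below 1e-9/day), with the scale held fixed during each line
search so the Newton direction remains a descent direction. The default
starting point is the endpoint of a 400-day forward simulation, which
selects the attractor of the post-irradiation dynamics when multiple roots
exist.

## Estimation

The objective is the sum of squared differences between log observed and
log simulated total counts over every compartment and replicate slot. Each
replicate contributes its own residual (equivalent to repeating time
points); this uses all measurements and reduces to the plain per-time-point
form when replicates are one. A `daymean` mode (log-scale averaging per
day) is provided since the source description is ambiguous on this point.

Conditioning follows the θ = θ_c ∘ θ_p decomposition: θ_p is the power of
ten nearest the initial guess (the original exponent vector is unpublished),
and the optimizer (scipy `least_squares`, Trust Region Reflective) works on
θ_c. Bounds: fractions (survival fractions, r₁, r₂₄, r_DN4) on [0, 1], all
other free parameters within a factor of ten of their guess. Kinetic
parameters, pre-irradiation sizes, survival fractions and dying-pool decay
rates can all be freed simultaneously; the reduced studies below free
documented subsets. Failed simulations at a trial point return a large
finite penalty so the trust region can retreat. Initial guesses default to
the template values; every fit records its guess, bounds and θ_p for
reproducibility.

Two-stage detailed-model estimation: stage 1 fixes the shared parameters
(φ₁, θ₂, K₂, μ₂, τ₂, φ_c, δ_c) to the coarse estimates and fits the DN-stage
parameters; stage 2 re-frees φ₁ from a caller-supplied small guess. On
noise-free stage-resolved data the re-freed φ₁ returns exactly to the
generating value; under realistic noise φ₁ is weakly identified and can
drift to its search bounds — the same boundary-peak behaviour the bootstrap
shows (below).

## Bootstrap

Parametric bootstrap on the log scale: σ̂ᵢ² is the residual sample variance
per compartment (denominator m−1 with replicate slots counted), resamples
perturb the *fitted* trajectory at every original slot, and each resample is
refitted from the point estimate (a flag restarts from the original guess
instead). One master seed spawns independent child streams per resample, so
any subset of resamples is reproducible in isolation; results are
bit-reproducible given (problem, B, α, seed). Intervals are two-sided
percentile intervals at [(1−α)/2, (1+α)/2] — the printed order-statistic
convention in the source ((B(1−α)/2, Bα/2)) cannot be a two-sided interval
and was replaced by the standard one. Refits that fail to converge are
excluded and counted; more than 20% failures flags the result unreliable.
No BCa or studentized refinements.

## Derived kinetic quantities

Evaluated at the steady state: DN inflow φ₁; DN apparent proliferation
δ₁ − μ₁(1−r₁)c*; DN differentiation μ₁r₁c*; DP apparent proliferation
θ₂(1−P*/K₂) − (1−r₂₄)μ₂c*; DP→SP4 differentiation r₂₄μ₂c*; residence times
24/(exit rate) in hours; DP→SP4 fraction 100·r₂₄; SP4 apparent export
μ₄m*. All are net rates — apoptosis and pure proliferation are not
identifiable from population sizes, so residence times based on exit fluxes
can overestimate true residence when death is appreciable.

## The synthetic-data world

The generator emulates the recovery study's structure: 13 sampling days
(0–49), per-day replicate numbers (4,6,3,3,3,3,2,3,3,3,3,6,3 for
thymocytes; 4,6,3,6,3,3,2,3,6,3,3,6,3 for TECs), baseline samples (15
thymocyte / 16 TEC animals) at the steady state, multiplicative log-normal
noise (default σ = 0.2, a modeling choice — the source reports no
per-compartment variance; 0.2 gives the ±20% visual scatter of the
published panels), and the DN-gate contamination correction (16.6% non-T
admixture, applied and invertible for round-trip testing). DN1–DN4 counts
are reconstructed from stage proportions, with unsampled days filled by the
mean of the neighbouring observed days.

The default truth regime is constructed once from steady-state targets
(DN* = 3.3e6, DP* = 1.5e8, cTEC* = 1e4, mTEC* = 3e4 cells) such that the
composite quantities equal the published point estimates (DN differentiation
0.14/day, DP→SP4 0.11/day, r₂₄ = 10%, SP4 export 0.52/day, DN inflow
3.3e4/day, …). The free shape parameters (r₁ = 0.12, θ₂ = 1.7/day,
φ_c = 3000/day, δ_c = 0.5/day, γ_mp·DP* = 0.35/day, r_m = 0.5/day, survival
fractions and ω per compartment) were calibrated to the qualitative recovery
shape: biphasic decay, recovery onset within ~5 days, DP and mTEC interior
maxima near days 15–17 with terminal values below the peaks, and a DN
compartment that is nearly self-sustaining (δ₁ ≈ μ₁c*). That last property
is essential: it makes the DN influx φ₁ weakly identified, so replacing the
fitted φ₁ by a value 500× smaller moves no trajectory by more than ~4%, and
bootstrap samples of φ₁ scatter over the whole factor-of-ten search range —
the behaviour reported for this system.

What a green test does *not* establish: the generator draws independent
log-normal errors around a trajectory of the fitted model class itself, so
recovery and coverage results say nothing about model misspecification,
between-animal heterogeneity, day-to-day batch effects, or flow-cytometry
gating bias; and the composite-rate targets are construction inputs, not
re-derivations of the study's fits.

### A deliberate tension, kept visible

Weak identifiability of φ₁ and accurate recovery of φ₁ are mutually
exclusive: if a 500-fold change in φ₁ moves the noiseless trajectories by
only a few percent while measurement noise is ~20%, no estimator can pin φ₁
to 25%. The recovery study therefore reports the DN-inflow composite
separately from the eight curvature-identified composites (which recover to
~3–10% median error); the corresponding test is expected to fail and is kept
failing rather than weakened, as an honest record of this identifiability
limit.

## Scaled-down studies and runtimes

The full estimator supports freeing all 34 coarse-model parameters, but the
replicated studies in the test suite free documented subsets to stay inside
CI budgets: parameter recovery frees {φ₁, δ₁, μ₁, θ₂, K₂, μ₂, μ₄}; bootstrap
coverage frees {φ₁, δ₁, μ₁, θ₂, μ₂, μ₄} with B = 200 and 20 outer
replicates; fits during these studies use solver rtol 1e-6. Coverage is
assessed per composite quantity against the generating truth and summarized
as the mean across quantities (each individual quantity is also checked at
the scaled-down 0.80 level).

## Known limitations

* Constant delays only; no distributed or state-dependent delays.
* Deterministic dynamics; no demographic (birth–death) noise.
* The DP proliferation diagnostic θ₂(1 − n_DP/K₂) is the model-side
  analogue of a proliferation-marker time course, not a prediction of the
  marker-positive fraction; in this model it peaks at the DP minimum
  (immediately after irradiation) and stays near-maximal through the
  exponential-rise window.
* Rejection diagnostics for alternative topologies depend on the dataset:
  on synthetic data from the reference model the implied-lifetime
  diagnostics are computed and reported, but their values need not match
  those obtained on the original measurements.
* M1/M2 use an mTEC death rate μ_m that the reference topology does not
  contain; comparisons across topologies are on fit quality and implied
  rates, never likelihood-ratio statistics.
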