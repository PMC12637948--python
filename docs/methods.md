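# Methods

## The estimation problem

Cell-free single-enzyme assays report NADH concentration over time, read
spectrophotometrically at 340 nm (390/400 nm for high concentrations).
`cfkinetics` fits mechanistic rate-law parameters to groups of such traces
collected under varying initial substrate, cofactor, product, and enzyme
concentrations, and composes independently fitted single-enzyme parameter
sets into multi-enzyme cascade simulations.

Two enzyme systems are built in:

* **FDH** (formate dehydrogenase): NAD⁺ (A) + formate (B) → NADH (Q) + CO₂
  (C), an irreversible ordered bi-bi law with competitive NADH product
  inhibition:

      v = kcat·[A][B]·E / (K_IA·K_MB + K_MB·[A] + K_MA·[B] + [A][B]
                           + (K_IA·K_MB/K_IQ)·[Q] + (K_MA/K_IQ)·[B][Q])

  Every denominator term carries mM², so the expression is dimensionally
  consistent and the denominator is bounded below by K_IA·K_MB > 0. CO₂ is
  tracked stoichiometrically but appears in no rate law: the gas is assumed
  to leave the liquid phase fast enough to render the reaction irreversible.
  (Under carbonate buffering this assumption breaks down; reversible FDH is
  out of scope.)

* **BDH** (2,3-butanediol dehydrogenase): acetoin (S) + NADH (Q) ⇌
  2,3-butanediol (P) + NAD⁺ (A), in reversible convenience kinetics:

      v = E·[kcatf·(S/K_MS)(Q/K_MQ) − kcatr·(P/K_MP)(A/K_MA)]
          / [(1+S/K_MS)(1+Q/K_MQ) + (1+P/K_MP)(1+A/K_MA) − 1]

  The denominator is ≥ 1 for non-negative concentrations. No published
  mechanistic law exists for this enzyme; convenience kinetics captures
  saturation and reversibility with few parameters and is the standard
  exploratory choice.

Both systems include irreversible first-order non-enzymatic NADH
decomposition Q → X with rate constant k_dQ, which matters on multi-hour
horizons. The degradation product is routed to an inert sink X and **not**
recycled to NAD⁺; nothing in the chemistry suggests regeneration, but the
choice does affect the long-horizon NAD⁺ balance and is isolated in one
place (the `decomp` stoichiometry) if a user disagrees. Protons are excluded
from the model state.

### Units

Canonical internal units are mM and minutes. Turnover numbers are stored in
1/s (the unit in which they are reported and compared) and multiplied by 60
on rate evaluation; k_dQ is stored in 1/min, with an explicit
`DecompParams.from_per_hour` constructor because decomposition constants are
quoted in both 1/h and 1/min in the literature. Dataset lags are stored in
minutes but handled in seconds inside the lag-search module, the scale on
which instrument dead times are quoted.

### Thermodynamic constraint

BDH reversibility is anchored by the Haldane relationship

    Keq = kcatf·K_MP·K_MA / (kcatr·K_MS·K_MQ) = exp(−ΔG°/(R·T)),

with ΔG° = −22.5 ± 4.1 kJ/mol at T = 310.15 K (Keq ≈ 6.16×10³). The fit
enforces the equality by *eliminating* kcatr — it is computed from the other
five parameters and Keq rather than optimized — so every solution satisfies
the constraint at floating-point precision by construction. A band mode
instead treats ΔG° as an extra decision variable bounded within ±1 standard
deviation, which admits the stated thermodynamic uncertainty while keeping
exact consistency at whatever ΔG° the optimizer selects.

## Preprocessing

1. **Beer–Lambert conversion**: conc = A/(ε·ℓ) with ε₃₄₀ = 6.220,
   ε₃₉₀ = 0.4276, ε₄₀₀ = 0.1205 mM⁻¹cm⁻¹ and pathlength ℓ = 0.623 cm (60 µl
   in a 384-well plate). Conversion precedes smoothing.
2. **Moving average**, default window 10 points, centered and truncated at
   trace boundaries (no padding — padding would fabricate data at the ends).
3. **RDP thinning** (Ramer–Douglas–Peucker) to a budget of 95–105 points per
   trace, which equalizes each dataset's weight in the joint objective and
   bounds the transcription size. Perpendicular distances are measured after
   per-axis min–max scaling of the trace, because time and concentration
   carry incommensurate units; epsilon is therefore dimensionless. The
   epsilon meeting the budget is found by bisection on log₁₀(ε) (the
   retained count is monotone non-increasing in ε), 60-iteration cap.
4. **Lag-phase trimming** for sigmoidal BDH traces whose early portion
   reflects temperature equilibration rather than kinetics: points before a
   user-chosen cut are dropped, time is re-zeroed, and the nominal initial
   NADH is recorded for the initial condition.

Dataset exclusion (traces too noisy or trending erroneously) is supported
only as an explicit user-provided list; it is never automated.

## Fitting

The contract is: minimize the unweighted sum of squared residuals (SSR, mM²)
between measured and predicted NADH over all datasets of a series, subject
to backward (implicit) Euler dynamics on each dataset's measurement grid
(one finite element per sampling interval), non-negative parameter bounds,
optional fixed ranges, and the optional Haldane equality. Equal weights
deliberately follow the field convention; the documentation warns that this
prioritizes high-NADH trajectories, and per-point weights are configurable.

`transcribe` materializes the discretized program — parameter and state
decision variables, implicit-Euler equality constraints, SSR objective — and
the solver eliminates the states by forward implicit-Euler simulation
(single shooting). A simultaneous interior-point solve of the same program
is an equivalent strategy; single shooting was chosen because the dynamics
constraints then hold by construction (Newton residual ≤ 1e−11 scaled by
state magnitude, i.e. defect < 1e−8 even for 100-mM substrates) and the
program objective provably equals the plain simulation SSR, which the test
suite asserts directly. Each implicit-Euler step is solved by damped chord
Newton with a finite-difference Jacobian (refreshed every third iteration or
on stall).

Local solves use trust-region-reflective least squares over log₁₀-transformed
parameters (kinetic constants span orders of magnitude; the log transform
makes bounds boxes and makes the trust region scale-free). The global
strategy is randomized multi-start: start *i* draws its initial vector
log-uniformly over [1e−4, 1e4] intersected with the bounds, seeded
`base_seed + i`, so any prefix of a run is reproducible and the running best
SSR is non-increasing in the number of starts. Convergence of a start means
the solver reported success with finite SSR; the dynamics defect is bounded
by construction. The solution pool keeps converged solutions within 10% of
the best SSR (the "alternatives"); per-parameter mean, sample (n−1) standard
deviation, and CoV = std/mean are computed over that pool.

**k_dQ pre-fitting.** Decomposition standards (enzyme-free NADH traces) are
fitted per trace — log-linear regression on ln Q(t) when all readings are
positive, a nonlinear exponential fit otherwise — and the [min, max] over
standards becomes a box constraint on k_dQ in the subsequent kinetic fit,
mirroring the two-stage protocol used with real assay campaigns.

## Time-lag correction

The dead time between reaction start and the first reading (typically
10–60 s) is estimated per dataset, sequentially, not jointly with the
kinetics:

1. **Initial guess** t₀: a cubic polynomial is fitted to the early trace
   (cubic is the lowest degree that fits these traces with scaled SSR
   < 1e−4) and extrapolated back to the start concentration — zero for a
   rising FDH trace, nominal initial NADH for a falling BDH trace. The real
   root closest to zero gives the guess; its magnitude is the lag (a root at
   −τ means the trace began τ before the first reading). No plausible real
   root falls back to half the first sampling interval, with a warning.
2. **Bracketing search**: starting from [t₀ − i₀, t₀ + i₀] with i₀ = t₀,
   each iteration evaluates 11 evenly spaced candidates (10 sub-intervals,
   step s₀ = 2i/10, endpoints inclusive, negative lags clamped to 0), keeps
   the best (lag, SSR), recenters there, shrinks the half-interval to s₀
   (a 5× contraction), and stops when the half-interval drops below
   ε = 0.001 s — hence ⌈log₅(i₀/ε)⌉ iterations. Candidate SSRs come from a
   20-multi-start fit of the single dataset with the candidate lag applied
   and initial concentrations held at their nominal values. The evaluator is
   injectable: recovery tests and the acceptance script pin the kinetics at
   known values, which turns each candidate into a single simulation and
   keeps the search seconds-scale.
3. Applying a lag re-interprets measurement *j* at model time t_j + lag with
   the initial condition fixed at model time 0; the data are never moved.
   After all lags are found they are frozen and the full series is
   re-parameterized.

Whether the lag significantly improves the fit is judged by a nested-model
χ² test, statistic n·ln(SSR_reduced/SSR_full) against the χ²(1−α, df) 
quantile at α = 0.001. This Gaussian likelihood-ratio form is the package's
default; the statistic is exposed in configuration so an alternative
Bartlett-style form can be substituted. A separate χ² goodness-of-fit screen
passes a solution when SSR/σ² ≤ χ²(1−α, df) with user-supplied residual
variance σ² (replicate noise is not something the package can invent) and
configurable df — conventions for counting df differ (parameters vs n−p),
so it is left to the caller.

## Simulation and fed-batch composition

`simulate_reference` wraps the SciPy BDF stiff solver (defaults rtol = 1e−8,
atol = 1e−10; the tolerances are the package's own choice) and is the oracle
against which the implicit-Euler discretization is verified to converge at
first order. Concentrations are floored at zero before rate evaluation;
reported concentrations in [−1e−9, 0) are clipped to 0 and anything more
negative raises.

Fed-batch cascade simulation is piecewise: each interval between sampling
points is integrated with a constant feed rate (the slope of linearly
interpolated cumulative addition), and the final state of one segment is the
initial condition of the next. Profiles are continuous but typically
non-smooth at boundaries — that is a property of the piecewise-constant feed,
not an artifact. The simulation is on a concentration basis with no volume
tracking: experimental comparisons are assumed re-normalized to mM after
volume-change accounting, as is standard when samples are withdrawn and
titrant added. Feed-schedule boundaries must coincide with segment
boundaries; misalignment is an error rather than a silent interpolation.

## Synthetic data

The generator emulates what the fitting assumes: reference-integrated true
trajectories observed at instrument times shifted by an injected dead time,
plus i.i.d. additive Gaussian noise (default sd 0.01 mM — plate-reader
absorbance noise is approximately additive and the Beer–Lambert conversion
is linear) clipped at zero. True parameters and lags are recorded on the
series so every stage is testable by recovery. Decomposition standards are
generated from the closed-form exponential. A fixed seed reproduces a series
byte-identically.

The generator offers two integrators. The default, `reference`, is the
realistic study condition: fitted predictions then differ from the data by
the implicit-Euler discretization error, exactly as with real data. The
`euler` option generates observations from the fitting discretization
itself; it is used by the exact-recovery checks, where the estimator's
correct answer is the generating parameter vector and the attainable SSR is
zero, so failures indicate estimator defects rather than discretization
bias. What the generator does **not** emulate: instrument drift,
evaporation, temperature-equilibration sigmoids, heteroscedastic noise at
the detector's range edges, or well-to-well cross-talk — passing recovery
tests therefore demonstrates estimator correctness, not robustness to every
real-data pathology.

### Problem sizes

Default test and acceptance-script sizes are chosen to exercise every code
path at desk scale: 5-dataset FDH campaigns of 31 points each with 4
multi-starts, 2-dataset BDH campaigns of 16 points with 3 starts, and
single-dataset lag searches with the kinetics pinned. Full-scale campaigns
(hundreds of starts over dozens of 100-point datasets) use the same code
with larger `n_starts`; nothing in the implementation is specific to the
small sizes.

## Numerical choices and limitations

* Implicit-Euler Newton: damped line search on the residual norm, 50
  iteration cap, chord Jacobian refreshed every 3 iterations.
* Random starts that land in regions where the Newton iteration fails are
  penalized with a large residual rather than aborting the start.
* The log transform excludes exact zeros from the decision space; bounds
  with zero lower limits are floored at 1e−12 in log space. k_dQ = 0 exactly
  is representable only by fixing the parameter.
* `auto_thin` errors (reporting the nearest achievable count) if the budget
  cannot be bracketed — possible for traces with fewer distinct geometric
  features than the budget requests.
* Identifiability is design-limited: with only NADH observed, parameters
  tied to unobserved metabolites (e.g. K_MB, K_IA) resolve poorly, which is
  visible as large CoV across the solution pool. That is a property of the
  experimental design, not the optimizer; the package reports it rather than
  hiding it.
* SBML export covers species, global parameters, and the built-in rate laws
  as content MathML (substance mM, time min); user-defined callables cannot
  be serialized. The export is minimal by design — annotations, unit
  definitions beyond the defaults, and SBO terms are omitted.
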