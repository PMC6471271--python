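# Methods

This note documents the models implemented in `saltivivc`, their
assumptions, the tunable parameters, and the numerical choices, in enough
detail to judge what a passing test suite does and does not demonstrate.

## 1. Salt solubility model (`salt_chemistry`)

For a 1:1 salt of a weak acid HA (pK_a,acid) with a protonatable base
counterion BH⁺ (pK_a,counterion), ideal-solution equilibria give

- S_salt(pH) = √(K_sp · (1 + 10^(pK_a,acid − pH)) · (1 + 10^(pH − pK_a,counterion)))
- S_acid(pH) = S₀ · (1 + 10^(pH − pK_a,acid))
- pH_max = pK_a,acid + log₁₀(√K_sp / S₀)

The square root in S_salt is required for dimensional consistency (K_sp is
in M², a solubility in M) and so that S_salt → √K_sp in the fully ionized
regime; the closed-form pH_max follows from equating the two curves there.

Defaults for the dexketoprofen trometamol (DKT) system
(`saltivivc.datasets.DKT_SYSTEM`): K_sp = 4.96 × 10⁻¹ M²,
S₀ = 1.36 × 10⁻³ M, pK_a,acid = 4.02, pK_a,counterion = 8.1. The closed
form gives pH_max = 6.73; the numeric curve intersection gives 6.74 — the
0.01 gap exists because trometamol is only ~95% ionized there. Both
behaviours are exposed (`ph_max(..., method="closed_form" | "numeric")`)
rather than silently reconciled. The same partial ionization is why the
K_sp estimator that simply squares a measured near-neutral salt solubility
(the default, matching how the packaged K_sp value was derived) differs by
~5% from the ionization-corrected estimator, available via keyword.

Assumptions: activity coefficients of 1 (dilute ideal solutions), no
common-ion or added-electrolyte effects, no precipitation of the protonated
drug, bulk-solution pH (interfacial pH at a dissolving particle is *not*
modelled — the supersaturation ratios refer to bulk conditions).

## 2. Gastrointestinal transfer simulator (`gis`)

A deterministic mass/volume balance of a three-vessel transfer apparatus.

Fluid: the gastric volume obeys dV/dt = S − k_e·V with k_e = ln2/t½
(t½ = 13 min, the reported human gastric half-life for liquids) and
secretion S = 1 mL/min, solved in closed form; the duodenum is held at
50 mL by matching outflow to inflow (gastric emptying + 1 mL/min
secretion); the jejunum starts empty and only accumulates. All pumps stop
at 60 min; dissolution continues to 120 min. Initial gastric volume is
300 mL (50 mL simulated gastric fluid + 250 mL water).

Drug: each compartment tracks dissolved drug, undissolved salt and
precipitated free acid (µg of salt equivalents, so conservation is exact
by construction). Dissolution follows a z-factor law,
dm/dt = −z · m^(2/3) · (S(pH) − C), with the driving term in molar units
and the solubility from the salt-chemistry model at the prescribed
compartment pH; precipitated acid can re-dissolve against S_acid at its
own z. Precipitation is first order in the excess over the acid
solubility, k_precip·(C − S_acid)·V, triggered when C/S_acid exceeds
`sigma_threshold` (default 1). The z units are µg^(1/3)·M⁻¹·min⁻¹; the
default z_salt = 0.4 makes one tablet (36.9 mg salt) reach ~60% dissolved
at 30 min and ~85% cumulative jejunal delivery at 120 min under the
biorelevant protocol — deliberately incomplete early dissolution, matching
the character of these products, while the three synthetic formulations
converge to similar extents by 120 min.

Compartment pH is prescribed per compartment (protocol presets: gastric
2.0 with either 50 mM pH 6.8 phosphate buffer or FaSSIF-v1 pH 6.5
downstream), not computed from buffer speciation; observed pH shifts (e.g.
an alkalinizing excipient raising gastric pH from ~2.5 to ~3.5, or to 5.3
in concentrated microscopy wells) are scenario inputs. Suspended solids
transfer with the fluid at the liquid's fractional rate (homogeneous
suspension, justified by the apparatus' periodic high-speed mixing
bursts). Media composition strings (NaCl, bile salts) are descriptive tags
that can inform user-chosen kinetics; they have no mechanistic effect —
the NaCl sensitivity seen experimentally has no established mechanism to
encode.

Numerics: explicit stepping at `time_step` = 0.1 min with per-step caps so
no mass goes negative and no compartment overshoots saturation; a
mass-balance check (0.1% of dose) halves the step on violation, up to 10
times. Halving the step changes the outputs by <0.5% at the defaults.

## 3. Two-compartment pharmacokinetics (`pk`)

Central volume V₁ with elimination k₁₀ and peripheral exchange k₁₂/k₂₁
(all first order; rates in 1/h, volumes in mL). IV bolus concentrations
use the closed biexponential form with hybrid constants α, β the roots of
x² − (k₁₀+k₁₂+k₂₁)x + k₁₀k₂₁ (β computed as product/α for stability).
Oral simulation propagates the linear system exactly over each interval
of a piecewise-constant absorption-rate input using the matrix exponential,
so superposition holds to machine precision and the simulator can serve as
its own convolution oracle.

Fitting is nonlinear least squares (lmfit Levenberg-Marquardt) on the
biexponential, uniform weighting by default (1/C optional — the original
analysis does not state its weighting), initialized by deterministic curve
stripping (log-linear terminal fit, residual peeling). Reported standard
errors are asymptotic; CV% = 100·SE/estimate. Identifiability: with only
central-compartment observations, V₁ and k₁₀ are estimated tightly
(replicate CV ≈ the assay CV) while k₁₂/k₂₁ carry several-fold larger
uncertainty — the packaged reference fit shows the same pattern (K₁₂ CV%
~3× that of K₁₀). A fit whose hybrid constants collapse (α/β < 1.05)
raises rather than returning meaningless distribution constants.

## 4. Loo-Riegelman deconvolution (`deconvolution`)

The cumulative absorbed amount per central volume is

X_A(t)/V_c = C(t) + k₁₀·AUC(0→t) + P(t),
P(t) = k₁₂·e^(−k₂₁·t)·∫₀ᵗ C(τ)·e^(k₂₁·τ) dτ.

AUC uses the linear trapezoid; P uses the exponentially weighted integral
of the piecewise-linear interpolant, evaluated analytically per segment —
exact (verified to machine precision) whenever C is piecewise linear
between samples. The overall scheme is second-order in the sampling
interval: halving Δt cuts the deviation from a tight ODE oracle by ≥4×.
At 15-min sampling of a profile with a 20-min absorption half-time the
residual discretization error is ~2% at the earliest samples; accuracy
claims in the tests therefore use ≤10-min grids, and inputs whose
absorption half-time is shorter than the sampling interval cannot be
resolved by any discretization.

Fractions absorbed are the deconvolved amounts normalized to their
terminal plateau (absolute bioavailability is unidentifiable without IV
data in the same subjects). A profile whose last interval still changes
the amount by >5% raises `TruncatedAbsorptionError`. Noise can make the
raw amounts dip; an isotonic-regression pass enforces monotonicity on the
fraction output only, with raw values retained in metadata. C(0) must be
zero for oral dosing unless back-extrapolation is explicitly requested.
With k₁₂ = 0 the method reduces to Wagner-Nelson (provided independently
for cross-checks; agreement ≤1e-6).

Cross-study normalization multiplies each test concentration by the ratio
of the reference formulation's concentrations in the anchor vs the test
trial (pointwise, with an AUC-ratio scalar variant); zero reference values
are tolerated only where the test is also zero.

## 5. Level-A IVIVC (`ivivc`)

Fractions dissolved are amounts divided by the single global maximum
across formulations (exactly one curve reaches 1.0). Pairing interpolates
linearly and never extrapolates; the pipeline pairs at the in vivo
sampling times (the sparse grid) and interpolates the dense in vitro
curve — interpolating the sparse in vivo curve at dense in vitro times
distorts its early shape and biases the fitted relationship (measured:
Hill γ pulled from 1.4 to 0.85 on the default study). The union-grid
variant remains available.

The default relationship is a two-parameter Hill curve constrained through
(0,0) and (1,1): f_abs = f^γ·(1 + f₅₀^γ)/(f₅₀^γ + f^γ) — monotone,
bounded, two parameters; a cubic through the origin is available behind a
flag. The fitted curve is verified monotone on a 0.01 grid. No
time-scaling (Levy plot) step is applied; the jejunal (not duodenal)
dissolved amounts are the in vitro input.

Reconvolution solves the mass balance above for C stepwise — trapezoidal
elimination term, exact piecewise-linear peripheral term — making it the
algebraic inverse of the deconvolution discretization; the working grid
subdivides every interval to ≤5 min (configurable), and negative
intermediate concentrations are floored at zero and counted. Validation
metrics: C_max is the maximum observed concentration and AUC the trapezoid
to the last sample (no extrapolation to infinity); predicted profiles are
sampled at the experimental sampling times before computing metrics, so
predicted and experimental values share an observation grid — comparing a
continuous-grid prediction against sparse samples injects a pure grid
artifact (~3% on C_max) unrelated to model quality. Prediction error is
the signed RE% = 100·(experimental − predicted)/experimental, and the
summary is the mean absolute RE% per metric.

## 6. Synthetic studies (`synthetic`)

The generator emulates the data situation of a bioequivalence programme
with no deposited raw data: an IV dataset for disposition fitting, oral
plasma profiles for three formulations split across two trials (the
reference arm dosed in both, so cross-study normalization is exercised,
with a bioanalytical scale shift of 1.1 on the second trial), and matching
in vitro profiles from the transfer simulator.

Study conditions (fixed defaults): disposition = the packaged reference
constants; formulation effects scale the dissolution z-factor
(reference 1.0, non-BE-like 1.5, BE-like 0.85 — the non-BE-like arm
dissolves faster and reaches a higher C_max); the true dissolved→absorbed
relationship is Hill(γ = 1.4, f₅₀ = 0.4); measurement error is
multiplicative lognormal with CV 5% (mean-unbiased), the standard
bioanalytical error model; plasma sampling is 0–2 h at 15 min then hourly
to 12 h; in vitro sampling 0–120 min at 5 min; seed 42. The bioavailable
amount at complete dissolution is 22.5 mg (90% of the 25 mg dose).

What the generator does *not* emulate: between-subject variability and
crossover structure (profiles represent study means), time-dependent
assay error, duodenal absorption, interfacial-pH-driven precipitation, and
any mechanistic NaCl effect. Passing end-to-end tests therefore
demonstrate that the pipeline recovers a known dissolution-limited truth
under realistic assay noise and cross-trial scale shifts — not that it
would overcome model misspecification in real data.

## 7. Known limitations

- The solubility model is bulk and ideal; supersaturation at particle
  surfaces (which explains phase separation in undersaturated bulk) is
  discussed but not computed.
- Dissolution/precipitation kinetics close the transfer model
  phenomenologically; z-factors are not derived from particle size.
- Fraction-absorbed normalization to the own plateau makes formulations
  with different dissolution *extents* deviate slightly from a single
  IVIVC curve; the default study keeps extent differences small.
- The deconvolution/reconvolution pair is second-order accurate;
  sub-sampling-interval absorption dynamics are unrecoverable.
- Validation AUC is truncated at the last common sample, not extrapolated.
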