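# Methods

## The model

`packinetics` models the batch biotransformation of benzaldehyde (B) and
pyruvate (A) to (R)-phenylacetylcarbinol (PAC, P) by partially purified
pyruvate decarboxylase (PDC) in phosphate (Gomori) buffer, together with the
by-products acetaldehyde (Q, from direct pyruvate decarboxylation) and
acetoin (R, from carboligation of two acetaldehyde units).  The driving
force is the relative carboligase activity E, expressed in % of a reference
volumetric activity.  Six coupled ODEs (time in min, concentrations in mM):

    dP/dt = V_p · [K_b B^h / (1 + K_b B^h)] · [A / (K_ma + A)] · E
    dA/dt = −dP/dt − dQ/dt − 2 dR/dt
    dB/dt = −dP/dt
    dQ/dt = V_q A E − V_r A Q E
    dR/dt = V_r A Q E
    dE/dt = 0                                  t <  t_lag
          = −(k_d1 + k_d2 B) E + k_a Ph_b      t ≥  t_lag

Benzaldehyde binding is Hill-type (h ≈ 2, consistent with a dimeric
operating form of PDC); pyruvate binding is Michaelis–Menten.  Enzyme
stability combines first-order background decay (k_d1), benzaldehyde-driven
decay (k_d2·B), a zeroth-order stabilisation by the phosphate buffer species
(k_a·Ph_b, Ph_b the constant buffer concentration in mM) and an initial
refolding lag t_lag during which E is constant.

The activation term multiplies k_a by the *buffer* concentration.  The
alternative reading (multiplying by the PAC concentration) is rejected
because k_a originates from buffer-activation experiments and because the
reported activation rate in 250 mM buffer, 2.34 × 10⁻³ % min⁻¹, is exactly
k_a × 250 with k_a = 9.38 × 10⁻⁶ % min⁻¹ mM⁻¹.

Two linear invariants follow from the stoichiometry and hold exactly under
explicit Euler stepping: B + P and A + P + Q + 2R are constant in time.
They are asserted to ≤ 10⁻⁹ mM (floating-point accumulation only) at every
internal step.

## Integration

Trajectories use explicit Euler–Cauchy stepping on a fixed grid, the
convention under which the reference constants were estimated.  The default
increment is 0.6 min (= 0.01 h); all rate constants are per minute.  The
step containing t_lag is split at t_lag so the stability branch switches
exactly there, and sampling times are inserted into the grid so sampled
values are exact grid states.  Euler overshoot below zero is clamped at 0
(logged; a clamp above 0.1 mM triggers a step-size warning).  Verification:
halving the step changes every sampled value by < 0.5%, and a two-segment
LSODA reference at rtol 10⁻¹⁰ agrees with the 0.6-min grid within 1%
(worst species ≈ 0.94%) for all three study conditions.  The hot path is a
numba-compiled kernel; a pure-Python fallback is used if numba is
unavailable.

## Objective and fit statistics

RSS_T sums squared deviations between replicate-mean observations and
simulated values over sampling times, species and profiles, unweighted
across species (mM and % enter as-is).  The PAC component RSS_P is included
by default; `include_P=False` reproduces the originally reported
five-component (A, B, Q, R, E) form of the objective.  By-products observed
below the detection limit are encoded as 0 mM, so RSS_Q/RSS_R penalise
simulated by-product formation.

Degrees of freedom per profile are n_obs − n_params = 8·6 − 10 = 38;
MSE = RSS_T/DOF.  Combined RSS_T and combined MSE over profiles are *sums*
of the per-profile values — the convention under which the published
per-profile and combined values are mutually consistent (24.6 + 66.5 =
91.1; pooled-DOF division would give 40.3 instead).  R² = 1 − RSS_T/TSS_T,
with TSS_T summing each species' total squares about its own observed mean
(no standard definition is attached to the reference values; this one is
the package's choice).

## Parameter estimation

The estimator is a derivative-free multiplicative grid search with a
refinement stage:

1. **Sweep phase.**  For each constant in reporting order, candidates are
   the current value times a fixed multiplier set
   {0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.25, 2}; the best candidate is
   accepted greedily and the move repeats (≤ 30 times) until no candidate
   improves.  The correlated pairs (K_ma, V_p) and (h, K_b) are searched on
   a joint 2-D candidate grid: their one-dimensional conditional optima lie
   along nearly degenerate directions, and one-at-a-time moves can slide
   into a spurious basin in which K_ma collapses towards zero (an actual
   local minimum, separated from the global one by an RSS barrier).  After
   each sweep a pattern move line-searches along the net sweep direction.
   The multiplier set sqrt-shrinks towards 1 when a sweep stalls; the phase
   stops when a sweep on the refined grid improves RSS_T by less than the
   convergence search criterion (CSC, default 1% relative).
2. **Refinement stage.**  Powell's conjugate-direction method (no
   gradients) over the nine log-parameters follows the flat, curved valleys
   of the objective down to the minimum.  t_lag is frozen here: it shifts
   the branch point of the integration grid, so RSS_T is piecewise in it
   and line searches stall on the jitter; it is located by the sweep phase
   only, which is consistent with its identifiability (about one
   integration step).
3. Phases alternate until a full cycle improves by < 10⁻⁶ relative
   (≤ 8 cycles).

Candidates outside the bounds are never evaluated; a candidate whose
simulation fails or yields non-finite RSS_T is rejected with a logged
warning.  Default bounds are ±3 decades around the start values, with
h ∈ (1, 3] and t_lag ∈ [0, 30] min.  The wide-but-finite default matters:
with effectively unbounded parameters, deep refinement on noisy data can
run away along the V_p/K_b/K_ma degeneracy to physically meaningless
values.

On noiseless synthetic data generated at the optimised reference constants
(30/36 + 100/120 mM conditions), the search started from the literature
initial values reduces RSS_T by ~10¹² and recovers every constant to
≲ 0.1% except t_lag (within one step) — comfortably inside the 10% band
asserted for V_p, K_ma, k_d1 and h.  Identifiability is uneven: K_ma
(pyruvate is nearly saturating throughout), k_a (a ~0.5% absolute effect on
E over 210 min) and t_lag are weakly determined, which shows up in the
parameter-error analysis below.

**Parameter errors.**  The original study's point-wise error propagation is
described only in an external reference.  The package uses a transparent
sensitivity stand-in, labelled as such in reports: refit against
observations shifted to mean + SE and to mean − SE; each parameter's error
is half the absolute range of its two refitted values.  For the
well-identified constants (V_p, K_b, h, K_ma) this agrees with a
parametric-bootstrap standard deviation within a factor of 3 on the
two-profile design.  For the weakly identified constants the two notions
diverge structurally — a correlated shift of all observations barely moves
parameters that respond to replicate scatter — so bootstrap-style errors
should be preferred when those matter.

**Validation.**  `validate` simulates with fixed parameters under a
held-out profile's conditions and reports the objective breakdown and fit
statistics; no parameter is updated.

## Synthetic data

The generator emulates the study design: three initial
benzaldehyde/pyruvate pairs (30/36, 50/60, 100/120 mM; molar ratio 1.2),
buffer levels 20/250/500/1000 mM with model calibration at 250 mM, 8
sampling times (0–210 min, 30-min interval) and quintuplicate replicates.
The canonical pairs use the study's apparent initial states (E₀ 89.4, 96.4,
114%; P₀ at the 0.01 mM apparent baseline; Q₀ = R₀ = 0); other pairs draw
E₀ uniformly from 89–114%.  Replicates are truth + Gaussian noise with
sd = max(CV·truth, floor), truncated at zero; the published error bars are
described only as "relatively small", so CV = 2% with 0.1 mM / 0.5%
absolute floors is an assumption (configurable).  By default acetaldehyde
and acetoin observations are zeroed to emulate the detection limit, since
neither by-product was detected experimentally.  Datasets are pure
functions of (parameters, design, noise model, master seed); per-profile
child seeds are derived by fixed offsets.

What the generator does *not* emulate: measurement-method-specific error
structure (HPLC vs enzymatic assays), benzaldehyde evaporation or
acetaldehyde volatilisation beyond the rate equations, replicate-to-replicate
variation in initial conditions, and any model misspecification.  Passing
recovery tests therefore demonstrate the correctness of the estimator under
the model's own assumptions, not the model's adequacy for real profiles —
reference fits to real data carry MSEs of order 17–67, far above replicate
noise, so real residuals are dominated by structure the model does not
capture.

## Problem sizes and runtime choices

The full-depth recovery fit (two profiles, 8 sampling times, ~2·10⁵
objective evaluations) is computed once and shared across checks.
Workflow-level checks (the config-driven fit/validate pipeline) use a
reduced search budget (40 sweeps, no refinement stage, one cycle), which is
ample for their R² > 0.99 assertions on noiseless data.  The bootstrap
comparison uses 12 parametric replicates of the two-profile design; more
replicates sharpen the standard-deviation estimate slowly (∝ 1/√n) without
affecting the factor-of-3 comparison.

## Known limitations

- Fed-batch/continuous feeding, two-phase systems, temperature/pH
  dependence and cofactor (TPP/Mg²⁺) mechanisms are out of scope.
- The grid search is a local method; it is robust from the literature
  starting values with the safeguards above, but pathological starts can
  still end in a secondary basin.  The search trace and final RSS_T are
  always reported so such cases are visible.
- R² and the parameter-error scheme are package conventions (documented
  above), not reproductions of the original (undocumented) definitions.
- Euler–Cauchy at 0.6 min carries ~1% discretisation error relative to a
  tight adaptive reference; it is retained because the reference constants
  were estimated under this convention.
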