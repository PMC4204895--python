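# Methods

## Model

Gene expression dynamics are modelled per gene as
dY_i/dt = F_i(A_i) − d_i·Y_i, with A_i = Σ_j q_ij·X_ij the signed weighted
sum of the levels of gene i's regulators (transcription factors and, where
declared, external signals). F is the bounded sigmoid
k1/(1 + k2·e^(−k3·A)). When the realized combined input is negative
(repressors dominate), the reflected form k1·k2·e^(k3·A)/(1 + k2·e^(k3·A))
is used instead; it is the same sigmoid with k2 ↦ 1/k2 and decays to 0 as
A → −∞. The two branches coincide for k2 = 1 and are dispatched on the
sign of A; either branch can be forced through the API for alternative
readings. Genes with no regulators transcribe at the constant basal rate
k1/(1+k2), the A = 0 value of the canonical branch (continuity is the only
argument for this constant; it is configurable). mRNA decay is first
order. Units: expression in arbitrary units (a.u.) of the upstream array
normalization, time in days (day 0 = induction of differentiation), k1 in
a.u./day, k3 in 1/a.u., d in 1/day, k2 and q dimensionless.

Assumptions worth stating: transcription responds instantaneously to
regulator levels (no delays), regulation acts through a single scalar
combined input per gene (no AND/OR logic beyond the weighted sum), decay
is not regulated, and the sign of every regulation is known a priori from
the topology.

## Data handling

Expression tables are gene × day matrices, floor-truncated at 20 a.u.
(values below the floor are considered unreliable; truncation is
idempotent and applied at load time). Sparse grids — the mouse-style
day −2/0/2/7 course — are densified by per-gene piecewise-linear
interpolation, never extrapolated; interpolated columns are flagged so
residuals can exclude them (off by default). Before any PLS step, each
feature row x is rescaled to x·mean(x)/std(x) (sample standard deviation,
n−1). This deliberately up-weights highly expressed features instead of
autoscaling them to unit variance, counteracting the information loss of
floor truncation; constant rows (genes pinned at the floor) pass through
unchanged and are flagged degenerate. The record of scale factors inverts
the transform exactly.

## PLS core

The dimension-reduction engine is single-output covariance-direction PLS:
each direction vector is the unit vector proportional to cov(x_i, y) of
the current residuals; inputs and output are regressed on the component
scores and deflated; iteration stops at a residual tolerance, at a
zero-covariance direction, or at n_samples − 1 components. X and y are
mean-centered internally and the intercept recovered, so a full-component
fit on tall full-rank data reproduces ordinary least squares exactly —
the property the test suite pins at 1e−8. Coefficients over the original
inputs are recovered by accumulating the deflation maps
X_{m+1} = (I − ax_m·p_mᵀ)·X_m. Component count is selected by minimizing
RSS(m) + λ·ln(1+m) with λ defaulting to the sample variance of y (one
output-variance unit per log-component; configurable). Fitted weights
whose sign contradicts the declared regulation are replaced by ±ε
(ε = 1e−3 on the normalized scale, configurable); the operation is
idempotent.

## The SSIO loop

Step 1 initializes per-target weights by sign-constrained PLS of regulator
levels against the target, L1-normalized per target. Step 2 initializes
kinetics at k1 = max observed level, k2 = 1, k3 = 1/std(A) (unit
steepness on the realized input scale), d = ln 2/2 per day (a two-day mRNA
half-life), with optional seeded jitter. The loop then alternates:

- **Kinetics (M-step).** Per gene, (k1,k2,k3,d) minimize the one-step-ahead
  shooting error: from each training timepoint the gene's ODE is
  integrated to the next timepoint and compared with the observed value.
  The gene's regulators are held at the piecewise-linear interpolation of
  the *training data* across each interval — both interval endpoints are
  data-anchored, so this conditional treatment stays close to a
  full-system restart while making the objective separable per gene and
  cheap (the scalar ODE is integrated by classical RK4 at 16 substeps per
  interval; the optimizer is bound-constrained trust-region least squares).
  Default bounds: k1 ∈ (0, 10·max level], k2 ∈ (0, 100], k3 ∈ (0, 10],
  d ∈ [1e−4, 5] — rates on the data's scale.
- **Weights (E-step).** The full system is simulated from the first
  timepoint with the stiff BDF solver; per target, PLS regresses the
  *simulated* regulator trajectories against the observed target; the new
  weights are q_prev + s·u with u the sign-constrained, L1-normalized PLS
  coefficient vector and s a per-target scalar optimized on the same
  one-step objective (a step that increases the objective is rejected,
  s = 0). Sign constraints are re-enforced after the update.

Each iterate is scored by BIC = N·ln(err²/N) + P·ln N with
P = [Σ |atan q_t − atan q_{t−1}|]·ln(iteration); err² is the one-step
residual pooled over genes and timepoints and N its count (a per-gene
breakdown is also emitted). The loop stops when the relative L1 change of
the weight vector falls below 1e−8 or after 100 iterations (defaults),
and the minimum-BIC iterate is returned. Both the sign constraint and the
component penalty can be disabled in the config to reproduce over-fitting
behaviour deliberately.

For the adipogenesis networks, samples strictly between induction (day 0)
and the immature-adipocyte stage (day 3 human / day 2 mouse) are dropped
from CEBPB's objective: external cAMP/GR signalling — not the modelled
TFs — dominates CEBPB there. This is implemented as a general per-target
timepoint mask supplied by the caller. Human GATA2 sits at the truncation
floor throughout, so all GATA2-sourced weights are frozen at zero for the
human variant.

## Built-in topologies and signals

Both 15-gene adipogenesis variants (core network, and the variant with
five candidate feedback edges from the key markers onto KLF4, GATA2,
STAT5A, STAT5B and KLF15) ship as constructors and as JSON/SIF files.
The sign map defaults to: anti-adipogenic factors (KLF4, GATA2, GATA3,
KLF2) repress, everything else activates; the feedback edges default to
PPARG→STAT5A(+), CEBPB→STAT5B(+), CEBPB→KLF15(+), CEBPB→KLF4(−),
CEBPB→GATA2(−). All signs and edges are overridable in the topology file,
since combination logic and exact sign assignments are a modelling choice.
Signal schedules: cAMP and GR run from day 0 to the immature stage, then
IR switches on and stays on; human cAMP/GR intensities decrease linearly
to zero over the window, mouse intensities are constant (no intermediate
mouse observations exist to constrain a shape). Signal intensity units
are a.u.; the default magnitude is 1 and is meaningful only jointly with
the fitted signal weights.

## ODE integration and equilibria

The stiff integrator is the BDF (Gear-type implicit multistep) family at
rtol 1e−6 / atol 1e−8. Tiny negative solver excursions are clamped to 0 in
reported trajectories only — never fed back into the solver state.
Equilibria are found by integrating over a 100-day horizon and polishing
the endpoint with non-negative trust-region root finding on the RHS; the
result must satisfy ‖dY/dt‖∞ < 1e−8 or an error is raised.

## Sensitivity analyses

**Regional (behavioral) sensitivity.** Parameters are sampled by a
Metropolis–Hastings chain whose stationary density is taken reciprocal to
the model's residual error; the proposal is an independence draw from the
uniform prior, which cancels the transition kernel in the acceptance
ratio α = min(1, (err_n/err*)^γ) (γ = 1 by default; a random-walk
proposal and other exponents are available). Priors per role: degradation
rates ±0.1 around the fitted value, regulatory weights uniform(0,1),
everything else uniform(0, 2v) if v > 0.25 else uniform(0, 0.5). Each
chain state is classified behavioral iff the simulated key markers end
above the midpoint of their observed pre/post levels with signals on and
below it with signals off (strict inequalities: a marker exactly at the
midpoint, or a failed integration, counts non-behavioral). After removing
a burn-in of 10000 states (default), each parameter is scored by the
maximum |CDF difference| between behavioral and non-behavioral samples on
a fixed 10-interval grid spanning its prior.

**Bistability scans** hold signals at zero, sweep one control parameter
(typically a key gene's k1) over an increasing grid, and compute
equilibria from a low and a high initial state. The trigger level is the
smallest control value at which the previously separated low branch has
jumped to the high branch; the separation threshold defaults to 5% of the
high branch's maximum. **Local sensitivity** re-runs the scan under
relative perturbations of a chosen parameter and reports whether
bistability persists and how far the trigger moves. **Importance
ranking** scores regulator i of target j as |∂(dY_j/dt)/∂X_i|·X_i =
|F′(A_j)·q_ij|·X_i at each differentiation-stage state (default stage →
day mapping: proliferating = −2, preadipocyte = 0, immature = 3 human /
2 mouse, mature = last day), descending per target, ties broken
alphabetically. **Cross-species comparison** evaluates q_i·X_i per
regulator at the four stages, z-scores the three stage-to-stage change
vectors within species, and compares species by the asymptotic two-sample
Kolmogorov–Smirnov test (exact small-sample mode available); targets with
fewer than two regulators in either species are reported undefined.

## Synthetic data

The generator emulates the features of short differentiation courses that
matter to the estimator: 4–9 (up to 20) timepoints, expression in the
tens-to-hundreds of a.u., floor truncation at 20, trajectories from the
sigmoid-ODE model itself, and multiplicative log-normal noise with unit
mean and configurable CV (positivity-respecting; real array noise is
heavier-tailed and probe-structured, which the generator does not
emulate). It does not emulate microarray probe-level artifacts,
normalization residue, or model misspecification — so passing recovery
tests demonstrates correctness of the estimator under its own model
family, not robustness to violated kinetics. Four curated cases with
frozen seeds provide ground truth: `cascade3` (noiseless 3-gene cascade,
20 points — weight-sign/ranking recovery), `feedback_bistable2` (two-gene
mutual activation whose two stable states and saddle-node location are
verified by brute-force enumeration of the reduced 1-D fixed-point
equation, independent of any ODE integration), `adipo_mini5` (a 5-gene
stimulus-latch motif that is behavioral by construction: a transient
signal pushes a mutually-activating pair past its basin boundary), and
`model1_like15` (the 15-gene core topology with generated parameters on
realistic scales — explicitly not fitted values from any real dataset —
as an end-to-end smoke case on the sparse mouse-style grid).

## Numerical choices and edge cases

- One-step objectives use fixed-step RK4 (16 substeps/interval): error
  O(h⁴) is far below data noise, and fixed stepping keeps objectives
  smooth for the trust-region optimizer and runs bit-reproducibly.
- Covariances below 1e−12 count as zero: PLS stops and keeps existing
  components (further directions are undefined).
- err² in the BIC is floored at machine epsilon before the logarithm.
- Sigmoid exponents are clipped at ±500 before exponentiation; both
  branches are evaluated in overflow-safe form.
- The importance-ranking test oracle uses central finite differences in
  extended (80-bit) precision: near saturation the difference of two
  rate evaluations cancels ~10 significant digits, which double-precision
  differencing cannot survive at the 1e−6 agreement level.
- Degenerate weight updates (step increases the objective) fall back to
  s = 0, so the best iterate's residual never exceeds iteration 1's.
- All stochastic operations take explicit integer seeds and reproduce
  byte-identical outputs; the CLI stamps every run with its full config
  and a config hash.

## Problem sizes

The shipped benchmarks are sized for interactive use: fits run ≤ 8
iterations on ≤ 20 timepoints, bistability scans use 13-point control
grids against a 5-a.u.-step brute-force oracle, and MCMC calibrations use
12 000 steps with 2 000 burn-in (10 000 kept samples). All are package
defaults chosen to make the full verification suite run in well under a
minute each.

## Known limitations

- One-step-ahead fitting conditions on observed regulator trajectories;
  with very sparse grids (4 points) the linear-interpolation assumption
  inside intervals biases kinetics toward the interpolant.
- Only relative regulatory weights are identifiable: k3 absorbs the
  overall input scale (weights are reported L1-normalized per target).
- The reflected-sigmoid dispatch is discontinuous at A = 0 when k2 ≠ 1;
  fits that cross A = 0 repeatedly can see small objective kinks.
- The Metropolis independence sampler explores the prior box only; it
  cannot concentrate on narrow posterior modes the way a tuned
  random-walk chain would (one is available behind config, untuned).
- No structure learning: the topology, including every regulation sign,
  is an input.
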