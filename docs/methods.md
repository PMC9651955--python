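# Methods

`sizevolve` simulates a minimal two-phase cell cycle coupled to gene-network
dynamics in a growing cell, evolves populations of such networks under
fitness pressure, and classifies the size-control mechanisms that emerge.
This note records the model, the defaults, and the design choices that were
genuinely open.

## The cell-cycle model

Cell volume grows exponentially, `dV/dt = λV`, with `λ = 0.5` per time unit
by default so the doubling time is `τ = ln 2 / λ ≈ 1.39` time units (one
time unit ≈ 30 min, so τ ≈ 40 min — a fast-cycling yeast-like cell).
Volume is expressed in units of the typical birth size. The cycle has two
phases:

- a **size-controlled phase** that ends stochastically with rate
  `h(s) = h_max K_h^n / (K_h^n + s^n)` where `s` is the sensed inhibitor
  signal — the *quantity* `I = [I]·V` by default, or the *concentration*
  `[I]` in concentration-sensing mode. Less inhibitor means a higher chance
  of progressing. Defaults `h_max = 20`, `n_h = 4`; `K_h = 0.16` was set
  once so that the seed network's mean G1 is ≈ 0.46 τ at V ≈ 1, matching
  the baseline structure in which G1 takes 46% and the timer 54% of the
  doubling time.
- a **timer phase** of duration `f_T · τ · (1 + U(−w, w))`, defaults
  `f_T = 0.54`, `w = 0.1`.

In the default (budding-yeast-like) structure the controlled phase is G1
and the timer is S/G2/M; in the inverted (fission-yeast-like) structure G1
is the timer and S/G2/M is controlled. The binary switch pseudo-species is
1 during the timer phase and 0 otherwise and acts as an exact 0/1
transcription factor. Division halves the volume (optionally with
partition noise, fraction `N(0.5, 0.5·CV)` truncated at ±3 sd); quantities
split in proportion to volume, so concentrations are continuous across
division. One daughter is followed. Lineages die below `V_min = 0.1`; the
volume is capped at `V_max = 10` and the record flagged, which downstream
fitness treats as a penalty.

## Network dynamics

Production of species X in concentration units follows

    (ρ0_X + Σ_activators ρ_a · h_act) · Π_repressors h_rep − δ_X[X] − λ[X] − complexation,

with Hill regulation `h_act = c^n/(K^n + c^n)`, `h_rep = K^n/(K^n + c^n)`.
Additive activators with multiplicative repressors is the common GRN
convention; repressors therefore carry no strength parameter of their own
(a repression gates the target's total production). Because production is
proportional to volume, concentration dynamics are volume-independent
except through dilution — the modelling constraint that forces nontrivial
size sensing. Complexes (`k_on[A][B] − k_off[C]`, degraded at `δ_C`,
diluted, partitioned like proteins) are inert: they regulate nothing and
are never sensed; titration needs only sequestration.

Molecular noise uses tau-leaping: each elementary reaction of
concentration-rate k advances by `kΔt + N(0, kΔt)` in molecule numbers
(`ω0·V` molecules per concentration unit; `ω0 = 1000` at `V = 1` ≈ 100 fL),
so concentration noise variance scales as `1/(ω0 V)` — small cells are
noisy. Dilution is deterministic (growth is not a chemical reaction). The
integrator is forward Euler at `dt = 0.01` with concentrations floored at
zero; degradation and complexation fluxes are capped at the available
material per step so that a mutant's stiff kinetics cannot manufacture
mass — integration failures that remain are treated as nonviable networks
during evolution and penalized rather than raised.

## Evolution

A population (default 50) of networks is evaluated each epoch on a fresh
stochastic lineage; fitnesses are NDiv (divisions in `T_total`, maximize)
and CVBirth (birth-size CV, minimize), with alternatives (target-size
residual, added-volume slope) available. Dead or degenerate lineages take
a CVBirth penalty ceiling of 10; touching the volume cap adds a penalty
*graded by the fraction of capped cycles* (10 × fraction, on top of the
measured CV). The grading matters: a binary cap penalty scores a first,
weak controller that brushes the cap once per hundred cycles identically
to a lineage pinned at the cap, removing the incremental path through
which weak control is refined into tight control. Selection peels Pareto
fronts (strict improvement in one objective, no worsening in the other),
keeps half the population — breaking the boundary rank by niche-count
fitness sharing in normalized objective space (radius 0.1 of each
objective's range) — duplicates the survivors and mutates the duplicates.

Mutation follows a numerical Drake's rule: every mutable element (each
parameter, each removable interaction, and one add-interaction plus one
add-species slot) is hit independently with a probability normalized so
the expected number of moves per network per epoch is exactly 1, with
weight mass 0.8/0.15/0.05 for parameter-change/removal/addition.
Parameter moves are multiplicative log-normal steps (σ = 0.3 in natural
log) clipped to the bounds ρ, K, k_on, k_off ∈ [10⁻³, 10³],
δ ∈ [10⁻², 10²], Hill n ∈ [1, 10]. Newly added elements draw their
parameters log-uniform over [1/20, 20]: a freshly rewired gene starts with
kinetics of ordinary magnitude (the unit conventions put meaningful scales
near 1), and mutation then explores the full bounds multiplicatively.
Drawing new elements over all six decades instead makes almost every
addition inert or lethal and pushes motif discovery far beyond practical
epoch horizons.

**Evaluation horizon.** `T_total = 150` time units (~108 cycles). This is
deliberately long: within ~35 cycles a weakly unstable network whose
log-volume performs an amplified random walk restarted from `V = 1` every
evaluation is statistically indistinguishable from — and often beats — a
genuine homeostat on both fitnesses, and selection then fixes lottery
winners instead of mechanisms. At ~108 cycles such strategies reliably hit
the death/cap bounds within a single evaluation and take the penalty, so
only true feedback control survives selection.

## Reference models and calibration

`seed_network()` is the minimal relaxation oscillator (Switch activates I;
I gates G1/S through its quantity). It cannot control size: G1 exit at a
fixed inhibitor quantity gives `V_G1S ∝ V_birth^{1+λ/δ}`, an exponent
above 1, so deviations amplify each generation — the package's instability
tests check exactly this signature.

`mixed_feedback_network()` adds one gene R that is repressed by I and
titrates I into an inert complex. R is synthesized only in the low-[I]
window around G1/S, where `[I] ∝ 1/V_G1S`, so `[R]` remembers the cell's
size; titration by that memory makes the inhibitor's G1 decay
size-dependent and closes the loop. Its kinetic parameters are the output
of `calibrate_homeostasis` (random log-normal search around the topology's
natural scales followed by coordinate descent, scored lexicographically on
viability, NDiv, then CVBirth over a 600-time-unit lineage), frozen as the
builder's defaults: ten independent 600-unit lineages then survive
unpenalized with mean `T_cycle/τ = 1.000 ± 0.001`, mean `T_G1/τ ≈ 0.455`,
CVBirth ≈ 0.19, and a whole-cycle added-volume slope ≈ 0.3–0.5 (a weak
adder/timer — consistent with CV-minimizing selection favouring weak
control). The `a2` variant adds switch-repression of R and R-repression of
I and carries its own calibration. The seed topology, calibrated under the
same procedure, fails as expected — there is nothing to calibrate into
homeostasis.

`fluctuation_network()` (concentration sensing, molecular noise on) adds a
self-activating gene A with steep (Hill n = 8) self-activation and equally
steep activation of I. Its parameters were chosen so that (i) the
deterministic, sub-threshold cycle has period < τ (the lineage shrinks),
and (ii) the activator's off-state sits a few noise standard deviations
below its ignition threshold at small volumes. Small cells then
stochastically ignite [A] bursts that flood the cell with inhibitor and
arrest it in a long G1 — statistical size control over many generations,
with a heavy tail of cycle durations past τ. The preset config lowers
`V_min` to 0.02 because this mechanism lets cells shrink well below the
typical birth size before rescue.

`ideal_rule_lineage` generates archetype lineages without any network: the
sizer divides at a fixed size, the adder after adding a fixed volume, the
timer after exactly τ. The noise parameter jitters the division fraction
(multiplicative lognormal at the stated CV) rather than the rule's
set-point. This is deliberate: with set-point noise the OLS slope of
ΔV_cycle on V_birth has standard error ≈ 2/√n *independent of the noise
amplitude* (the same shock enters the residual and the next birth volume),
so no finite noise level yields a sharp slope; division-fraction noise
keeps each archetype's return map — and its defining slope of −1/0/+1 —
exact while giving birth sizes a realistic spread. All stated archetype
properties (full correction in one generation for the sizer,
birth-volume autocorrelation 1/2 for the adder, constant volume for the
noiseless timer) hold under this choice.

## Diagnostics

- **Added-volume slopes**: unweighted OLS of ΔV per phase against
  phase-entry volume (birth for G1/cycle, V_G1S for S/G2/M), on ≥ 10
  post-warm-up cycles (first 10 cycles discarded everywhere); split fits
  break at the median entry volume.
- **CVBirth**: sample std (n−1) over mean.
- **T(V_C) curves**: the sensed variable uses a fixed control volume V_C
  while the real volume still grows and divides (bounds released, since
  the open-loop volume drifts by construction); ≥ 50 cycles per grid
  point after discarding 5. In birth mode the volume is instead reset to
  V_C at each division, which sets the molecular-noise scale. Archetype
  references: timer `T/τ = 1`; sizer `1 − log2(Vc/⟨V_G1S⟩)` (growth to a
  fixed final size); adder `log2(1 + ⟨V_G1S⟩/Vc)` (fixed increment); all
  floored at `f_T` (the incompressible timer) and all passing through
  (⟨V_G1S⟩, 1).
- **Perturbation recovery**: one division ratio is altered so a cycle is
  born at (1 ± m)×steady-state mean (probe and perturbed run share the
  RNG seed so the kick is exactly relative to the run's own history);
  recovery is the 1-based index of the first post-kick cycle whose V_G1S
  is inside a ±10% band and stays for two cycles; never re-entering is
  reported as censored.
- **CCDF tails**: least squares on the log-log empirical CCDF above the
  90th percentile (sensitivity at 85th/95th; a drift above 1 between them
  flags a non-power-law tail). Validated on synthetic Pareto samples.
- **Burst statistics**: duration = time with [A] above 10⁻³ concentration
  units (a strictly positive floor, since "above zero" is measure-zero
  under continuous noise); amplitude = mean [A] over the cycle's G1.
- **G1 attractor**: deterministic fixed point of the switch-off branch
  with [A] clamped, integrated to convergence; the crossing where the
  attractor exceeds the hazard half-max concentration marks the
  bifurcation between cycling and stuck-in-G1 regimes.

## Problem sizes

The packaged tests and the acceptance script use scaled-down problem
sizes chosen as the smallest that keep every statistic's sampling error
well inside its assertion band: oracle lineages of 500 cycles,
homeostasis statistics over ~300 post-warm-up cycles, evolution runs of
population 50 for up to 500 epochs and ensembles of ~8 runs per structural
condition with 120-epoch runs from the calibrated mixed-feedback start.
The library itself has no such limits.

## What the synthetic conditions do and do not show

Everything here is generated by the package's own models: there is no
external data. Passing tests show that the implementation realizes the
stated dynamics, selection algebra, and statistics under the unit
conventions above — not that real cells share the parameter values; the
biology enters only through the model structure (exponential growth,
two-phase cycle, volume-proportional synthesis, 1/V molecular noise).
Sub-exponential growth, lineage trees (both daughters), cell-to-cell
communication, and SBML interchange are out of scope.
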