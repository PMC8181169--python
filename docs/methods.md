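# Methods

This note documents the models implemented in `biohybrid`, the assumptions
behind them, the provenance of every default parameter, and the numerical
conventions that make runs bit-reproducible.

## 1. Modelling frame

All three organism models are mean-field: they track compartment totals of a
well-mixed population, not individuals.  Each describes a binary collective
decision — bees left vs. right, fish CW vs. CCW, plant mass left vs. right —
as a balance of an *individual* channel (spontaneous switching, rate α) and
a *social* channel (mass-action switching, rate β), modulated by stimuli the
robots control and by multiplicative noise (scale σ).  The bee and fish
systems are closed (the compartment pair sums to the group size at every
step); the plant system has one source (stem ingrowth) and two sinks
(outgrowth) with exact per-step mass balance in between.

Noise terms are written inside the dynamical equations; we resolve the
ambiguity of such "noisy ODEs" by drawing every named noise variable **once
per time step** and holding it frozen across the stages of one integration
step (piecewise-constant random coefficients).  This matches the 1-s
sense-and-act cadence of the physical robots and avoids any stochastic-
calculus interpretation; no Itô/Stratonovich machinery is implied or needed.

### Solvers

* Bees and fish: classical fixed-step RK4 at Δt = 1 s.  The fish model also
  exposes an explicit-Euler switch (`FishModel(solver="euler")`) since at
  these rates both give nearly identical trajectories; RK4 is the default
  for consistency with the bee model.
* Plants: the dynamics are *defined* as difference equations at Δt = 1 min
  and are integrated with exactly that forward-difference step.

### Noise streams, seeds, replicates

Every distinct noise symbol has a named draw site (e.g. `bee.indiv_r`,
`fish.obs_cw_by_ccw`, `robot.decision`).  Site streams are spawned from
`SeedSequence(seed, spawn_key=(crc32(site),))`, so a (seed, site) pair gives
a bit-identical sequence on every run and distinct sites are independent.
Replicate *k* of an ensemble uses `SeedSequence(base_seed, spawn_key=(k,))`
— a splittable scheme with no collisions and no arithmetic on raw seeds.
Distribution per site follows the model definitions: U(1−σ, 1+σ) for bee
flow noise, U(0, 1) for bee observation noise and all fish noise,
N(1, σ_plant) for plant motion noise, N(0, σ_plantcasu) for plant detection
noise.

With all σ set to zero, runs with different seeds are identical — except
for presets whose *controllers* are intrinsically stochastic (the F2
two-state robot and the F3 tie-break coin consume draws regardless of σ);
the determinism property is therefore asserted on the fixed-schedule
presets.

## 2. Bee model

State (B_R, B_L, T_R, T_L): bees per side plus CASU-side temperatures,
advanced jointly by RK4.  Resting time after a stop is linear in local
temperature, anchored at two measured points — 1 s at 28 °C and 25 s at
36 °C (span τ_Δ = 24 s over T_Δ = 8 °C) — shortened by airflow φ and
doubled at full vibration ψ.  This linear law approximates the sigmoid
found empirically; the sigmoid is left as an extension hook.

CASU thermodynamics: passive exponential decay towards the 28 °C ambient
plus fixed-rate active heating/cooling outside a deadband ε around the
target.  Feedback targets step the *current* temperature by ±Δ_temp
depending on which side's 30-s gliding-average bee count is larger
(positive mode: crowded side warms; negative mode: inverted), clamped to
[28, 36] °C.  The gliding average warms up on the mean of the samples
available during the first 30 s.  On an exact observation tie both sides
take their else-branch (consistent with the controller equations).

Conventions and guards:

* The `switch_X` flow terms move bees *into* side X (the equations'
  subscripting is authoritative over any verbal gloss).
* After each step the bee pair is clipped at zero and rescaled so that
  B_R + B_L equals B_total exactly; a correction above 1e-6 of the total
  raises a warning (it indicates rates too fast for Δt = 1 s; the shipped
  defaults never trigger it).
* Temperatures are clipped to the CASUs' physical range [28, 36] °C, which
  also keeps the resting-time law inside its domain (it is undefined below
  ambient).
* Fixed-target runs start pre-heated at the t = 0 targets (the protocols
  heat the arena before releasing bees); feedback runs start at ambient.

## 3. Fish model

State (F_CW, F_CCW) plus the robot direction budget R_CW ∈ [0, 1].  With
sight area ≈ 1/5 of the arena (between 1/3 near the outer wall and 1/7 near
the inner wall), five or more agents mean no fish is ever alone, so in all
shipped presets only the social channel operates.  Fish perceive each
other's direction erroneously (scale σ_fish, one independent U(0, 1) draw
per error term per step) and align with the perceived majority via a
mass-action term whose denominator (+1) is the focal fish itself.

Robots enter every social term with weight n_robots · γ_fish, a linear
superposition consistent with the mean-field treatment (the single-robot
equations carry one γ·R term; F1 uses three robots).  γ_fish < 1 encodes
partial acceptance of the lure as a conspecific.  Setting γ = 0 and
n_robots = 0 reduces all equations *exactly* (bit-for-bit) to the
robot-free forms, which the tests verify against an independently written
oracle.

Robot controllers:

* constant direction (F1);
* exogenous two-state machine flipping with probability 0.014 per 1-s step
  (F2), initial direction a fair coin;
* closed-loop majority following (F3): each second the tracking software
  reports one observed CW proportion — true counts plus an antisymmetric
  counting error of scale σ_fishrobot, normalised by F_total so the two
  proportions always sum to 1 — and the robot follows the gliding average
  of the last `window` proportions (default 1 s, matching one proportion
  per model second; the window is configurable).  Exact ties and an empty
  history fall to a fair coin.

Guards: perceived counts are floored at 0 — with a compartment below one
fish-equivalent the "−1 self term" can push the raw expression negative,
a corner of the continuous state the counting argument behind the equations
does not cover.  The net switching flow is source-limited (a compartment
cannot lose more fish in one step than it holds), the same donor-cap logic
used in the plant model; afterwards the pair is rescaled to F_total
exactly.  The initial state is the symmetric split F_total/2 (2.5/2.5 for
five fish — the mean-field reading of an odd group).

## 4. Plant model

State (P_stem, P_Rflex, P_Lflex): flexible biomass in a central stem
compartment and on the two sides, at 1-min resolution, starting empty.
Constant influx ρ_in enters the stem; the stem splits evenly into the two
sides each step (so P_stem = ρ_in exactly from step 1 on); sides exchange
mass by phototropism (α_plant, weighted by the light ratio Λ) and
circumnutation (β_plant, mass-action with N(1, σ_plant) noise, so motion is
largest in balanced configurations); mass leaves by outgrowth at ρ_out.
Total flexible mass relaxes geometrically to ρ_in/ρ_out at rate 1 − ρ_out.

The tip's horizontal position is the inhomogeneity metric
Υ = 0.5·((P_R − P_L)/(P_R + P_L + 1) + 1) ∈ (0, 1): 0.5 is an upright stem,
and the +1 denominator pins low-mass (young) shoots near the centre, like a
short stem that cannot reach far sideways.

Light laws on Υ: positive feedback Λ = Υ + noise (light follows detected
mass; runs end with mass concentrated on one side), negative feedback
Λ = 1 − Υ + noise (tip held near centre), and the binary target-tracking
rule Λ = 1 if Υ < Γ else 0 — the distilled form of the evolved tip-guidance
controller: tip left of target ⇒ right light on.  Detection noise is
omitted in the binary rule (tip detection by image processing is nearly
perfect); a tie Υ = Γ falls to the else-branch (Λ = 0), an arbitrary but
fixed convention.  After adding Gaussian detection noise the feedback laws
clamp Λ to its defining range [0, 1].

Guards: the net side-switch flow is capped at what the donor side holds
after its own growth input and outgrowth, so compartments cannot go
negative in one step; because the cap moves mass only *between* the sides
it never disturbs the per-step balance Δ(total) = ρ_in − ρ_out·(P_R + P_L),
which holds to 1e-12 in every run.  The target-tracking preset uses the
three-phase schedule Γ = 0.85 (t ≤ 640), 0.2 (641–880), 0.5 (881–1200 min).
The time-to-height reading of the vertical axis is a plotting convention
only and plays no role in the dynamics.

## 5. Lattice scale-up

`biohybrid.lattice` realises the building-block idea minimally: a grid of
complete bee/CASU units where, after each unit advances its own dynamics,
nearest neighbours (von Neumann, reflecting boundaries) exchange bees
side-by-side at rate d_coupling times the momentarily mobile fraction B/τ.
Pair flows are antisymmetric and donor-capped (at most a quarter of a side
per neighbour per step), so the global total is conserved exactly.  The
flow law and boundary handling are this package's extrapolation — the
source concept specifies only "diffusion flows between neighbouring
systems" — and are documented as such.  A 1×1 grid replays the standalone
bee model's exact noise substreams and is bit-identical to it.

## 6. Parameters

Anchored by measurement or protocol (not tunable in spirit):

| parameter | value | role |
|---|---|---|
| τ_Δ / T_Δ | 24 s / 8 °C | resting-time law anchors (1 s @ 28 °C, 25 s @ 36 °C) |
| T_ambient, T_min / T_max | 28 / 36 °C | arena ambient and hottest CASU setting |
| obs_window | 30 s | CASU gliding-average window |
| sight_ratio | 0.2 | A_sight/A_arena (mean of 1/3 and 1/7 ≈ 1/5) |
| p_switch (F2) | 0.014 /s | exogenous robot switching probability |
| group sizes, durations, N | per preset | protocol constants (12/15 bees, 3–6 fish, 1200/780/360/1800 s, 1200 min) |
| Γ schedule | 0.85/0.2/0.5 | target-tracking phases |

Calibration defaults (chosen once so the ensembles reproduce the
qualitative regime separations the physical experiments show; the
choice procedure is reproducible via `scripts/calibrate_defaults.py`):

| parameter | default | rationale |
|---|---|---|
| α_bees | 0.1 | slow spontaneous stopping: symmetric wander persists over 20 min |
| β_bees | 0.06 | social noise strong enough for natural symmetry breaking (~0.65 majority at 28/28) |
| σ_bees | 0.9 | wide flow noise; the main driver of decision variability |
| λ_heating | 0.1 °C/s | CASU reaches 36 °C in ≈ 2 min, matching fast actuation |
| λ_cooling | 0.01 °C/s | weak active cooling: under negative feedback both sides ratchet warm, slowing the bees and freezing the split near 50:50 — the suppression mechanism |
| λ_passive | 0.005 /s | ≈ 3 min passive decay to ambient |
| ε_temp, Δ_temp | 0.5, 1.0 °C | deadband just below the 1 °C feedback step |
| σ_beecasu | 0.4 | substantial one-sided undercounting (blind spots, occlusion) |
| α_fish | 0.01 /s | spontaneous switching; inert in the shipped presets (no fish is ever alone) |
| β_fish | 0.01 /s | weak enough that a single exogenous robot measurably biases which consensus forms (F2 correlation ≈ 0.4) |
| σ_fish | 0.3 | moderate misperception; larger values invert majority perception |
| γ_fish | 0.7 | lure accepted as conspecific most, not all, of the time |
| σ_fishrobot | 0.1 | small tracking error; keeps the F3 loop tight |
| ρ_in, ρ_out | 0.4 /min, 0.01 /min | equilibrium flexible mass 40; ≈ 100-min turnover of the flexible zone |
| α_plant | 0.45 /min | phototropic response fast against outgrowth: posFB escapes the centre within a run, negFB holds the tip tightly |
| β_plant | 0.01 | circumnutation a perturbation on top of phototropism |
| σ_plant | 0.5 | strong motion noise, the escape driver under posFB |
| σ_plantcasu | 0.05 | small detection noise on Υ |

## 7. What the simulator does and does not emulate

The ensembles regenerate the *protocol structure* of the laboratory
studies: group sizes, run lengths, stimulus schedules, sampling intervals
and analysis windows, and replicate counts.  They reproduce regime-level
phenomenology — warm-side majorities, vibration- and airflow-induced
redistribution, the positive/control/negative feedback ordering, robot-
biased shoaling, tighter closed-loop coupling, and target-tracked plant
tips.  Passing tests therefore certify the implementation and these
qualitative regimes, not quantitative agreement with any animal dataset.

Known limitations, shared with any mean-field treatment: no spatial
structure, travel times, crowding or sensing range (agents are
infinitesimal and perfectly mixed), no population heterogeneity (age, sex,
state), and variance across replicates markedly below what real animal
groups show.  Fish speed, wall-following and lure kinematics, bee positions
within a side, 3-D stem geometry and branching are all outside the model's
scope.  The lattice module is a structural sketch for scale-up studies, not
a calibrated spatial model.

## 8. Problem sizes used in the checks

The quantitative reference script evaluates the two analytic resting-time
endpoints and 10^5 controller steps.  The regime tests use 100 seeded
replicates per arm for the bee-feedback ordering and the plant-feedback
separation, 100 replicates for the F1 bias and 50 each for the F2/F3
correlation comparison — ensemble sizes at which the reported medians and
orderings are stable across base seeds while the whole suite stays
inexpensive.
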