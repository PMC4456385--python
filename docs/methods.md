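# Methods

`bgrl` implements a network-level reinforcement-learning model of the basal
ganglia (BG) for a probabilistic reward/punishment categorisation task,
together with the behavioural statistics and parameter-fitting machinery
needed to compare simulated cohorts of healthy controls and Parkinson's
disease (PD) patient groups — ON/OFF dopaminergic medication, with and
without impulse-control disorder (ICD).

## Task

Four stimuli map to two responses. For reward stimuli (I1, I2) the optimal
response wins +25 points with probability 0.8 (0 otherwise) and the
non-optimal response with probability 0.2. For punishment stimuli (I3, I4)
the optimal response loses −25 points with probability only 0.2, the
non-optimal with 0.8. A session is 160 trials, each stimulus appearing 40
times in a seeded balanced shuffle ("pseudorandomised" is implemented as a
uniform seeded permutation of the balanced multiset; no blocking constraint
is imposed because none is defined). The model consumes rewards on the unit
scale r ∈ {−1, 0, +1} mapped from {−25, 0, +25}.

## Striatum: value, punishment and risk pools

Three pools of medium spiny neurons carry cortico-striatal weights over
(state, action): D1-receptor MSNs code action value Q, D2-receptor MSNs code
punishment expectation, and D1R–D2R co-expressing MSNs code risk h. Cortical
input is one-hot on the current stimulus, so each pool's response equals its
weight. Utility combines value and risk,

    U(s, a) = Q(s, a) − α_D1D2 · sign(Q(s, a)) · h(s, a)

with sign(0) := 0, making the agent risk-averse for gains and risk-seeking
for losses. A `risk_transform="sqrt"` switch applies a signed square root to
h (an older lumped-model convention); the default is linear, which is also
the form that preserves the four-group behavioural pattern in our
simulations.

Learning uses the immediate TD error δ = r − Q(s, a), passed through
receptor-specific sigmoid gains before the weight update:

    Δw_pool = η_pool · λ_pool(δ),   η_D1 = 0.01, η_D2 = η_D1D2 = 0.1

* λ_D1(δ) = 2/(1 + exp(−50 δ)) − 1 — rises with dopamine: rewards
  strengthen, punishments weaken the value weight.
* λ_D2(δ) = 2/(1 + exp(50 (δ + 0.05))) − 1 — the mirror image with a small
  NoGo margin: ≈ +1 for punishments, ≈ −1 for rewards, ≈ 0 for neutral
  outcomes. The D2 weight therefore accumulates punishment evidence. The
  midpoint at δ = −0.05 (rather than exactly 0) keeps the small negative
  prediction errors produced by reward omission from masquerading as
  punishments; without the margin the D2 weights of frequently-correct
  actions drift upward and the indirect pathway ends up suppressing correct
  responding wholesale.
* λ_D1D2(δ) = λ_hD1(δ) + λ_hD2(δ), the sum of an increasing and a
  decreasing half-height sigmoid (height 0.05, slope 50, midpoints ∓0.05):
  a U-shape in δ that is ≈ 0.008 at δ = 0 and ≈ 0.05 for |δ| ≥ 0.1, so the
  risk weight grows in proportion to squared surprise. The steep slope is
  essential: with a near-flat U-shape the risk pool contributes a constant
  Go bias toward previously punished (risky) actions, which in our
  calibration collapsed healthy-control punishment optimality below chance.

The gain constants ship in `bgrl/configs/gains.yaml`; the calibration above
is this package's own. Midpoints and slopes were set so that each pool
expresses its documented functional role (D1 = reward, D2 = punishment,
D1R–D2R = risk) and the four-group behavioural orderings below emerge; see
"Limitations" for what was explored.

## Parkinsonian dopamine availability

The TD error is conditioned on the subject group before any gain is
evaluated: healthy controls pass δ through unchanged; PD-OFF clamps it from
above at δ_Lim = 0.001 (dopamine-cell loss removes positive transients;
negative transients survive, so punishment learning is spared while reward
learning is abolished); PD-ON adds a medication constant δ_Med = 0.06 after
the clamp (tonic dopamine restores — and over-expresses — positive
learning). No lower clamp is applied. The per-group serotonin coefficients
(α_D1, α_D2, α_D1D2) and dopamine constants load from
`bgrl/configs/subjects.yaml`:

| group         | α_D1 | α_D2  | α_D1D2 | δ_Lim | δ_Med |
|---------------|------|-------|--------|-------|-------|
| HC            | 1    | 0.185 | 0.997  | —     | —     |
| PD-OFF        | 1    | 0.991 | 0.033  | 0.001 | —     |
| PD-ON-ICD     | 1    | 0.046 | 0.001  | 0.001 | 0.06  |
| PD-ON-nonICD  | 1    | 0.916 | 0.160  | 0.001 | 0.06  |

## Pathway gating and the utility-difference signal

At selection time a second dopamine signal, the trial-to-trial utility
difference δ_U, gates the pathways through a separate set of gain constants
(same functional forms; D1 midpoint −0.01, D2 midpoint +0.01, so that both
pathways are weakly active at baseline and dopamine tilts the balance toward
Go). Per candidate action i:

    x_DP_i = α_D1 · λ_D1(δ_U) · y_D1_i
    x_IP_i = α_D2 · λ_D2(δ_U) · y_D2_i
             + α_D1D2 · sign(y_D1_i) · λ_D1D2(δ_U) · y_D1D2_i

δ_U is the utility of the best currently available candidate minus the
utility realised at the previous selection (a scalar carried across trials;
0 on the first trial). Two alternative conventions are implemented and OFF
by default: `delta_u_mode="chosen"` (the realised post-selection difference,
gating the next trial) and `u_prev_mode="reevaluate"` (the previous action
re-scored in the current state). Both were evaluated against the four-group
behavioural pattern and both destroy parts of it (the realised form washes
out value-guided selection; the re-evaluated form, which makes δ_U
non-negative, removes the NoGo episodes that produce the slow non-ICD
reaction times), so the anticipatory scalar form is the default. δ_U is
shared by all candidate actions, mirroring a diffuse dopamine signal;
per-action δ_U is deliberately not supported.

## STN–GPe–GPi–thalamus race

One STN and one GPe unit per candidate action, coupled one-to-one, with
weak lateral connectivity (ε_s = 0.12 within STN, ε_g = −ε_s within GPe)
and explicit-Euler updates using the published per-iteration coefficients
(1/τ_s = 0.1, 1/τ_g = 0.033, STN output tanh slope 3). Unforced, the loop
sustains slow large-amplitude oscillations (period ≈ 230 iterations);
moderate indirect-pathway input (|x_IP| ≳ 0.2) pins it at a saturated fixed
point. This transition does the behavioural work: net-negative x_IP drives
GPe up and STN output to −1 (disinhibiting thalamus, fast "Go"), while
net-positive x_IP pins STN output at +1 (suppressing thalamus, "NoGo"), and
near-zero x_IP leaves oscillatory "Explore" noise in the race.

GPi combines the pathways, x_GPi = −x_DP + w·y_STN (w = 1), and the
thalamic afferent is its negation. Each thalamic unit integrates its
afferent; the first to reach the threshold 1.815 determines the choice, and
the iteration count is the reaction time (ties broken by maximum activity,
then lowest index). Within a trial the striatal drives are held fixed; the
STN/GPe state is re-initialised per trial with uniform ±0.01 noise (the
symmetry-breaking the race needs) and the thalamic integrators start at 0.

The thalamic update is y ← y + dt·(−leak·y + x). The `CircuitParams`
default is the leaky unit (leak 1, dt 0.1), which has the closed-form
crossing time ceil(log(1 − θ/x)/log(1 − dt)) used by the unit tests. The
behavioural simulations (`task_circuit_params()`) run the unit as a pure
accumulator (leak 0, dt 1) instead: with zero-initialised weights, value
steps of η_D1 = 0.01 and 40 trials per stimulus, the pathway drives stay an
order of magnitude below the threshold, which a leaky unit (asymptote =
drive) can then never reach, whereas an accumulator crosses in tens to a
few hundred iterations — the regime in which a race-to-threshold readout is
meaningful.

Races that have not crossed by the iteration cap (default 1,000) are
recorded as responses at the deadline and **included** in reaction-time
averages (`SimOptions.uncrossed_rt="deadline"`). This matters: the stalled
races are precisely the NoGo-suppressed trials of the strong-indirect-
pathway groups, and censoring them (the `"missing"` option) inverts the
group ordering of mean RT. Reaction times are reported in race iterations;
`ms_per_iter` (default 1.0) and `calibrate_ms_per_iter()` provide a purely
presentational linear scale to milliseconds.

## Simulated cohorts and what they reproduce

`run_group` simulates n independent sessions (default 100) per group with
consecutive seeds; a single vectorised engine advances all instances in
lockstep and is seed-for-seed identical to the per-subject reference path
(`run_trial`/`run_session`). With the shipped parameters the four groups
reproduce the qualitative clinical pattern, each ordering significant at
p < 1e-30 across 100 instances:

* reward optimality: PD-ON-ICD > PD-OFF (medication restores positive
  prediction errors; the OFF clamp abolishes them);
* punishment optimality: PD-OFF > PD-ON-ICD (strong serotonergic drive of
  the D2 pool gives OFF an intact punishment-avoidance channel; the ICD
  group has lost it);
* mean RT: PD-ON-nonICD > PD-ON-ICD and > PD-OFF (the non-ICD group
  combines a strong indirect pathway with medication-driven utility
  fluctuations, producing NoGo stalls; the ICD group's near-silent indirect
  pathway races unopposed; the OFF group's punishment-loaded D2 weights
  act through a net-Go gain at its near-zero δ_U).

A DA-only ablation (α_D1 = α_D2 = 1, α_D1D2 = 0 for every group, leaving
only the dopamine parameters δ_Lim/δ_Med to differ) collapses PD-ON-ICD and
PD-ON-nonICD onto identical models and loses the punishment ordering —
serotonergic modulation of the three pools is necessary, not decorative.

## Behavioural statistics

Per subject: proportion of optimal responses to reward stimuli, to
punishment stimuli (analysed on the percentage scale), and mean RT over
trials with an RT. Group comparison is a fixed-effects one-way ANOVA on the
per-subject summaries (the published df = (3, 72) with 76 participants
identifies the subject as the unit of analysis), preceded for RT by
iterative two-sided Grubbs outlier removal at α = 0.05 within each group
(subject-level means are screened; sd = 0 and n < 3 are treated as
outlier-free). Post-hoc pairwise t-tests are pooled-variance two-tailed by
default (`equal_var=False` switches to Welch); no multiple-comparison
correction is applied because none is reported for the reference analysis.
`anova_from_table` rebuilds MS, F, p and the α = 0.05 critical F from a
published table's SS/df cells, for internal-consistency checks.

## Synthetic cohorts

`synthesize_cohort` generates trial-level records shaped like the clinical
dataset: per subject a latent optimality per valence (truncated normal) and
a latent RT level (normal, occasionally inflated to emulate outlier-prone
responders), then 160 trials with Bernoulli optimal responding, schedule-
drawn outcomes and lognormal trial RTs (CV 0.25). The default profile uses
the published group sizes (20/16/14/26) and levels chosen once to express
the qualitative group pattern (reward optimality highest in PD-ON-ICD,
punishment optimality highest in PD-OFF, RT shortest in PD-OFF and longest
in PD-ON-nonICD; within-group spreads ~0.10–0.13 for proportions and 35 ms
for RT). The generator emulates the *structure* of the empirical data, not
its values: passing tests demonstrate that the analysis pipeline recovers
whatever pattern the generator encodes at these sample sizes, nothing more.
Real data differ in ways the generator does not model (trial-level RT
autocorrelation, within-session learning curves, response-key biases).

## Parameter fitting

Two-step estimation per group, reflecting the published free/fixed split
(HC: the three α's; PD-OFF: α's + δ_Lim; PD-ON-ICD: α's + δ_Med with δ_Lim
carried over from OFF; PD-ON-nonICD: α's with both carried over). Step 1
minimises the squared error between simulated and target (reward,
punishment) optimality with a coarse Cartesian grid whose best points seed
a real-coded GA (tournament size 3, BLX-0.5 crossover at 0.9, per-gene
Gaussian mutation at 0.1 with σ = 10 % of range, elitism 1 — all
configurable). Step 2 keeps every evaluated candidate within 10 % of the
best step-1 cost and returns the one with the smallest normalised squared
error to the target mean RT. All cost evaluations share one set of session
seeds (common random numbers), making candidate ranking stable and the
self-target cost exactly zero. Bounds: α's in [0, 1.2], δ_Lim in [1e−4, 1],
δ_Med in [0, 0.5]. Default budgets are grid 5 per parameter, population 50,
100 generations, 100 instances per evaluation; the test suite uses
`FitBudget.small()`-scale budgets and a shortened race deadline so a fit
completes in seconds — parameter recovery at that scale is assessed as
ordering recovery, not value recovery.

## Numerical choices and degenerate inputs

Selection ties: simultaneous threshold crossers resolve to the larger
thalamic activity, exact ties to the lowest index. Races that never cross
return the argmax at the cap, flagged `crossed=False`. Empty sessions
(n_trials = 0) return empty record lists and untouched weights. Grubbs on
constant vectors removes nothing; ANOVA requires ≥ 2 non-empty groups;
degenerate-variance t-test pairs return p = 1 (equal means) or NaN with a
warning. Weights start at zero (Q = h = 0 gives unbiased first choices) and
are finite-checked; an optional saturation bound (`weight_bound`) clips
them to [−b, b] and is off by default.

## Limitations

* The gain-constant calibration is this package's; during development we
  verified that plausible alternatives (a D2 learning midpoint far from
  zero, equal-signed selection midpoints, near-flat risk gains) each break
  at least one of the four group-level orderings, typically by letting the
  indirect pathway amplify whichever action early noise favoured.
* The within-group reward-vs-punishment *imbalance* of the ICD group is
  under-expressed: simulated PD-ON-ICD shows reward 0.67 / punishment 0.63,
  a smaller internal gap than healthy controls (0.71 / 0.62), even though
  every between-group ordering is reproduced. The acceptance suite tests
  this balance property and it currently fails; we report it rather than
  re-tune around it.
* Reaction times have no identified millisecond scale; only ratios and
  orderings are meaningful.
* The STN–GPe model is a two-unit rate loop; spiking dynamics, pallidal
  back-projections to GPi and noradrenergic modulation are out of scope.
* Fitting recovers parameter *orderings* under common random numbers at
  small budgets; exact value recovery is not expected from two behavioural
  summary statistics per group.
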