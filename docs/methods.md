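# Methods

This note documents the models, procedures and design choices behind
`glampi`, a pipeline for analysing immersive-VR triangle-completion
(path-integration) behaviour with a generative linear-angular model.

## The task and its standardization

A triangle-completion trial guides a participant along two legs of a
triangle (cone 1 → cone 2 → cone 3, lengths `l1`, `l2`, turn `θ2`) inside a
square tracking arena, then asks them to return to cone 1 unaided.  The raw
record per trial is the three cone positions, cone-arrival timestamps, the
response position (or the boundary-hit position for out-of-bound trials),
and 10 Hz head position/orientation samples.

Each trial is canonicalized before analysis: cone 1 to the origin, the first
leg along +x, and right-turn trials mirrored so every outbound turn is a
left (counter-clockwise) turn.  In this frame the produced inbound turn `θ3`
is the counter-clockwise angle from the final outbound heading
(cone 2 → cone 3) to the response direction from cone 3, wrapped to
[0, 2π) under the convention that the intended response uses the short
anticlockwise turn.  `θ2 ∈ (0, π]` is the magnitude of the egocentric
outbound turn after flipping.  All derived quantities are invariant under
rigid motions and mirrorings of the raw trial (property-tested).

Exclusion rules: trials whose inbound path terminates within 0.5 m of
cone 3 (no clear movement intention; measured as straight-line distance,
since that is what the downstream geometry uses); out-of-bound trials with
no recorded boundary-hit point (tracking fault); trials whose inbound
trajectory re-enters within 0.3 m of cone 2 (a configurable automated proxy
for the original study's manual retracing screen, applied when inbound
tracking is available); and finally any participant-condition cell with
fewer usable trials than the model has parameters (7).  Out-of-bound trials
are otherwise retained: their turn is valid, their distance is recorded as
missing (never zero) and excluded from all distance computations.

## Behavioural errors

Proportional linear error = ‖response − cone3‖ / ‖cone1 − cone3‖;
proportional angular error = `θ3` / correct turn, the correct turn computed
to the true cone-1 location in the same convention.  1 is perfect; <1 is
under-walking/under-turning.  Summaries average trial → participant-condition
cell → participant (unweighted across conditions) → group.

## The generative model

Seven parameters, Θ ∪ Φ = {k, g2, β, g3, m3, σ, ν}:

1. **Encoding.** Walked distance is accumulated by a leaky integrator of
   walking speed, `dl'/dt = −β·l' + k·v`.  At constant within-trial speed
   this integrates to `l' = l·k·(1−e^{−βT})/(βT)`; the first leg's trace
   keeps decaying during the second leg (extra factor `e^{−βT2}`).  The
   β → 0 limit is evaluated analytically, and the closed form is
   oracle-checked against numerical ODE integration (≤ 1e−6 over a
   β ∈ [−0.3, 0.8], T ∈ [1, 20] grid; β < 0 represents growth).  The turn is
   encoded with a gain: `θ2' = g2·θ2`.  For constant speed the time-domain
   encoder is exactly equivalent to the distance-domain integrator used in
   desktop (joystick) tasks at rate `α = β/v`; this equivalence is kept as a
   tested property, not a pipeline stage.
2. **Calculation.** The intended return is computed by vector addition of
   the encoded legs: `h = √((l1'+l2'·cosθ2')² + (l2'·sinθ2')²)` and
   `α = π − asin(l1'·sinθ2'/h)` (calculation noise terms are absorbed into
   the production noise below).  The asin form is implemented literally.  It
   equals exact planar geometry only while the encoded triangle's
   return-vertex angle is acute (`l2' + l1'·cosθ2' > 0`); past that point it
   returns a large turn where exact geometry returns a small one.  This
   branch behaviour is load-bearing: it is how a large angular encoding gain
   (g2 ≈ 1.45) generates simultaneous under-walking (h shrinks) and strong
   over-turning (proportional angular error well above 1), the joint
   signature of the amyloid-positive MCI profile.  `calculate_inbound`
   exposes a flag marking trials where the literal form and an atan2 oracle
   disagree.
3. **Production.** Regression to the session mean:
   `l3' = m3·h + (1−m3)·l̄r`, `θ3' = g3·α + (1−g3)·θ̄r`, where `l̄r`, `θ̄r`
   are the means of the *correct* return distance and turn over the
   participant-condition's usable trials.
4. **Noise.** The realised `l3`, `θ3` are Gaussian around `l3'`, `θ3'` with
   SDs σ, ν.  The negative log-likelihood of a cell is the sum of the two
   independent Gaussian negative log-densities per trial (distance terms
   omitted on out-of-bound trials).  The angular residual is linear — no
   re-wrapping of `θ3 − θ3'` — matching the model's Gaussian definition.

## Fitting and model selection

Each participant-condition cell is fitted by multi-start bounded L-BFGS-B
(default 20 Latin-hypercube starts plus one heuristic start at the
error-free values with moment-based noise SDs; deterministic given the
seed).  Bounds: k, g2 ∈ (0, 3], β ∈ [−0.5, 1], g3, m3 ∈ [−1, 2],
σ ∈ (1e−4, 3], ν ∈ (1e−4, π]; σ and ν are optimized on a log scale to keep
positivity.  Cells with fewer than 7 usable trials are refused.

The reported noise SDs carry a degrees-of-freedom correction
(`σ̂ = σ̂_MLE·√(n_d/(n_d−p_d))`, with `n_d` the number of distance
observations and `p_d` the number of free parameters shaping the distance
mean; analogously for ν̂ over all trials): the raw Gaussian-SD MLE is biased
low by ≈ √((n−p)/n) at these trial counts (≈ −11% at 27 trials with ~28%
out-of-bound), the same correction OLS applies to its scale estimate.  Raw
MLEs are kept alongside; NLL/AIC/BIC use the MLE.

Candidate models are the 2⁵ = 32 masks over {k, g2, β, m3, g3} (σ, ν always
free; masked parameters fixed at k=1, g2=1, β=0, m3=1, g3=1), compared by
mean AIC across cells (`AIC = 2·n_free + 2·NLL`, counting σ and ν as free;
BIC secondary; ties broken toward fewer parameters; cells missing any
candidate dropped pairwise).

## Group inference and classification

Two-way fixed-effects ANOVA (group × condition, Type-III sums of squares
with sum-to-zero contrasts for unbalanced designs) on participant-condition
cells — three rows per participant, deliberately treated as independent to
match the published degrees-of-freedom convention.  Bonferroni-adjusted
pairwise group contrasts form the post-hoc family within one measure.
One-sample two-tailed t-tests compare fitted parameters to their error-free
values; Pearson correlations screen demographic confounds; achieved power
uses the noncentral-F distribution with λ = f²·N.

Classification of clinical contrasts uses a single feature at a time: a
linear-kernel SVM (C = 1) under 1000 stratified 60/40 hold-out repetitions,
ROC/AUC per repetition from sigmoid-calibrated posteriors on the held-out
40%, curves averaged on a fixed 101-point false-positive-rate grid.  The
feature is z-scored inside each training fold (an unscaled narrow-range
feature gives the SVC a near-degenerate margin and an unstable calibration
slope).  Correlated AUCs are compared with DeLong's z-test, either per
repetition (fraction significant) or once on posteriors averaged over
repetitions; the DeLong implementation is checked against a bootstrap
variance oracle.

## The synthetic cohort generator

The generator emulates the study conditions so every stage runs without
clinical data: square arenas (3.5 m young / 4.0 m MCI / 4.5 m elderly),
pseudo-random triangles with cone 1 near the corner farthest from the
previous trial's goal and cones 2–3 near the two opposite sides
(cone 2–cone 3 separation ≥ 1 m), 9 trials per condition (12 for young),
constant within-trial walking speed that varies lognormally across trials,
10 Hz tracking with small position jitter and heading-facing orientations,
inbound responses drawn from the generative process above, and out-of-bound
truncation at the boundary plus the 0.3 m warning overshoot.  One cohort
seed expands into per-participant streams (SeedSequence spawning) so
regeneration is exactly reproducible.

Unstated placement tolerances were fixed once: cone 1 sits 10–30% of the
arena side from its corner's walls (a clearance so the return target is not
flush with the boundary), cones 2–3 within 25% of their sides; rejection
sampling additionally requires legs ≥ 0.5 m, a non-degenerate turn
(θ2 ∈ [0.15, π−0.15]) and an acute *physical* return-vertex angle — the
regime where the calculation stage's trigonometric branch is exact, which
makes the zero-noise closure property (response exactly at cone 1,
proportional errors exactly 1) hold on every generated trial.

Group parameter presets encode the qualitative group profiles (means, with
truncated-normal between-participant spread): elderly k=1.25, g2=1.05,
β=0.10, g3=0.80, m3=1.00, σ=0.30, ν=0.40; MCI− g2=1.15; MCI+ g2=1.45,
ν=0.75, σ=0.45; young near-veridical with low noise.  These were calibrated
once against the published group-level behavioural ranges and then frozen;
the synthetic elderly group lands at PLE ≈ 0.91, out-of-bound ≈ 29%, MCI+
at PLE ≈ 0.6 with the largest over-turning.  What the generator does *not*
emulate: curved or hesitant walking, boundary-aware response strategies
(real participants rarely walk straight out of bounds — the low-noise young
profile consequently over-produces out-of-bound trials, ~40% vs the
reported 13.8%), trial-order learning, and any link between conditions and
parameters (conditions share one truth per participant).  Passing tests
therefore demonstrate internal consistency of the pipeline under its own
generative assumptions, not fidelity to every property of clinical data.

## Validation studies and problem sizes

`glampi.studies` (run by the test suite and `scripts/acceptance.py`):

- **Parameter recovery** — 100 elderly-preset participants, 9 trials × 3
  conditions; fits pool each participant's 27 trials because the generator
  shares one truth across conditions.  Median bias of every parameter stays
  below 10% of its preset mean (observed ≤ ~3% after the df correction).
- **Group-difference detection** — 20 replicates of MCI+ vs MCI− presets,
  n=20 per group, per-condition fits (4 starts), group × condition ANOVA on
  ĝ2 and ν̂; detection ≥ 80% required (observed ~100%).
- **Model selection** — full-model truth (every structural error source
  clearly non-null: k=1.3, g2=1.15, β=0.15, g3=0.6, m3=0.7) with 14
  participants × 27 trials: the full model must win the 32-candidate AIC
  race; noise-only truth with 8 participants: the noise-only candidate must
  sit within 2 AIC units per spurious free parameter of the minimum.  These
  cohort sizes were chosen as the smallest at which the selection outcome is
  stable across seeds.
- **Classification sanity + synthetic contrast** — separable/null feature
  AUCs, single-split rank-AUC identity, DeLong null; plus a synthetic
  MCI+/MCI− cohort in which the angular parameters (ĝ2, ν̂) out-classify
  k̂, β̂, m̂3, reproducing the ordering that makes the angular terms the
  biomarker-relevant readout.

## Numerical notes and known limitations

- `(1−e^{−βT})/(βT)` uses `expm1` with a Taylor branch below |βT| < 1e−10.
- The asin argument is clamped to [−1, 1] against float overshoot; a closed
  encoded path (h = 0) is a degenerate-trial error.
- Zero σ or ν yields an infinite NLL (fit-reject signal), never NaN.
- Speed reconstruction: EMA with α = 0.9 initialized at the first finite
  instantaneous speed, Gaussian kernel of σ = 1 s (truncated at 3σ,
  reflected edges), stationary samples (< 0.2 m/s) and a 1 s burn-in
  excluded from the mean; all-stationary intervals return a missing value.
- Session means θ̄r are taken over usable trials only, and may lie in
  [−2π, 2π].
- A participant whose every trial is out-of-bound carries no distance
  information; σ/m3 are then unidentified and such participants are dropped
  from feature-based classification.
- Hierarchical (shared-prior) estimation, non-Gaussian noise, homing-vector
  variants and trial-order learning are out of scope.
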