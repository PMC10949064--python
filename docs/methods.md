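# Methods

## Detection model

**Threshold detector.** A trace is a regular grid of quantized T_sk samples
with a validity mask. Within each maximal run of valid samples, a state
machine flips to normothermic at the first sample of ≥2 consecutive samples
*strictly above* the threshold and to torpid at the first sample of ≥2
consecutive samples *at or below* it ("above" strict, "below" inclusive —
unambiguous with 0.5 °C-quantized data). Single-sample excursions never flip
state. The first qualifying run decides the initial state; earlier samples
join that first bout. Bout intervals are half-open `[start, end)` with the
last bout closing at the final sample time plus one cadence, so bout
durations tile the observed span exactly. Bouts abutting a trace edge or an
invalid gap are censored on that side and excluded from duration statistics
(kept in outputs with flags). Segments in which no run of length ≥2 exists
yield no bouts: the state is undecidable there.

**Behavioural detector.** Movement intervals separated by stillness shorter
than the merge gap (default 90 min, the "motionless > 1.5 h" termination
rule) merge into one arousal. An arousal runs from its first movement to its
last merged movement; the alternative convention that counts the terminal
stillness window as part of the arousal is exposed as
`end_rule="movement_plus_gap"`, since observational protocols differ on
this. Gaps of exactly the merge gap do *not* merge (stillness must exceed
the window to terminate; at the 1-min resolution of video logs the
distinction is immaterial, but the convention is fixed). The complement of
the arousals within the observation span forms the torpor bouts.

Because animals are removed from hibernation while torpid, the final torpor
bout is an artifact of the removal date; `drop_last_torpor` removes it, so
per-animal arousal counts may exceed torpor counts by one.

## Threshold calibration

The sweep runs the threshold detector at 13–27 °C in 1 °C steps, collecting
cohort arousal counts (all detections) and uncensored durations. The
count-vs-threshold curve is fitted with a continuous two-segment model
`y = β₀ + β₁x + β₂(x − ψ)₊`; ψ is grid-searched at 0.1 °C over the interior
(≥3 points per side), and a breakpoint is declared only when the two extra
parameters (ψ and the slope change) improve on a single line by an F-test at
α = 0.05. Perfectly linear data are handled explicitly (zero RSS on both
models ⇒ no breakpoint). Per-segment slope tests allocate the grid points at
`x ≤ floor(ψ)` to the left segment. ψ is invariant under affine rescaling of
the counts.

Duration concordance uses Dunnett-style many-to-one comparisons of each
threshold group against the behavioural reference on the √ scale. The
repeated-measures structure (each animal contributes to every group) is
absorbed by within-animal centering before pooling; the pooled degrees of
freedom are reduced by the number of animals minus one. Family-wise adjusted
p-values come from a Monte-Carlo simulation of the joint max-|t| null
(correlated through the shared reference and pooled variance) with a fixed
internal seed, so results are deterministic; a Bonferroni fallback is
available. A Levene variance-homogeneity check across groups is reported as
a warning, never a halt.

Selection returns the *minimum* threshold that is strictly above ψ (the
whole grid when no breakpoint exists) and duration-concordant
(non-significant adjusted comparison) — minimal, to stay maximally sensitive
to shallow rewarming among reliable thresholds.

## Cohort statistics

Bout durations (arousals in hours, torpor in days, censored excluded) are
√-transformed and fitted by REML linear mixed models with treatment and
initial body mass as fixed effects and a per-animal random intercept
(statsmodels `MixedLM`). Repeatability is R = V_I/(V_I + V_Res) from the
random-intercept model on the transformed scale; variance components come
from REML by default, with the one-way ANOVA moment estimator (exact in
closed form, unbalanced-safe) available as `method="anova"`. The
significance of the individual effect is a likelihood-ratio test of ML fits
with and without the random intercept, referred to χ²₁ — the naive reference
for a boundary variance, which is conservative; this convention is kept
deliberately.

Counts use log-link Poisson GLMs (treatment + initial mass; Pearson
overdispersion reported); the proportion of arousals with drinking uses a
binomial GLM on the (with, without) composite; mass loss uses a gamma GLM
with log link (the positive-support, multiplicative-effects choice) on
initial mass, treatment, total drinks and total arousals. Treatment-only
variants reproduce the closed-form group-mean rate ratio and pooled-table
odds ratio exactly, which the tests assert. Cohen's d uses the pooled sample
s.d. with n−1 denominators and the 0.2/0.5/0.8 magnitude cut-points, no
small-sample correction. Welch's t uses the Welch–Satterthwaite d.f.

The HSI of a binary mask is exactly 100 × foreground/total pixels. The
between-treatment HSI contrast is a log-link quasi-Poisson GLM (Poisson mean
structure, Pearson-estimated dispersion), which is well-defined for
non-integer percentages.

## Synthetic cohorts

The generator emulates a two-incubator humidity experiment (humid = 98% RH,
dry = 50% RH, both 8 °C, 110 days, 10 + 9 females) and is the test bed for
every stage. Per animal, an alternating torpor/arousal renewal process draws
gamma durations with treatment means of 8.3/7.9 days (torpor) and
134/106 min (arousals); shapes 4.0 and 2.7 match the dispersion implied by
the reported spread of bout durations. A per-animal lognormal multiplier
(CV 0.25) creates consistent individual differences, making durations
repeatable. Durations are floored at 12 h (torpor) and 45 min (arousals) so
every event is resolvable at the 15-min cadence; the floor shifts the
realized arousal mean upward by a few minutes. Timelines always end in a
right-censored torpor bout (animals are removed while torpid), so every
truth arousal is complete. Note that the *observed* mean torpor duration
(≈7.5 days) sits below the generating mean because long bouts are
preferentially cut by the finite window — an edge-censoring effect shared
with the real design, not corrected for.

Traces put torpid samples at ambient + 1 °C with ±0.25 °C jitter; arousals
rewarm toward a 30 °C plateau by exponential approach at an initial
2 °C/min, hold with ±0.5 °C jitter, and decay back at an initial 1 °C/min
(rewarming faster than Newtonian cooling; the rates are config defaults, the
source experiment reports none). Samples land every 15 min and are quantized
to 0.5 °C. With these rates the 20 °C crossings bracket the true arousal
almost symmetrically, so on artifact-free traces the 20 °C detector recovers
arousal counts exactly and durations within two sample intervals — a tested
invariant.

Movement logs fragment each arousal into 1–3 movement intervals with
stillness gaps kept below the merge window, so the behavioural detector
reconstructs the true arousal exactly. Drinking occurs within an arousal
with treatment-dependent probability (0.45 humid, 0.75 dry) and 1 + Poisson
extra visits (0.35/0.2), reproducing the reported ≈1.5× dry excess in total
drinks. Initial masses are uniform on 22.4–29.5 g; mass loss is
3.0 g + 0.93 g/g of initial mass above the minimum, plus Gaussian noise —
heavier animals lose more, with no treatment effect.

Artifacts mirror what real datalogger studies report: *heating* events
(T_sk above 20 °C in a motionless animal, peak ≤ 23.2 °C), *sub-threshold
movements* (activity with T_sk peaking at 11.3–18.6 °C), *shallow thermal*
events (motionless excursions peaking at 12.5–18.0 °C — the events that
make arousal counts threshold-sensitive below ≈17.5 °C and give the
count-vs-threshold curve its breakpoint), logger shedding (validity
truncated from a uniform day; behavioural bouts persist) and outright logger
failure. Bumps are only placed ≥3 h clear of any movement; an artifact that
cannot be placed is recorded as skipped. Default rates (1.4/1.2/5.0 per
animal-study; shed 0.3, failure 0.1) are scaled from the reported artifact
tallies and count-sensitivity of the emulating study.

Huddle masks are 352×238 binary images whose foreground is an exact-count
elliptical region (the n smallest values of a random ellipse quadratic —
convex and 4-connected), with area fractions drawn about treatment means
2.14%/1.81% (s.d. 0.10/0.20, chosen to match the reported effect size, whose
printed standard errors are mutually inconsistent with it). Mask truth
therefore round-trips exactly through the HSI computation.

All randomness flows from one root seed through per-purpose/per-animal
`SeedSequence` substreams: identical configs are bit-reproducible, and
adding an animal never perturbs the others. Arousal cascades (group-
synchronized arousals) are available as an opt-in
(`cascade_strength > 0`): onsets snap to shared treatment-level template
times with Gaussian jitter; off by default since the emulated experiment
describes them only qualitatively.

## What the synthetic data does not capture

No thermodynamics (heat exchange, evaporative water loss), no humidity
dynamics, no video rendering, no within-huddle positions. Rewarming is a
clean monotone curve — real traces show overshoot, plateaus and cold
arousals. Passing tests therefore demonstrate correctness of the *rules and
estimators* under the stated generative assumptions, not robustness to
every pathology of field data.

## Numerical choices and sizes

- Breakpoint grid resolution 0.1 °C (matching the precision at which such
  breakpoints are conventionally reported); RSS tie-break takes the first
  minimizer; noiseless fits use a relative RSS tolerance of 1e−9.
- Dunnett Monte-Carlo: 20 000 replicates, internal seed fixed, two-sided.
- Degenerate inputs: all-invalid traces warn and return no bouts; constant
  mass loss returns a zero-slope table rather than a failed gamma fit;
  zero pooled variance makes Cohen's d an error and Welch's t an
  exact-equality shortcut.
- Test-suite problem sizes: detector-oracle comparison on 10 000 random
  traces; 200-replicate recovery simulations for the breakpoint,
  repeatability (50 animals × 10 observations) and GLMs (50 per group);
  50-seed end-to-end calibration runs on the default 19-animal cohort.
  These sizes give Monte-Carlo error comfortably inside the asserted
  tolerances while keeping the default suite around a minute.

## Known limitations

- The Dunnett adjustment simulates the exact many-to-one null for the
  *centered, pooled-variance* statistic; with strongly unbalanced per-animal
  counts the centering absorbs slightly too few/many degrees of freedom.
- The χ²₁ LRT reference at a variance boundary is conservative (kept by
  design, matching field convention).
- `MixedLM` can report a singular random-intercept fit on degenerate data;
  this is flagged in `extras["singular"]`, not raised.
- The breakpoint estimator assumes a single kink; multi-breakpoint count
  curves are out of scope.
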