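# Methods

This note documents the models, conventions and numerical choices behind
`saccsdt`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what a passing test does and does not establish.

## Task model

Thirteen display configurations: each of the three stimulus identities
(red target, G/R = 0; easy yellow distractor, G/R = 1; difficult orange
distractor, 0 < G/R < 1) alone in either hemifield (6), the three identical
pairs (3), and the target paired with either distractor on either side (4).
Stimuli sit at 20° eccentricity, at the horizontal meridian and ±20°
elevation, three positions per hemifield; response windows have 5° radius.
The G/R ratio is stored as an exact rational (`fractions.Fraction`) and
rounded to two decimals only for reporting. The whole array (fixation
included) can be shifted horizontally (`array_x_offset`) to model the
midline adjustment used to equalize baseline choice behavior; no further
calibration procedure is modeled. Luminances (11 / 35 cd/m²) are recorded
as metadata constants; there is no photometric model.

Condition ordering is canonical (singles, double-same, double-different;
target before easy before difficult; left before right) purely so that
condition indices are stable across runs — the task itself defines no
order.

## Synthetic sessions

The generator stands in for unreleased primate data, so its defaults *are*
the stated world of the analysis:

- **Choice policy.** Per condition, a probability vector over
  (select left, select right, stay). Anchored values: difficult singles
  realize hit rate 0.70 and false-alarm rate 0.40 (the worked-scenario
  control state); easy false alarms are near zero (0.02 singles / 0.01
  doubles). The remaining entries (double-target: 0.45/0.45/0.10;
  difficult double-distractor: 0.20/0.20/0.60; target-distractor pairs:
  0.75/0.15/0.10 difficult, 0.90/0.02/0.08 easy) were fixed once as
  plausible control performance for a well-trained animal — strong "go"
  tendency on double targets, intermediate difficult discrimination, near
  ceiling on easy — and are not tuned against any test outcome.
- **Trial structure.** Each condition appears exactly
  `n_trials_per_condition` times (default 75, ≈ 1000 trials/session over
  13 conditions, matching reported session totals) in a seeded
  pseudorandom order. Double-stimulus trials use same-row and diagonal
  position pairings in equal proportions (odd counts favor same-row);
  elevations are uniform. Timing: fixation hold uniform 0.5–0.9 s after a
  0.2 s acquisition margin, 500 ms response window, 500 ms target hold,
  2 s intertrial interval. Optional aborts (off by default) are uniform
  across conditions and re-queued at a random later position, so completed
  counts are unchanged.
- **Perturbation effects.** `criterion_shift` removes up to δ probability
  from contralesional selection, moving it to ipsilesional selection and
  staying in a 50/50 split (all to staying when the ipsilesional side is
  empty); shortfalls (e.g. easy distractors with only 0.02 to give — the
  floor effect) are clipped and logged. `sensitivity_change` mixes each
  condition's policy toward the policy of the condition with the
  contralesional stimulus's role swapped (target ↔ difficulty-matched
  distractor; target-only displays pair with the difficult distractor, the
  plausible confusion), emulating a perceptual deficit: a mixing weight λ
  changes the difficult-single hit rate by −0.3·λ and the false-alarm rate
  by +0.3·λ with almost no criterion change. Only the directions of both
  effects are externally specified; magnitudes are parameters (0.2 and 0.4
  are the canonical values exercised in tests, chosen as moderate effects
  of comparable size before any test was run).
- **Latencies.** Truncated normal in (100, 500] ms; control mean 180 ms
  both directions (SD 30), perturbation slows contralesional-ward saccades
  to mean 220 ms. The truncated normal is a pragmatic choice — reported
  data constrain only session means and their direction.
- **Gaze traces.** 220 Hz samples; saccades follow a raised-cosine speed
  profile (amplitude = peak velocity × duration / 2; defaults 800°/s and
  50 ms give exactly the 20° eccentricity), rescaled to land on the
  selected stimulus if the parameters disagree; optional white position
  noise. Real gaze data have drift, microsaccades, blinks and
  nystagmus — none are modeled, so detector tests on these traces
  establish correctness of the algorithm, not robustness to artifacts.

Seeding: one integer seed expands to per-stage and per-session
`numpy` generator streams (`default_rng([seed, stage])`; session k of arm a
uses `seed·1000 + a·500 + k`), so identical parameters give byte-identical
trial tables and adding sessions never perturbs existing ones.

## Saccade detection

Pipeline: linear interpolation of x and y from the nominal 220 Hz to
1 kHz; 12 ms rectangular moving average on each coordinate; speed =
√(vx² + vy²) from first differences of the smoothed coordinates; the speed
series smoothed again with the same window. A saccade candidate starts at
the first sample after the go signal exceeding 200°/s and ends when speed
falls below 50°/s; candidates shorter than 30 ms are discarded.

Conventions that the verbal description leaves open, fixed here:

- *Interpolation* is linear (no overshoot around thresholds).
- *Boxcar edges* shrink (window clipped at the trace ends, output length
  preserved) so no phantom velocity appears at boundaries.
- The even 12-sample window at 1 kHz is centered on
  `[i − 6, i + 5]`, i.e. half a sample early; speed is assigned to the
  left sample of each first difference. Thresholds apply to the doubly
  smoothed series.
- *Onset refinement.* The 200°/s crossing occurs ~8–11 ms into the
  movement (for raised-cosine profiles with peak velocities 300–800°/s),
  so reporting the crossing itself would systematically inflate latencies.
  "The first eye position change that exceeded the threshold" is read as
  the start of the suprathreshold movement: the onset is back-tracked to
  the rising edge at the 50°/s offset threshold and refined by linear
  extrapolation of the rising edge to zero speed (t₀ = t − v/v′, clamped
  at the go signal). On noiseless synthetic saccades this recovers onsets
  within ±5.5 ms for amplitudes ≥ 5° and peak velocities ≥ 300°/s
  (verified across the amplitude/duration grid); the residual error is a
  property of the smoothing, not of sampling phase.

## Outcome classification

One label per occupied hemifield, pooled over the three positions: target
→ hit iff selected, else miss; distractor → false alarm iff selected, else
correct rejection; empty → not applicable. The rule is uniform across
stimulus types, so a double-different trial where the ipsilesional
distractor is chosen scores a contralesional miss *and* an ipsilesional
false alarm, staying on a double-distractor display scores two correct
rejections, and choosing one of two targets scores a hit and a miss. This
uniform rule is an interpretive choice — it is the one that makes staying
and going equally frequent correspond exactly to the pooled criterion
0.6745 on double-different displays (the go/stay boundary printed as
0.67). If the original analysis excluded double-target stay trials instead
of scoring two misses, double-same hit rates would shift; this variant is
not implemented.

Analysis cells contrast each distractor difficulty with the *same* target
trials, so target-only displays (single target, double target) contribute
their hit/miss counts to both the easy and the difficult cell
(`sdt_cells`). Accuracy is trial-level — a trial is correct iff rewarded,
counted once per trial even for double displays — per stimulus type and
difficulty with hemifields pooled.

## SDT metrics

d′ = z(H) − z(F) and c = −0.5(z(H) + z(F)). The printed formula in the
source description has the d′ sign flipped relative to its own worked
example (H = 0.5, F = 0.2 must give +0.84); the standard convention is
implemented and pinned by a regression test. Quantiles come from
`scipy.stats.norm.ppf` (checked against a bisection-on-erf oracle to
1e−10). Extreme rates (exactly 0 or 1) get the log-linear correction — 0.5
added to both cells of the affected pair only — and the event is flagged;
the correction scheme of the original analysis is unknown, so the flag
travels with every output row. Reported values round half-away-from-zero
to two decimals. The go/stay bias is the criterion of hemifield-pooled
counts; its neutral boundary is 0.6745 (= −z(0.25), printed 0.67) for
double-different displays and 0 for singles and double-same.

## Hypothesis scenarios

A scenario fixes before-proportions for hits and false alarms (100 target
+ 100 distractor trials by default), applies signed deltas, and converts
to counts (largest-remainder rounding conserves totals; clipping into
[0, 1] warns). Default effect magnitude 0.2. Templates: response bias =
equal −δ on contralesional hit and false-alarm proportions, with the FA
delta zeroed when the before-FA is below the 0.05 floor (producing the
predicted spurious d′ drop for easy discrimination); perceptual deficit =
−δ hit, +δ FA. Ipsilesional companions exist for double displays: under
bias, the contralesional loss reappears as ipsilesional hit/FA gains
(floor-limited); under deficit, single and double-same ipsi cells are
unaffected while double-different couples across hemifields (fewer ipsi
targets selected, more ipsi distractors). The floor threshold (0.05) and
all deltas are parameters — only the directions are externally fixed.

## Inference

- **Pooled t-test** (not Welch): 7 + 7 sessions must give df = 12. Zero
  pooled variance is resolved explicitly (t = 0/p = 1 for equal means,
  ±∞/p = 0 flagged otherwise).
- **Rank-sum**: exact null distribution when the pooled sample is tie-free
  and n ≤ 20, else normal approximation with tie correction and no
  continuity correction (identical samples then give p = 1 exactly).
- **Two-way mixed (split-plot) ANOVA**, within = hemifield, between =
  perturbation: implemented directly from the balanced-design decomposition
  (between stratum: group SS tested against subjects-within-groups; within
  stratum: factor and interaction against the subject × factor residual)
  because the full strata table with exact SS partition is part of the
  output contract; `pingouin` reproduces the F ratios and serves as the
  independent cross-check in tests. Unbalanced designs are rejected.
- **One-way RM ANOVA** across stimulus types with Bonferroni-corrected
  paired-t post-hocs (m = 3).
- **Psychometric fit**: accuracy(x) = lower + (upper − lower)·Φ((x − μ)/σ)
  over the distractor G/R ratio, maximum likelihood on binomial counts
  (Nelder-Mead on (μ, log σ), two starts). Accuracy *increases* with the
  ratio — it is lowest when the distractor approaches the target color —
  the orientation is configurable. Asymptote defaults 0.5 (the go/stay
  pre-test is effectively a two-choice discrimination) and 1.0; the
  original fitting configuration is unknown, so both are parameters.
  `invert(a)` returns the ratio achieving accuracy a in closed form, used
  to pick a distractor in the 70–80 % band.
- Higher-order (3-/4-way) omnibus mixed ANOVAs are intentionally out of
  scope; each omnibus effect of interest maps onto the implemented
  two-way ANOVA (perturbation, hemifield, interaction per stimulus type ×
  difficulty) and the per-cell t-tests that the headline inferences rest
  on.

## What the tests establish

Green tests establish: the analytic anchors (worked scenario, go/stay
boundary, color ratios, combinatorics); detector recovery on clean
synthetic kinematics; that the *generative* criterion-shift and
sensitivity-change effects are recovered as criterion and d′ changes
respectively through the complete pipeline (100 seeded session-pair
replicates at 100 trials/condition: mean off-target change within ±0.1,
on-target sign in ≥ 95 %); oracle equivalence of tallies, ANOVA strata and
exact rank-sum; and nominal type-I calibration of the pooled t-test at
n = 7 + 7. They do not establish robustness to real-data pathologies
(artifacts, drift, aborted-trial structure, unequal session sizes), and
they cannot reproduce the original animal statistics, which require the
unreleased raw data.
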