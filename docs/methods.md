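# Methods

## The model

`steerstress` treats one steering turn as the step response of an
underdamped second-order mass–spring–damper (MSD) system. The mass *m*
aggregates arm, hand and wheel inertia; the spring *k* is the stiffness
contributed by muscle tension in the arm and shoulder; the damper *c* is
the total friction. A force step of amplitude *A* produces

    x(t) = A [1 − e^(−ζ ω_n t) (cos ω_d t + ζ/√(1−ζ²) · sin ω_d t)],

with natural frequency ω_n = √(k/m), damping ratio ζ = c / (2√(km)) and
damped natural frequency ω_d = ω_n √(1−ζ²). Because psychological stress
raises muscle tension, and at constant mass ω_d grows with √k, the damped
natural frequency inferred from steering movements serves as a stress
surrogate: within a subject, the condition with the larger ω is called the
stress condition.

Only the output movement is observed, so the system is identified by
inverse filtering: an order-4 linear predictive coding (LPC) model is
fitted to each turn segment by the autocorrelation method
(Levinson–Durbin recursion on the biased autocorrelation sequence), and
the complex roots *r* of the prediction-error polynomial
z⁴ − a₁z³ − a₂z² − a₃z − a₄ characterize the resonance:

    ω = |ℑ(r)|,      ζ = |ℜ(r)| / |r|,

evaluated at the dominant complex root (largest modulus among roots with
positive imaginary part; exact modulus ties break toward the smaller
|ℑ(r)|). The fit quality metric is the variance of the one-step prediction
residual on the min–max-normalized segment.

### Conventions worth knowing

- **ω is a per-sample surrogate, not rad/s.** The formulas above are
  applied to the z-plane roots directly, so ω is dimensionless and is a
  *biased but strictly monotone* image of the physical ω_d (verified on
  noiseless simulations: Spearman 1.0, R² > 0.99 against √k over the
  simulator's stiffness regime k ∈ [45, 90]). The method only ever
  compares ω within a subject, which any monotone surrogate preserves.
  An s-plane mapping (`root_mapping="log"`, ω = |ℑ(log r)|) is available;
  in our simulations it degrades within-subject contrast substantially
  (the root angle barely moves with k while its modulus does), so the
  literal convention is the default.
- **Min–max normalization before fitting.** Each segment is scaled to
  [0, 1]. This makes a single residual-variance threshold meaningful
  across turns of different size and makes ω and ζ exactly invariant to
  affine rescaling of the input (measured drift < 1e-13 on simulated
  segments).
- **No windowing or pre-emphasis** is applied; the segments are short
  deterministic transients, not speech frames.

## Segmentation

The signed, clockwise-positive angle is cleaned (duplicate timestamps
dropped, first occurrence kept), folded to absolute value, and cut into
maximal non-decreasing runs from valley to peak. Plateaus extend a run; a
trailing plateau at the top is cut at its first sample. Runs whose
amplitude (peak − valley) falls below the lower bound (default 40°, the
threshold below which the large arm/shoulder muscle groups are not
engaged) are discarded. Retained runs are truncated at the first sample
whose excursion above the valley exceeds the upper bound (default 150°,
where drivers re-grip the wheel and inject a second impulse that breaks
the single-step-response assumption). Both bounds compare the *excursion
since turn start*, not the absolute wheel angle, because the arm movement
size is what matters and the pre-turn wheel position is arbitrary; both
are configurable. Boundary runs (drive starting or ending mid-maneuver)
are kept.

The "initial turns" rapid scope is a time window (default 110 s of the
drive) rather than a count of eight turns, because the number of turns
completed in a fixed early interval varies between drives.

## Quality filter

Residual variances are pooled per condition × scope group
(CALM/STRESS × ENTIRE/INITIAL8); each group gets a Tukey upper fence
Q3 + 1.5·IQR (quartiles by linear interpolation, the numpy default —
other hinge conventions shift the fence and are selectable); the overall
fitting threshold is the minimum of the four fences. Values exactly at
the threshold are kept. Only the upper fence is applied: a low residual
variance is a good fit, never an anomaly.

## Individualized classifier

The empirical 150° bound needs video coding, so the automated method
sweeps the upper bound from lower + 10° in 10° steps until the largest
observed turn amplitude is covered, running segmentation → LPC → quality
filter at every bound. Per-segment fits are cached per distinct
truncation point, since bounds beyond a segment's amplitude all see the
same series. The decision then:

1. takes the bound with the maximum segment count averaged over the two
   conditions (ties toward the smaller bound) — small-amplitude segments
   are progressively removed by the fitting threshold at high bounds, so
   the count curve rises and then falls;
2. selects the first quartile of the remaining bound range above that
   peak (the reference set for "first quartile" is a convention, exposed
   in config);
3. pools one ω per (segment, bound) pair inside that interval per
   condition and labels as STRESS the condition with the larger median ω.
   Pooling across a bound interval rather than one bound trades a little
   sensitivity against the Type II risk of an unlucky single bound.

Median ties are reported as undecided by default (never silently
guessed); a `tie_policy` flag can prefer a label when sensitivity matters
more than specificity. The per-sweep fitting threshold is recomputed from
the data being classified (minimum of the per-condition fences at each
sweep point); a fixed cohort-level threshold can be supplied instead.

## Cohort statistics

Self-report (0–10 scales), heart rate and RMSSD are min–max normalized
per participant across phases and baseline-corrected (corrected baseline
is exactly 0; all values in [−1, 1]). Condition contrasts use a
within-subject permutation t-test: the observed paired t statistic is
compared against the null generated by independently sign-flipping each
participant's paired difference (the exchangeable null for a
within-subject design; a full across-participant shuffle is available
behind a flag). P is the proportion of permuted statistics at least as
extreme as observed — with `alternative="directional"` in the direction
of the observed effect, or with a fixed a-priori direction
(`"greater"`/`"less"`), which is the calibrated choice when a rejection
rate at level α matters: the post-hoc directional reading doubles the
null rejection rate by construction. Constant differences make the test
degenerate (t = 0, P = 1). Bonferroni correction multiplies by the number
of planned comparisons (4 in the stimulus-validation set). Cohen's d uses
the pooled (n−1) standard deviation of the two condition groups. RMSSD is
√(mean of squared successive RR differences).

Defaults: 100,000 permutations for analysis runs; the calibration
experiments in the test-suite use 2,000–10,000 to stay fast, which leaves
Monte-Carlo noise on P of at most ~0.011 SD.

## The simulator

`synthetic_driving` exists because no real drives ship with the package:
it generates traces whose ground truth is known exactly, so every stage
can be tested for *recovery* rather than plausibility.

A drive is a schedule of non-overlapping turns (default 10 per drive,
onsets 6 s apart): each turn rises toward its signed amplitude as an MSD
step response for half its duration and returns to center over the other
half. Gaussian angle noise is added, then the signal is quantized to the
0.1° sensor grid and clipped to ±450°, at 100 Hz.

Default magnitudes, chosen once and documented here:

| parameter | default | why |
|---|---|---|
| mass m | 1 (arb.) | only ratios matter |
| calm stiffness k | log-normal, median 64, log-SD 0.15 | ω_n ≈ 8 rad/s, ~15 % between-subject spread — a plausible arm-stiffness regime; nothing in the source study pins real values |
| damping ratio ζ | uniform 0.20–0.35 | underdamped enough to ring, as the model requires; damper c is derived from the calm draw and shared across conditions (friction does not change with stress) |
| turn amplitudes | normal(120°, 50°) clipped to [45°, 250°] | exercises both the 40° filter and upper-bound truncation, echoing a closed course of varying-radius turns |
| angle noise | 0.15° SD | a production steering encoder is clean at its 0.1° LSB; a little road vibration bleeds through. This value places the pipeline in the operating regime the method is designed for (cohort effect ≈ 0.7 alongside ~0.8 individual accuracy); at 0.3° the individual accuracy floor drops to ~0.73 |
| stress stiffness multiplier | 1.15 | calibrated so the cohort-level Cohen's d on *recovered* ω is ≈ 0.7. The literal z-plane ω compresses the planted shift (a 7 % ω_d shift maps to ~1.5 % recovered-ω shift), which is why the multiplier is larger than naive √k arithmetic suggests |

Ancillary tables (self-report, HR, RMSSD per phase) are drawn from fixed
per-phase generative means with stress phases shifted in the expected
directions.

### What the simulator does not emulate

Real CAN steering data carry road curvature, lane-keeping
micro-corrections, speed-dependent steering forces, power-steering
torque, colored road/tire noise (a noise-filter hook exists but no
colored model ships), and drivers whose grip and posture change
mid-drive. Simulated turns also ring more than human steering does
(ζ ≤ 0.35 gives visible overshoot oscillation, which can add small extra
segments per turn). Passing tests therefore demonstrate that the
*inference chain is correct and calibrated on its own model class* — not
that the stress effect is detectable in any particular real vehicle.

## Problem sizes used by the validation suite

The test-suite's end-to-end detection check runs 50 planted cohorts and
30 null cohorts of 22 participants × 2 drives × 10 turns (~2 min); the
permutation calibration uses 1,000 replicate null cohorts at 4,000
permutations. The reproduction script (`scripts/acceptance.py`) uses 10
planted + 10 null cohorts and 400 calibration replicates, and one
30-turn-per-drive cohort for the fitting-threshold/outlier-fraction
analysis, completing in well under a minute.

## Known limitations

- ω and ζ have no physical units under the literal root convention; only
  within-subject contrasts are meaningful.
- The autocorrelation-method LPC fit on a short monotone rise is biased;
  the dominant complex root is a window artifact whose position is a
  monotone image of the true pole, not the pole itself. Cross-subject
  comparisons of absolute ω values should not be interpreted.
- The per-sweep Tukey threshold needs ≥ 4 fits per condition at a sweep
  point; below that it falls back to a pooled fence or no filtering.
- With fewer than ~6 turns per drive the count-peak and quartile-interval
  selection become unstable; the undecided outcome is reported rather
  than guessed.
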