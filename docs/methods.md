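# Methods

`pupilpath` analyzes pupil diameter recorded by a 60 Hz remote eye
tracker while readers interpret zoomable whole-slide images. Two
complementary signals are extracted per trial (one participant reading
one case): the **tonic** profile — slowly varying diameter over the
whole interpretation, indexing sustained effort — and the **phasic**
response — the transient deflection within 5 s of the first fixation
inside a diagnostic region of interest (dROI).

## Preprocessing

**Null samples.** A sample is null when its validity flag is false or
its diameter is ≤ 0; both encodings collapse to one internal null
state. Blinks appear as null runs. Interior runs are repaired by linear
interpolation in sample-index space between the nearest valid
neighbours; leading/trailing runs take the nearest valid value
(nearest-value fill avoids extrapolating a trend into unobserved time).
Gaze position is repaired the same way so fixation detection can bridge
blinks. Interpolation never changes a valid sample, and filled values
are bounded by their bracketing neighbours. Recordings are validated to
be strictly increasing in time with inter-sample intervals within ±20%
of the nominal period; after validation, all windowing is defined on
sample indices, not wall time.

**Luminance adjustment.** Pupil diameter also tracks screen brightness.
The adjustment multiplies each diameter by the mean grayscale intensity
(normalized to (0, 1]) of the screen frame on display at that sample —
i.e. division by the reciprocal of intensity — so dilation attributable
to a darkening display is discounted. Frame lookup is a step function
(latest frame at or before t), matching video-capture semantics. The
opposite convention (division by intensity) is selectable via
`mode="divide"` for sensitivity analyses; the default is documented
here because the verbal description of such adjustments is ambiguous in
much of the applied literature. Because a constant intensity rescales
every diameter by the same factor and F statistics are scale-invariant,
the adjustment cannot manufacture an effect from a constant-brightness
display.

## Fixation detection and ROI hit-testing

Gaze is classified with the dispersion-threshold algorithm (I-DT): a
maximal run of samples whose dispersion `(max x − min x) + (max y −
min y)` stays within a threshold, lasting at least a minimum duration,
is a fixation with centroid at the mean position. Defaults: 41 px
dispersion (≈1° of visual angle on a 22″ 1920×1080 display at 60 cm)
and 100 ms minimum duration; both are configuration keys since
conventional choices vary. The minimum duration is converted to a
window of `round(min_ms / period) + 1` samples so the spanned time
`(n − 1) × period` reaches the minimum. Output is invariant to uniform
translation of all positions; fixations are ordered and non-overlapping.
A fixation composed of more than 50% interpolated samples is flagged
but retained.

The slide viewer's viewport maps screen to slide coordinates as
`slide = origin + screen / zoom` (screen origin top-left, y down; slide
coordinates in base-resolution pixels at 1×; zoom 1–60). Viewport
states are piecewise constant, right-open in time. A fixation's ROI
membership is evaluated by mapping its centroid through the viewport
state at fixation *onset* (a fixation spanning a pan/zoom change is
anchored at onset — an interpretation choice, since a reasonable
alternative would require full overlap); a point on the polygon
boundary counts as inside. The first fixation landing in any dROI
defines the trial's phasic event; trials that never fixate a dROI are
excluded from the phasic analysis.

## Tonic profiles

Interpretation times vary across trials, so each trial's full
(interpolated, optionally luminance-adjusted) diameter trace is
time-normalized to a fixed 500 samples by band-limited trigonometric
interpolation — forward DFT, symmetric spectrum padding/truncation with
Nyquist-coefficient splitting, inverse DFT scaled by `n_out/n_in` (the
classic MATLAB `interpft` behaviour; verified in tests against
`scipy.signal.resample` to 1e-9). This resampling preserves the signal
mean exactly for any length pair. The choice of 500 follows from the
10 time increments of 50 samples each used downstream; the overlapping
verbal bin boundaries ("1–50, 50–100, …") are resolved as half-open
blocks of exactly 50.

Tonic analysis uses raw (not baseline-referenced) diameters; the
first-second baseline (mean of the first 60 samples) is computed and
reported but not subtracted. Six-point difficulty ratings are collapsed
to four conditions — A: 1–2, B: 3, C: 4, D: 5–6 — to even out sparse
scale endpoints. Ratings are the *same participant's* per-trial
ratings, not case-level means. Trials are averaged into a participant ×
condition × bin grid; a participant with no trial of some condition has
those cells filled with the mean of all other participants for that
condition × bin (condition-mean imputation, which leaves each column's
observed grand mean unchanged; imputed cells stay flagged). The grid
enters a 4 × 10 repeated-measures ANOVA.

## Phasic responses

Around each trial's event sample `e`, the window covers samples
`[e − 6, e)` (100 ms) and `[e, e + 300)` (5 s) — 306 samples. The six
pre-event samples are averaged into a baseline and all 300 post-event
samples referenced to it by subtraction (not ratio), giving relative
diameter in camera pixels; referencing is exactly invertible. Events
closer than 6 samples to the start or 300 to the end of a recording are
skipped and logged (the 5 s window is long enough to capture both the
response and its return toward baseline). Windows whose
*pre-interpolation* null fraction over all 306 positions strictly
exceeds 50% are dropped — exactly 50% is kept.

Surviving trials are classified 2 × 2: agreement of the participant's
diagnosis with the consensus reference, crossed with a median split of
rated difficulty. The median is pooled over the analyzed trials'
ratings (per-participant splits would leave near-empty cells at this
scale); ties at the median go to "low" by default (configurable). The
relative trace is reduced to 10 bins of 30 samples (500 ms) each, and
the participant × trial-type × bin grid (condition-mean imputed as
above) enters a 4 × 10 repeated-measures ANOVA.

## ANOVA implementation

The two-way within-subjects ANOVA uses the univariate sums-of-squares
partition: each effect is tested against its own effect × subject
interaction. For n subjects and 4 × 10 factors the df are (3, 3(n−1)),
(9, 9(n−1)) and (27, 27(n−1)) — (3, 60), (9, 180), (27, 540) at n = 21.
No sphericity correction is applied by default (matching the integer df
convention of the source analyses); Greenhouse–Geisser epsilon and
corrected p values are available by flag, with epsilon computed from
the double-centered covariance of the effect's subject-level score
matrix. Degenerate all-constant grids return F = 0 with a
zero-variance flag instead of raising. The SS decomposition sums
exactly to total SS, and F is invariant to affine rescaling of the
data.

Diagnostic agreement rates (participant × category) enter a mixed
ANOVA with diagnostic category within and expertise (resident/faculty)
between: the between effect is tested against subjects-within-groups
(df 1, n − 2), the within effect and interaction against the within ×
subjects-within-groups error. Note that with two groups and 21
subjects the standard partition yields within-effect error df
3 × (21 − 2) = 57, not 60; the implementation reports its own partition
rather than forcing any particular accounting. Pairwise follow-ups are
two-sided paired t-tests with unadjusted p values (Holm correction is
deliberately not applied by default, for comparability; pairs with
zero-variance differences are flagged rather than tested). Both ANOVAs
are verified against independent oracles in the test suite: explicit
textbook loop-summation formulas and `pingouin`.

## Synthetic studies

No public recordings of this task exist, so the generator produces
complete studies — gaze logs, viewport logs, ROI polygons, metadata,
luminance traces — in exactly the formats the readers consume, plus a
truth record of every planted quantity. Defaults mirror the recorded
study's conditions: 21 participants (6 faculty, 15 residents, two
12-case subsets with categories in 1:2:2:1 proportion), 30–90 s trials
at 60 Hz, mean baseline diameter 13.3 px (SD 0.3 across participants),
a 0.2 px tonic step per difficulty condition (the observed ordering
spans ≈0.6 px), a ±0.5 px phasic amplitude, and an 81% dROI-visit
probability.

Per trial: ratings are drawn from low/high-difficulty case
distributions whose pooled median is 3, so the 6→4 collapse and the
median split are exercised with realistic imbalance; agreement is
Bernoulli with probability 0.75 (easy cases) or 0.45 (difficult).
Diameter = participant baseline + tonic step × condition + AR(1) drift
(φ = 0.95, innovation SD 0.05 px — slow wander resembling real pupil
series) + luminance-coupled term + an event-locked kernel. The kernel
is a raised-sine rise to peak at 2 s with 3 s exponential decay,
amplitude +A for difficult-agree trials, −A for difficult-disagree, 0
for easy trials — planting the signed interaction pattern the phasic
analysis should recover. Scanpaths are fixation clusters (1 px
Gaussian jitter) separated by 2–5-sample saccades, with consecutive
centres ≥150 px apart so the fixation structure is unambiguous at the
default dispersion threshold; the saccade sweep stops at 60% of the
inter-centre distance so detected onsets are sample-exact. The
viewport shows non-diagnostic slide regions until the scripted event,
then jumps to a state centred on the ROI, guaranteeing that the
scripted fixation — and no earlier one — maps inside the ROI polygon.
Blinks are Poisson-placed null runs (10/min, 100–400 ms); a margin
around the scripted event is kept blink-free so the event sample stays
exactly recoverable. Generation is deterministic given the seed, with
counter-keyed per-trial substreams.

**What the generator does not emulate:** head movement and
pupil-foreshortening artefacts, smooth pursuit, microsaccades,
measurement noise in gaze position beyond cluster jitter, overlapping
phasic responses from successive ROI visits, and any dependence of
scanpath structure on case content. Passing recovery tests therefore
demonstrate that the pipeline's arithmetic and inference are correct
under the planted model, not that the effects exist in new recordings.

## Problem sizes and numerical choices

Recovery and calibration checks use replicate studies at the default
size (252 trials each): 100 replicates for planted-effect recovery and
200 for the null-calibration (type-I error) check, sizes chosen to
keep the full suite to a few minutes while leaving binomial
uncertainty well inside the asserted bands. Internal comparisons use
absolute tolerances of 1e-9 (linear-algebra identities) and 1e-6
(trigonometric interpolation of a band-limited sinusoid). Degenerate
inputs — empty recordings, all-null trials, zero-variance grids,
out-of-range ratings or zooms — raise typed errors or set flags as
documented above, and every exclusion is recorded per trial in the run
manifest with a reason code.

## Known limitations

* The luminance adjustment's direction is an interpretation; both
  readings are implemented, one is default.
* Condition-mean imputation slightly understates between-participant
  variance in conditions with missing cells; the imputed fraction is
  small at the default study size and imputed cells are flagged.
* The mixed-ANOVA partition assumes at least two subjects per group
  and reports count-weighted (sequential) sums of squares for
  unbalanced groups.
* Camera-pixel diameters are not calibrated to millimetres; all
  effects are expressed in the tracker's native unit.
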