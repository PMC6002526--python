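# Methods

## The task and its measurement model

A participant answers 76 yes/no questions by clicking YES/NO boxes in
the upper screen corners, starting each trial from a START button at the
bottom center. Questions belong to nine categories crossing content
(experimental-condition controls EX; typical depressive symptoms DS;
very atypical symptoms VAS) with structure (simple single-proposition
items vs complex conjunctions, concordant or discordant). A complex item
is keyed "yes" iff both component propositions are true; discordant
conjunctions (one true, one false component) are keyed "no". This makes
the keyed answer a pure function of (category, clinical state), which is
how `protocol` derives the answer keys rather than hard-coding response
tallies. The SIMS-AF screen flags a respondent who endorses more than
five of the 15 VAS items.

Each trial's mouse path is mapped into the standard tracker space (start
at the origin, box centers at (−1, 1.5) and (1, 1.5)), mirrored so every
trial moves leftward, and linearly resampled to 101 frames spanning
movement onset → click. From the standardized path the classic curvature
and hesitation metrics are computed; a participant is summarized by an
83-feature vector (7 metrics × 9 categories + 7 overall + 4 overall
velocity/acceleration means + 6 endorsement counts + 3 control-error
counts). Group comparisons use one-way ANOVA with omega-squared and
Tukey HSD; feature selection uses Hall's CFS merit with forward greedy
search; classification uses a native Gaussian naive Bayes, a native
depth-2 Gini tree, the fixed two-rule tree, and standard linear-SVM /
logistic / random-forest classifiers behind adapters, evaluated by
stratified 10-fold cross-validation (cohort of 60 → folds of 6) and a
held-out cohort of 27.

## Conventions and numerical choices

* **Movement onset (IT).** Onset is the timestamp of the last sample at
  (or within ε of) the start position before the first threshold
  crossing — i.e. when the movement began, not when it was first
  observed. With the default ε = 0 px this is the last static sample;
  the alternative reading (first displaced sample) would bias IT upward
  by one sampling interval.
* **Signed MD and AUC.** Both are signed, positive toward the non-chosen
  response side; group means are therefore net-attraction measures. MD
  is the signed perpendicular distance of the farthest frame from the
  straight line through frames 0 and 100; AUC is the shoelace area of
  the closed polygon path + reversed ideal segment (equivalently
  ∫ deviation d(chord projection), trapezoidal).
* **MD-time clock.** MD-time is reported on the question-onset clock
  (includes IT), consistent with RT; across groups MD-time ≈ 0.5–0.6 × RT
  under this convention. A movement-onset clock would subtract IT.
* **Velocity/acceleration.** v = X_n − X_{n−1} and a = v_n − v_{n−1} are
  reported as signed means (an absolute-mean variant sits behind a
  switch). Because the mean per-frame velocity telescopes to
  (endpoint − start)/100, v_x and v_y are functions of the click point
  in standardized space; under the mirrored convention v_x is negative
  for every leftward-standardized trial.
* **Flips.** Direction reversals are sign changes of successive nonzero
  per-frame increments; zero increments are skipped.
* **ANOVA/Tukey.** F and ω² come from explicit sums of squares
  (ω² = (SS_b − df_b·MS_w)/(SS_tot + MS_w), clamped at 0, flagged);
  Tukey-adjusted p-values use the studentized range distribution with
  Tukey-Kramer standard errors, and both the q statistic and a t-style
  statistic (difference / SE with pooled MS_w) are reported, since
  published post hoc tables print t-style values.
* **CFS class correlation.** For a binary class the signed point-biserial
  correlation; for three classes the mean absolute point-biserial over
  one-vs-rest binarizations. A symmetric-uncertainty variant (equal-width
  discretization, 10 bins) is available behind a switch. Greedy ties
  break by column order, making selection deterministic.
* **Decision-tree thresholds.** "Fewer than 3.5" and "more than 4048 ms"
  are strict; a value exactly at a threshold falls to the other branch
  (symptom counts are integers, so only the time threshold can be hit).
* **Cross-validation.** Folds are stratified by class by default (every
  fold of 60 holds 2 per class); unstratified partitioning is a switch.
  Overall accuracy is trace(confusion)/N, which equals the fold-mean for
  equal fold sizes.

## The synthetic-data generator

No human recordings are deposited, so cohorts are synthetic and the
generator is a first-class, tested component. Its contract is
statistical: for each group, the *extracted* feature means must equal
the configured targets, which are the published group statistics.

**Endorsements.** Each symptom-bearing item is endorsed independently
with a per-category probability p = target mean / item count. Published
tables give only pairwise group differences, so truth-teller means are
anchored (DS = 1.0, 2DS-c = 1.5, VAS = 0.5, 2DS-d = 6.0, DS&EX-c = 0.5,
DS&EX-d = 0.5) and the liar/depressed means derived from the printed
differences (liar DS = 8.75, 2DS-c = 13.35, VAS = 7.30; depressed
DS = 6.30, 2DS-c = 8.35, VAS = 4.45). These anchors respect every
printed difference, keep truth-tellers below and the other groups above
the 3.5 decision-tree threshold on 2DS-c, and stay within item counts.
The 2DS-d direction (truth-tellers *higher*) reproduces the printed sign
pattern even though it is counter-intuitive under conjunction semantics;
the anchor is a configurable calibration direction. Controls are
answered by key with a per-group error probability (0.13 / 0.04 / 0.09
for truth-teller / depressed / liar, anchored to the one printed error
contrast).

**Trajectories.** A trial is constructed directly in the standardized
101-frame space, in chord coordinates (t = progress along the straight
start→click line, d = signed perpendicular deviation):

1. IT and RT are lognormal with the configured mean/SD (moments matched
   exactly); RT is redrawn if below IT + 200 ms. The path idles at the
   start until IT.
2. The deviation profile rises to a drawn amplitude A ~ N(md_mean,
   md_sd) at the drawn peak frame (fraction of movement time ~
   N(frac, 0.05), where frac is derived so that IT + frac × (RT − IT)
   equals the published MD-time mean), with a narrow dome making the
   maximum unique.
3. The progress profile is a *double swing* — approach sweep to the
   click, partial return near the chord, second sweep back — and the
   return length B is solved in closed form (the shoelace area is linear
   in B) so the area equals the drawn AUC target A·r,
   r ~ N(auc_mean/md_mean, 0.15). This shape exists because the published
   AUC/MD ratios (≈ 2.1–2.3) exceed what any single-bump path can
   produce in this space (area ≤ MD × chord length ≈ 1.6 × MD): sustained
   deviation with a partial backtrack is the geometrically smallest
   realization. B is capped at 0.88 × chord, so extreme area draws fall
   slightly short; the resulting mean shortfall is well inside the
   recovery tolerance.
4. Direction reversals are topped up to per-axis targets drawn around
   the published flip means by inserting small isolated
   counter-movements (amplitude 0.004–0.012 normalized units) away from
   the deviation peak; each adds exactly two reversals, an odd residual
   is added with probability 1/2.
5. The click point is drawn per group inside the response box; its
   height calibrates v_y (mean standardized click height 1.326 / 1.315 /
   1.326 → v_y 0.01326 / 0.01315 / 0.01326).
6. The 101 frames are emitted as a raw pixel log at ~70 Hz whose sample
   times include the frame breakpoints, so linear re-interpolation by
   the extraction stage reproduces the frames exactly; sample times are
   quantized to 0.01 ms and coordinates to 0.1 px (below any metric's
   resolution) so serialized logs survive any float parser.

**What the generator does and does not emulate.** It reproduces the
first moments (and roughly the dispersions) of RT, IT, MD-time, MD, AUC,
flip counts, v_y and all endorsement counts per group, and hence the
group separations every downstream stage depends on. It does not emulate
submovement structure, velocity profiles within a trial,
learning/fatigue across trials, item-level difficulty, response-side
biases, the published v_x magnitudes (not reconstructible under the
signed mirrored convention, where mean velocity telescopes to the
endpoint coordinate), correlations between features beyond those induced
by the shared draws, or any questionnaire text. Passing tests therefore
demonstrate that the pipeline recovers configured group structure from
raw logs — not that real malingerers are classifiable at any particular
accuracy; the published human-data accuracies are deliberately not
reproduction targets.

## Problem sizes

Defaults mirror the study design: training cohort 20 + 20 + 20,
held-out cohort 9 + 9 + 9, 76 trials per participant, 10-fold
stratified CV. Parameter-recovery checks use 500 trials per group
(kinematics, ≈ 3-SE resolution of a few percent of each target) and 60
participants per group (endorsement counts); chance-level checks use
100 label permutations at k = 5.

## Limitations

* Endorsement anchors (and therefore absolute counts) are a modeling
  choice; only between-group differences are evidence-based.
* The truth-teller/liar RT difference in the published means is ~12 ms —
  far below any realistic cohort's resolution — so ordering checks
  involving that pair are asserted on configured parameters, not on
  extracted sample means.
* The two-class feature subset includes control-question timing features
  whose group contrasts are weakly constrained by the published tables;
  their synthetic analogues carry whatever separation the RT/MD-time
  calibration induces.
* The LMT (logistic model tree) classifier is represented by a
  standardized logistic-regression stand-in; SMO by a linear SVM. Both
  are pluggable, not re-implementations.
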