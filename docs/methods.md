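# Methods

## Task model

The delayed-recognition alphabetization task presents an array of 3–9
distinct consonants for 3 s, a 5 s delay during which the array is
mentally alphabetized, and a 4 s letter–position probe, followed by a
jittered inter-trial interval with a 5 s mean. A run holds 30 trials in
254 volumes at TR = 2 s; a session holds 4 runs. Maintenance demand is
the array length (Set Size); manipulation demand is the minimum number
of reordering moves needed to alphabetize the array (Sorting Steps).

### Sorting-step counting rules

No published convention defines what one "step" is inside each sorting
algorithm, so the package fixes explicit rules and verifies them against
independent oracles:

* *insertion*: one step per letter that is not a left-to-right running
  maximum (it must be extracted and reinserted into the sorted prefix);
  equals `n − #maxima`.
* *selection*: one step per executed swap; equals `n − #cycles` of the
  sorting permutation, which is also the graph-theoretic minimum number
  of transpositions (verified exhaustively against breadth-first search
  for n ≤ 6).
* *merge variants*: split at ⌈n/2⌉, count each half with the base rule,
  then one step per element taken from the second half while the first
  is non-empty during the merge. The combine cost is a convention; it
  is documented here because the alternatives (free combine, block
  moves) change absolute counts.

The per-trial demand code is the minimum over the four rules, computed
at stimulus-generation time and stored in the trial table.

Because any exchangeable letter distribution makes the relative order a
uniform random permutation, the joint distribution of (set size, min
steps) is fully determined by these counting rules. Under them the
pooled Pearson correlation between absolute set size and steps in a
default cohort is ≈ 0.78 (the acceptance script recomputes it); lower
values would require a materially different step definition, not a
different stimulus generator.

## Titration

The Day-1 staircase adds one letter after a correct response and
removes two after an error, clamped to the stimulus range [3, 9] (the
clamp is a package choice; the floor is the smallest stimulus, the
ceiling the largest). Default length is 150 trials (six 25-trial
blocks). Per-size accuracies are fitted by unweighted least squares
with a two-parameter sigmoid, asymptotes fixed at 1.0 and 0.5 — the
values implied by the peripheral anchors (sizes 1–2 at 100%, sizes
10–11 at 50%) that are always appended before fitting. Observed sizes
with fewer than 10 trials are entered at 50% only when they lie above
the best-sampled range: the staircase rarely overshoots a subject's
span, and those sparse top sizes are where raw accuracies are pure
noise; under-sampled *small* sizes keep their raw values because the
100% anchors already stabilise that end.

*Criterion* is the continuous set size where the fitted curve crosses
82% accuracy (clipped to the anchored range [1, 11]). The four titrated
levels are consecutive: Easy is the largest integer size whose fitted
accuracy is still above Criterion, Very Easy sits below it, Medium and
Hard above; the starting size is clamped to [3, 6] so all four levels
stay within the stimulus range. Weighting the sigmoid fit by trial
counts is a plausible alternative; unweighted fitting is used and
flagged as an assumption.

## Synthetic cohorts

The generator's defaults are the study conditions: 41 subjects, 4 runs
of 30 trials, starting sizes drawn 12/19/9/1 over 3–6, equal trial
counts per relative level (balanced within runs to 7–8), probe mix
40/40/20 within each run, truncated-exponential ITIs with 5 s mean on
[2, 10] s (redrawn until a run fits its 508 s), and a 1.6% uniform
non-response rate whose trials are excluded from all model fits.
Criterion is drawn uniformly inside (start+1, start+2), the interval
the level-derivation rule maps back to that starting size.

Behaviour follows the mixed-model coefficient structure with relative
level coded 1–4 (uncentred) and raw steps 0–7: accuracy
`logit p = 4.10 − 0.94·level − 0.49·steps + 0.11·level·steps` plus
subject random intercepts/slopes (SDs 0.60/0.25/0.15), and RT
`1129.17 + 284.36·level + 89.22·steps − 29.14·level·steps` ms plus
random effects (SDs 180/40/20 ms) and Gaussian residual (SD 300 ms),
truncated at the 4000 ms deadline. The covariate coding is an
assumption (the source tables do not state centering), so recovery
checks are stochastic, not exact.

### BOLD generative model

Per run, node *i*'s signal is a sum of HRF-convolved per-trial delay
regressors weighted by a trial amplitude, plus AR(1) noise (stationary
SD 1.0, coefficient 0.3) and a linear mix of eight confound random
walks (six motion, WM, CSF; mixing SD 0.08). The amplitude carries:

* a node-specific unmodulated delay response (U(0.012, 0.036));
* demand modulation — maintenance nodes gain U(0.030, 0.066) per
  relative level, manipulation nodes U(0.018, 0.042) per sorting step;
* a community latent: all 23 maintenance nodes share a per-trial
  amplitude weighted 0.19, all manipulation nodes one weighted 0.115,
  drawn bivariate-normal with correlation
  `rho(level) = −0.15 − 0.12·gain·level`;
* a *static* shared latent with zero-mean node loadings (SD 0.12) —
  a stable edge pattern that anchors state-to-state similarity;
* a *level-specific* shared latent with loadings redrawn per difficulty
  level, scaled by the subject's reconfiguration gain (SD 0.12·gain) —
  the component that makes connectivity states differ more in subjects
  with higher gain.

The gain is `max(0, 1 + 0.5·(Criterion − mean) + N(0, 0.2))`, tying
network flexibility to ability. Amplitudes and coupling weights were
calibrated once so that the estimated cPPI means land on the intended
regime — within-network ≈ 0.23 (maintenance) and ≈ 0.12 (manipulation),
between-network ≈ −0.04 and declining with level — and then frozen;
the property tests measure, they do not tune.

What the generator does **not** emulate: spatial structure (the 471
"ROIs" are abstract indices), physiological noise beyond AR(1) plus
confound mixing, HRF variability across regions, non-linear BOLD
saturation, learning or fatigue across runs, and probe-period activity
differences by probe type. Passing tests therefore demonstrate that the
estimators recover the planted statistical structure at realistic SNR,
not that they are robust to everything real data contains.

Structural matrices place within-network FA 0.05 above a 0.40 baseline
with edgewise noise SD 0.05, clipped to [0, 1].

## GLM

Events are modelled on a 0.1 s microtime grid, convolved with a
double-gamma HRF (peak delay 6 s, undershoot 16 s, ratio 1/6, 32 s
kernel, unit peak; the dt factor keeps regressors on the
continuous-convolution scale) and sampled at volume times. Parametric
modulators are mean-centred across the run's correct trials before
convolution and residualised against the unmodulated delay column
afterwards (orthogonalisation after convolution is the software
convention adopted here). Incorrect and non-response trials get
duplicate array/delay/response regressors. A constant modulator is
dropped with a warning rather than entering as a zero column.

Per-ROI OLS is fitted per run; runs combine by inverse-variance
(fixed-effects) averaging, subjects by a one-sample t converted to z
through the two-sided p-value, capped at ±38 to keep zero-variance
synthetic cases finite. VIFs are computed per run from the task columns
only (confounds excluded) and averaged across runs; runs where a
modulator is perfectly collinear — possible when a weak subject leaves
only a handful of correct trials — are excluded from the average with a
warning. No prewhitening is applied beyond the generator's AR(1); OLS
is used and flagged.

## Network definition

ROIs are ranked by group z per effect and the top `floor(fraction ×
n_rois)` form each network — floor, not round-half-even, so 5% of 471
gives exactly 23. A contested ROI goes to the effect with the larger z
(ties to set size) and the other network backfills from its ranking;
remaining ties break by ascending ROI id, making the partition a
deterministic function of the map. The subject-level conjunction
utility thresholds `min(z_set, z_steps)` at 2.576 (uncorrected), a
replacement for voxelwise cluster correction that is out of scope at
ROI level.

## cPPI connectivity

No deconvolution is applied: the PPI term is the demeaned BOLD
timecourse times the demeaned convolved psychological regressor. The
psychological regressor of a condition is the unmodulated delay
regressor restricted to that level's trials (weight 1), since levels
are analysed separately. For each node pair the partial correlation
removes the psychological regressor, both raw timecourses, six motion
parameters and WM/CSF — solved in closed form from Gram blocks and
verified against per-pair regression to 1e-10. Estimation is per run
with Fisher-z averaging (run order invariant); a run lacking trials at
a level is skipped for that condition. Steps are rebinned within
subject to four equal-count levels by quartile assignment with stable
ties in trial order ("interpolation" of the 0–7 distribution is
unspecified; quartile binning achieves the stated equal-count goal).
Encoding and response regressors are excluded from the nuisance set by
default (configurable).

## Segregation, reconfiguration, behaviour

Within-network means use the upper triangle of each community block,
the between mean the full cross block; means are *signed* (negative
edges included), following the defining formula over the "mean
magnitudes" phrasing — the magnitude variant is available via
``magnitudes=True`` but would change the sign behaviour of segregation
and is intentionally not the default.
Segregation is `(Z̄w − Z̄b)/Z̄w`, undefined (raised) at `Z̄w = 0`.
Node-level segregation (per-node within/between means, averaged per
network) is reported alongside, since the defining text is ambiguous
about the level of aggregation. Reconfiguration is `1 − mean pairwise
state similarity` with Spearman similarity by default (Pearson as an
option); with four states the ordered-pair average equals the
unordered-pair mean because similarity is symmetric.

Difficulty trends are tested by a linear mixed model (subject random
intercepts) fitted by ML with and without the linear level term;
the LRT chi-square has 1 df. Brain–behaviour coupling is the Pearson
correlation of a per-subject reconfiguration score with Criterion, and
two correlations on the same sample are compared by Fisher's r-to-z
with `z = (z1 − z2)/sqrt(2/(n − 3))`.

The trial-level behaviour models are delegated to lme4 (glmer/lmer)
via Rscript — binomial logistic for accuracy over responded trials,
linear for RT over correct trials — with by-subject random intercepts
and uncorrelated random slopes for level and steps, and LRTs from ML
refits. Subject-level covariates (gender, starting set size) are
accepted as additional fixed-effect controls and otherwise
uninterpreted. statsmodels MixedLM provides an in-process linear
backend used as a cross-check. lme4 cannot fit exactly noise-free data
(zero residual variance), so the exact-recovery check uses the MixedLM
route there.

## Numerical choices and degenerate inputs

* z statistics capped at ±38; partial correlations clipped to [−1, 1]
  and Fisher-z inputs to ±0.999999.
* Constant node timecourses yield NaN-flagged connectivity entries.
* ITI draws are rejected (up to 1000 times) until the run fits; a
  proportional compression toward the 2 s floor is the fallback.
* Logits are clamped at ±30 with a warning for extreme parameters.
* Sub-seeds derive from `SeedSequence([master, stage-code, index])`, so
  any stage/subject is reproducible in isolation.

## Problem sizes in the test suite

Unit tests run on reduced instances (120 ROIs with 12-node communities,
5–12 subjects); the study-level checks use the full 41-subject design
for trial arithmetic, VIF and behavioural recovery (20 seeded cohorts),
and 20 seeded 12-subject imaging cohorts for the directional network
properties. These sizes were chosen so the full suite runs on a single
CPU while keeping every directional check at ≥ 90% per-cohort
reliability.

## Known limitations

* The step-counting rules are conventions; absolute step counts (and
  any statistic derived from them, such as the pooled set-size/steps
  correlation of ≈ 0.78) depend on them.
* OLS without prewhitening mildly miscalibrates single-run standard
  errors under AR(1) noise; the group-level z calibration test bounds
  the practical effect.
* The generator's reconfiguration mechanism is rank-one per level; real
  connectivity reconfiguration is higher-rank, so the
  reconfiguration–ability correlation here is a recovery check, not a
  quantitative prediction. Between-network reconfiguration does not
  systematically exceed within-network reconfiguration under these
  defaults.
* FA matrices are generated only for the 46 network nodes, with no
  distance structure.
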