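# Methods

`cmipipe` implements the analysis chain of a cognitive-motor integration
(CMI) study design: a center-out reaching task under direct and
decoupled visuomotor mappings, symptom questionnaires, within-network
resting-state functional connectivity (RSFC), and along-tract diffusion
statistics, tied together by covariate-adjusted linear models.  This
note records the models, the defaults and why, the numerical choices,
and what the synthetic cohort does and does not emulate.

## The reaching task and its kinematic model

The task geometry is four peripheral targets at 55 mm eccentricity
around a 7.5 mm central target, a 2,000 ms pre-go hold, a 500 ms
terminal hold, and two mappings: *standard* (cursor follows the finger)
and *plane-change + feedback reversal* (finger on a horizontal surface,
cursor on a vertical screen, motion reversed 180°).

Synthetic trials use a minimum-jerk ballistic segment,
`s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`, whose tangential speed peaks at
`1.875·D/T` for amplitude `D` and duration `T`.  Minimum-jerk is the
standard kinematic model for ballistic center-out reaches and gives
closed-form oracles for the scorer (peak speed, threshold-crossing
times).  Corrective sub-movements are appended as smaller minimum-jerk
segments; direction-reversal (DR) trials first launch 180° off-goal for
a configurable fraction of the amplitude (default 0.3, large enough to
exit the central target) before correcting.  Sampling is 200 Hz,
positions in mm in a screen-centered frame (x rightward, y upward) —
tablet rate and units are declared defaults, not inferred.  Feedback
reversal is modeled in cursor space: stored trajectories are cursor
positions, with the point-reflected finger trace retained alongside.

### Scoring conventions

Velocity profiles are central differences of positions smoothed by a
5-sample moving average (raw differencing of tablet data produces
spurious threshold crossings; the window is configurable and `1`
disables smoothing).  Movement marks use the 10 %-of-peak-velocity
convention with crossing times interpolated linearly between samples and
clamped to the sample interval:

* **onset** — first upward crossing after the go cue.  This anchors the
  marks to the *initial* movement: on a DR trial the global speed peak
  belongs to the later corrective movement, and scoring backwards from
  that peak would skip the wrong-direction excursion entirely.
* **ballistic offset** — end of the first supra-threshold burst (first
  downward crossing after onset).
* **full offset** — the final downward crossing after which every
  subsequent sample stays within target radius + 2 mm of the terminal
  position (the operational replacement for visual plateau inspection).

The reported PV is the maximum speed within the ballistic span, while
the 10 % threshold is set from the whole-profile peak: the textbook
definition is circular (PV defines the threshold that delimits the
ballistic segment), and this single-pass cut resolves it.

Error filters, applied in order: finger left the central target before
the go cue; RT < 150 ms; RT > 8,000 ms; MTf > 10,000 ms (strict
inequalities; a trial at exactly 150 ms passes).  The home-hold check
reads raw pre-go positions directly because an early-moving trial is
often unscorable by the crossing rules.

DR classification walks the trajectory from onset to its first exit of
the central target region and flags an angle strictly greater than 45°
between the exit displacement and the straight line to the target.  It
is assessed in cursor space by default (the behavioral goal is
cursor-to-target); finger space is available via `space="finger"`.

Session summaries drop a trial when any of RT, MTf, PV, PLb, PLf
deviates more than 2 SD from the participant-condition mean, in a single
pass.  AE is the distance from the per-target mean endpoint to the true
target, averaged over targets; VE is the root mean squared distance of
endpoints about their per-target mean — the root form keeps VE in mm.
Endpoints are terminal-plateau means (robust to single-sample jitter;
exactly the target on a noiseless trial).  %DR uses all non-error
attempts as the denominator.  Composites average cohort z-scores:
timing = mean(z_RT, z_MTf, −z_PV), trajectory = mean(z_PLf, z_AE,
z_VE).  Standardization pools both conditions by default: standardizing
within condition forces each condition's composite mean to exactly zero
and makes the paired between-condition contrast degenerate;
`by_condition=True` provides that variant anyway.

## Questionnaires

RPQ: 16 items on 0–4; RPQ-3 = items 1–3 (early physical cluster, max
12), RPQ-13 = items 4–16 (max 52).  A rating of 1 ("no more a problem")
stays in the sums but never counts as endorsed; endorsement requires a
rating ≥ 2.  DHI: 25 items on {0, 2, 4} with configurable
item-to-domain schemes, because the instrument description is
internally inconsistent: the default `paper` scheme has 6 physical, 10
functional, 9 emotional items (domain maxima 24/40/36), the `standard`
scheme follows the published instrument (7/9/9 → 28/36/36); both total
100.  Endorsement tables report counts, two-decimal percentages, and
mean ± SD among endorsers.

## Connectivity

Pairwise Pearson correlations of parcel time-series are mapped through
Fisher's r-to-z (`arctanh`), with |r| clamped at 1 − 1e−7 so degenerate
pairs stay finite; zero-variance parcels are flagged and their pairs set
missing, and within-network means run over the surviving distinct pairs
only.  The analysis networks are VN, SMN, DAN, SVAN, FPCN and DMN (the
limbic network is excluded); FPCN parcels are split into a/b/c
subnetworks by nearest-centroid matching (Euclidean, MNI mm) against a
finer parcellation's labeled centroids, ties broken toward the lowest
candidate parcel id.  Parcel homogeneity — the mean pairwise temporal
correlation of the vertices inside a parcel — is provided as the QC
metric; parcellation optimization itself is out of scope and the label
table is an input.

## Along-tract statistics

A profile is `participants × L` values of FA or MD at shared
cross-sections.  `AlongTractGLM` fits OLS at every cross-section and
tests one contrast; the cluster-forming threshold is the two-sided
t(n − p) quantile at p = 0.05 (supplied on the p scale, converted to
|t|).  Contiguous supra-threshold runs form clusters, split at sign
changes so opposite-direction effects report separately.

Familywise correction is permutation-based (default 5,000 permutations)
with the Freedman–Lane scheme: profiles are residualized on the nuisance
design, residual rows permuted, the reduced-model fit added back, and
the full model refitted; the null statistic is the maximal cluster over
the profile, pooled across signs.  `cluster_p = (1 + #{null ≥ obs}) /
(1 + n_perm)`, so the smallest attainable p is `1/(1 + n_perm)`.
Bilateral tracts get a factor-2 Bonferroni across hemispheres;
commissural tracts factor 1.

The default cluster statistic is **size** (reported in points and in mm
via the point spacing); a **mass** option (summed supra-threshold |t|
exceedance) is available.  Two properties of the size statistic are
worth knowing.  First, it is integer-valued, and ties between observed
and null maxima make it conservative at desk-scale profile lengths:
measured familywise error on null AR(1) profiles sits at roughly
0.013–0.03 for a nominal 0.05, while the continuous mass statistic
calibrates at the nominal level.  Second, an overwhelming effect cannot
reach the minimal attainable p under the size statistic: the observed
cluster is capped at the effect window's width, which
effect-carrying permuted residuals also reach in about α of
permutations; under the mass statistic an exact effect has infinite
observed mass and attains the floor deterministically.  The calibration
tests reflect this: two-sided calibration is asserted for mass, valid
(at-or-below-nominal) control for size.

Entire-tract analyses average the profile per participant and feed the
shared regression layer; Holm step-down adjustment is applied across
the non-intercept terms of each regression (the family is the single
regression analysis).

Numerical guards: residual variances below 1e−25 are treated as exact
fits (zero), so noiseless profiles yield t = ±∞ at true effects and
t = 0 elsewhere instead of rounding-noise t-values.

## Shared inference layer

`fit_linear_model` wraps a numerically stable OLS (statsmodels) and
reports unstandardized B, SE, t, two-sided p, 95 % CI and R²; rows with
missing values are dropped listwise with the retained n reported;
rank-deficient designs are rejected naming the collinear columns.  Two
preset adjustment families exist: symptom models adjust for {age, sex,
sport experience, days since last concussion}; visuomotor models add
video-game experience.  Sex (and any two-level string covariate) is
encoded as a 0/1 indicator of the lexicographically later level.
`paired_t` handles the degenerate zero-variance cases explicitly (t = 0
for all-zero differences, ±∞ otherwise).  Holm adjustment is the
standard step-down, verified against the textbook recursion.

## The synthetic cohort: what it emulates, and not

Defaults mirror the study design: 22 participants, 20 trials per
condition (5 per target), both mappings, 16 RPQ + 25 DHI items driven by
a latent severity, 200 parcels in a 7-network layout, and tract profiles
with a smooth baseline, AR(1) noise along the tract (ρ = 0.5 — real
diffusion profiles are smooth, and white noise would make cluster
inference unrealistically easy), and a localized linear covariate
effect.  Direction reversals are injected at 0.02 (standard) vs 0.30
(decoupled) and corrective sub-movements at 0.10 vs 0.40, which is what
drives the expected positive condition differences in %DR and full path
length.  One integer seed is fanned out through counter-based
`(seed, participant, stream)` keys, so enlarging a cohort never
reshuffles existing participants.

Not emulated: eye movements, biomechanics, raw MRI/BOLD images,
physiological noise spectra, scanner drift, realistic between-network
correlation structure (cross-network correlations are zero in
expectation), or item-level questionnaire factor structure beyond a
single severity dimension.  Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated under the assumed data model,
not that the generator reproduces real concussion data.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale study conditions: unit tests use cohorts of 2–12
participants; oracle-equivalence checks run 100 randomized instances per
rule; Monte-Carlo recovery uses 200 replicate cohorts (n = 40) for the
tract slope, 100 replicates for within-network correlation, and 240
trials for DR recovery; type-I calibration runs 500 replicate null
cohorts (n = 20, L = 50) at 500 permutations; the acceptance script
fits one tract model at the full 5,000 permutations.

## Known limitations

* The full-offset plateau rule replaces per-trial visual inspection; a
  per-trial override is possible by editing the trial table, but no GUI
  exists.
* The permutation engine permutes participant rows as given; inputs
  should be in a canonical participant order for bit-reproducibility
  across differently-ordered files.
* "Multivariate" entire-tract models are fitted per outcome with Holm
  across terms; a joint multi-outcome model is not implemented.
* FA values are clipped to [0, 1] in the generator, which distorts the
  injected linear effect when |slope·covariate| approaches the clip
  boundaries.
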