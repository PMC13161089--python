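# cmipipe

Analysis pipeline for cognitive-motor integration (CMI) studies of
persistent post-concussion symptoms: it scores center-out reach trials
into kinematic outcomes, scores symptom questionnaires, summarizes
within-network resting-state connectivity, and runs along-tract and
entire-tract white-matter regressions with permutation cluster
correction — all exercised end to end on a built-in synthetic cohort
generator, so every stage is testable without any imaging data.

It is written for researchers who already have tabular outputs of
standard neuroimaging preprocessing (per-trial finger trajectories,
questionnaire item tables, parcellated BOLD time-series, along-tract
FA/MD profiles) and want a reproducible, covariate-adjusted analysis of
how visuomotor performance, symptoms and brain measures relate.

## What it computes

**Reach kinematics.** Trials under a *standard* mapping and a
*plane-change + feedback-reversal* mapping (finger and cursor move in
opposite directions on different planes) are scored at the 10 %-of-peak
velocity convention into seven outcomes: reaction time RT, full
movement time MTf, peak velocity PV, ballistic and full path lengths
PLb/PLf, absolute error AE (accuracy: distance of the mean endpoint
from the target), variable error VE (precision: endpoint dispersion),
and %DR — the percentage of trials whose initial movement deviates more
than 45° from the straight line to the target.  Trials violating timing
filters (home hold, RT < 150 ms, RT > 8,000 ms, MTf > 10,000 ms) are
errors; outcomes more than 2 SD from the participant mean are trimmed.
Cohort z-scores combine into composites: timing = mean(z_RT, z_MTf,
−z_PV), trajectory = mean(z_PLf, z_AE, z_VE).

**Questionnaires.** RPQ (16 items, 0–4) splits into RPQ-3 (early
physical symptoms, max 12) and RPQ-13 (later psychological/cognitive,
max 52); a rating of 1 stays in the sums but is not an endorsed symptom
(endorsement ≥ 2).  DHI (25 items) yields physical/functional/emotional
domain scores totalling 100 under configurable schemes.

**Connectivity.** Pairwise parcel correlations are Fisher-z transformed
(z = arctanh r) into a symmetric connectivity matrix; within-network
means over all distinct parcel pairs summarize the visual, sensorimotor,
dorsal-attention, salience-ventral-attention, frontoparietal-control
(split a/b/c by nearest-centroid matching) and default-mode networks.

**Tract statistics.** For a profile `y_ij` (participant i,
cross-section j), an OLS model is fitted at every j; contiguous runs
with |t| above the t(n−p) quantile form clusters whose sizes are tested
against a Freedman–Lane permutation null of the maximal cluster
(`cluster_p = (1 + #{null ≥ obs})/(1 + n_perm)`), with Bonferroni
doubling across hemispheres.  Entire-tract means feed covariate-adjusted
regressions with Holm step-down correction per regression family.

## Worked example

```python
import numpy as np, pandas as pd
from cmipipe import (CohortSpec, generate_cohort, score_cohort, paired_t,
                     AlongTractGLM, generate_tract_profiles)

# a 22-participant synthetic cohort with the default study design
cohort = generate_cohort(CohortSpec(seed=7, n_participants=22))
trial_df, sessions = score_cohort(cohort.trials)
wide = sessions.pivot(index="participant", columns="condition",
                      values=["pct_DR", "PLf"])
for m in ("pct_DR", "PLf"):
    r = paired_t(wide[(m, "pc_fr")], wide[(m, "standard")])
    print(f"{m:>7}: {r.summary()}")

# an along-tract model with a known localized severity effect
rng = np.random.default_rng(7)
cov = rng.normal(size=40)
prof = generate_tract_profiles(40, 60, cov, (20, 30), 0.5, (0.05, 0.5),
                               rng, measure="MD")
res = AlongTractGLM(prof, pd.DataFrame({"severity": cov}),
                    contrast="severity").fit(n_perm=5000, seed=7)
print(res.summary())
```

prints

```
 pct_DR: paired t(21) = 11.689, p = 1.18e-10, mean difference = 28.99
    PLf: paired t(21) = 4.878, p = 7.991e-05, mean difference = 2.875
Along-tract GLM: MD along synthetic_tract (left), n = 40, L = 60, contrast = severity
cluster-forming |t| > 2.024 (p = 0.05 two-sided, df = 38); 5000 permutations; hemisphere Bonferroni x2
          tract hemisphere measure  start  end  size_points  size_mm  peak_t  sign  cluster_p  bonferroni_p
synthetic_tract       left      MD      7    7            1   1.0000 -3.4978    -1     0.8960        1.0000
synthetic_tract       left      MD     20   29           10  10.0000 60.7473     1     0.0372        0.0744
synthetic_tract       left      MD     32   32            1   1.0000  2.2415     1     0.8960        1.0000
synthetic_tract       left      MD     39   40            2   2.0000  2.6092     1     0.3605        0.7211
```

The paired tests recover the built-in condition difference: the
decoupled mapping produces ~29 percentage points more direction
reversals and ~2.9 mm longer full paths than the standard mapping.  The
tract model finds the injected effect exactly where it was placed
(cross-sections 20–29, a 10-point cluster with permutation-corrected
p = 0.037 before and 0.074 after hemisphere Bonferroni), while the
stray single-point excursions are correctly dismissed.

## Command line

```sh
cmipipe simulate --seed 1 --out cohort/          # write a synthetic cohort
cmipipe score-kinematics --trials cohort/trials.tsv --out kin/
cmipipe score-questionnaires --items cohort/questionnaire_items.csv --out q/
cmipipe tractglm --profiles cohort/tract_profiles.tsv \
        --covariates cohort/covariates.csv --outcome rpq3 --n-perm 5000
cmipipe demo --seed 1 --out demo/                # every stage, small cohort
cmipipe validate --trials mydata/trials.tsv      # schema checks
```

All I/O is plain CSV/TSV; `cmipipe simulate --dump-config` prints every
generator default as JSON.

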