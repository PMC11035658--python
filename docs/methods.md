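# Methods

## Problem setting

Ecological momentary assessment (EMA) apps collect the same short
questionnaire from each user many times — several times a day for symptom
trackers, weekly for mental-health panels.  A natural supervised task is to
predict the ordinal class of a user's *next* answer (at `t_next`) from the
answers they just gave (at `t_now`).  All assessments of one user form a
*group*: they share a stable person-level component, so a model evaluated
with folds that ignore the grouping sees fragments of the same user on both
sides of the split.  `emabench` measures how much that choice, and the
choice of baseline, biases the performance estimate.

## Evaluation protocol

1. **Outer split.**  Users are ordered by sign-up (first assessment) and
   the last `ceil(0.2 · n)` users form the test set; the same test users
   are reused by every approach.  Not shuffling users mimics deployment —
   newly joining users are the ones the model must serve — and lets any
   cohort-level drift flow into the test set.  A `random` ordering mode
   replaces the sign-up order by a seeded permutation.
2. **Internal validation** (k = 5 folds) with four approaches:
   `time_cut` (contiguous blocks by arrival time of the labelled
   assessment; assessment-level, group-unaware), `user_cut` (users dealt
   into k disjoint groups; group k-fold), `average_user` (user_cut after
   an expanding per-user median/mode smoothing of the features), and
   `user_wise` (one model per user with a per-user temporal 80/20 split;
   users with fewer than 10 assessments are excluded).
3. **Baselines.**  Four training-free heuristics predict from known
   targets only: the latest or the modal previous answer, either of the
   same user (user level) or of everyone (assessment level).  The user's
   own just-completed `t_now` answer counts as known at user level (the
   "last completed questionnaire"); at assessment level only records from
   strictly earlier completions enter the shared pool — otherwise the two
   "latest" heuristics would coincide by construction.  A brand-new user
   falls back to the assessment-level pool, then to the training modal
   class.
4. **Scores.**  Weighted F1 (per-class F1 weighted by true support)
   per fold and on the test set.  The final score is

   `f1_final = f1_test − α · σ(f1_train)`,  α = 0.5 by default,

   with σ the *sample* standard deviation over fold scores, penalising
   approaches whose validation estimate is unstable.  The fold σ doubles
   as an estimator of the generalisation error: a result is *in range*
   when `f1_train − f1_test ≤ σ`.  Approaches are ranked per dataset by
   final score (average ranks on ties) and aggregated across datasets as
   mean rank ± sd of ranks.

The classifier is deliberately fixed: a random forest, 100 trees, Gini
impurity, one shared seed, no tuning — so ranking differences are
attributable to the splitting approach, not the model family.

The final test model is trained once per feature representation on all
training-user instances, so `time_cut` and `user_cut` share `f1_test`
exactly; their final scores differ only through the fold σ.

## Synthetic study generator

Real EMA exports are rarely shareable, so the pipeline ships a generator
whose defaults emulate a mid-sized mobile-health study.  For user *i*
(sign-up quantile `q_i`) at assessment *t*:

`y*_it = u_i + δ·q_i + s_it + e_it`,  `target = Φ(y*_it)` ∈ [0, 1],

* `u_i ~ N(0, icc)` — user effect; `icc` is the between-user share of the
  drift-free latent variance (default 0.5);
* `s_it` — stationary AR(1) chain, coefficient `rho` (default 0.6),
  variance `ar_share · (1 − icc)` with `ar_share = 0.8`; initialised at
  its stationary law so there is no burn-in;
* `e_it` — white noise with the remaining variance, so the latent variance
  is 1 and the Φ-mapped target fills [0, 1] with equal 20 % mass per
  default class;
* `δ` (`drift_strength`) — cohort drift: later sign-ups get a higher
  latent mean.  Drift acts through the sign-up quantile, not calendar
  time, matching the device of sorting users by sign-up to expose drift.

Structure around the latent model:

* **Counts.**  Per-user assessment counts are log-normal
  (median 12, σ = 1 by default, minimum 1), giving the heavy right tail of
  power users.
* **Timestamps.**  Sign-ups are uniform over the study span; within-user
  gaps are log-normal around `median_gap_hours` (default 24 h, σ = 1,
  hours-to-weeks tails) with a mild per-user gap multiplier.
* **Features.**  `n_informative` features equal `y*` plus noise at
  `feature_snr`; `n_noise` features are outcome-free.  Every feature also
  carries a stable per-user intercept (`feature_user_sd`, default 0.5) —
  the idiosyncratic answer style that makes users *identifiable* to a
  model without helping it predict unseen users.  This is the
  subject-specific (as opposed to outcome-related) signal that
  group-unaware cross-validation exploits; with it set to zero the
  leakage effect largely disappears, because the shared features then
  tell the model everything the user's identity would.  One feature is
  quantile-binned into 4 categorical levels to exercise mode imputation
  and categorical encoding; answers are masked missing completely at
  random at `missing_rate`.

What the generator does **not** emulate: informative missingness,
notification-schedule autocorrelation in response times, item-level
response styles beyond an intercept, panel attrition, or any real study's
joint feature distribution.  Passing tests therefore demonstrate that the
pipeline detects the targeted mechanisms when they are present — not that
any particular real dataset exhibits them at the same magnitude.

## Study conditions used by the shipped experiments

* **Leakage / in-range.**  300 users over a 60-day window, count median
  15, `icc 0.6`, `rho 0.6`, `feature_snr 0.5`, `feature_user_sd 1.0`,
  6 informative + 4 noise features.  The short, well-mixed window makes
  time blocks and users cross-cut, which is what gives assessment-level
  folds their optimism; 20 replicate studies are used for the in-range
  frequency comparison.  Sizes are chosen so a full replicate runs in
  seconds on one core while the effect is well clear of seed noise.
* **Heuristic competitiveness.**  250 users, `rho 0.95`, near-noise-free
  features, no answer-style intercepts: the features measure the current
  state almost exactly, and the outcome barely moves between assessments —
  the regime in which "the next answer equals the last one" is hard to
  beat.
* **Concept drift.**  200 users over a year with `drift_strength 1.5` on
  top of the weak-feature regime.  On a bounded ordinal scale a strongly
  drifted late cohort concentrates near the top class, so the sign-up
  sorted test set diverges from the shuffled baseline with a large
  *positive* signed drop (the concentrated test set is easier for a
  majority-leaning model).  The diagnostic is the divergence between the
  sorted and shuffled runs — under no drift both estimates coincide —
  together with the mean absolute rank change of the approaches.

## Numerical conventions and edge cases

* Timestamps are parsed as ISO-8601 and held tz-aware UTC; rows are kept
  in (user, time, assessment-id) order, the id breaking ties, so every
  causal operation has a reproducible total order.
* Target binning uses half-open intervals `[k/5, (k+1)/5)` with the top
  interval closed at 1.0; natively ordinal targets bypass binning.
* Imputation: per-user mean (numeric) or mode (categorical/boolean, ties
  toward the smallest value), falling back to the dataset-wide statistic;
  a feature missing everywhere is an error, not a silent fill.
* Expanding mode (average_user) breaks ties toward the earliest-observed
  value, keeping the transform causal and deterministic; the transform
  touches features only, never targets.
* `user_wise` counts the 10-assessment threshold on assessments, not
  instances; its fold scores are one per retained user (mean of a
  time-ordered CV on that user's training part) and its test score pools
  all per-user test predictions into one weighted F1.  The approach is
  independent of the outer user ordering by construction.
* Sample sd (ddof = 1) is used for fold scores and cross-dataset rank
  spreads; a single fold or dataset has sd 0.
* All F1 quantities are fractions internally; percent formatting happens
  only in reports.
* Sub-seeds derive from the master seed via SHA-256 of
  `(seed, label, purpose, index)`, keeping every cell of an experiment
  independent yet byte-reproducible; random-forest fits canonically sort
  training rows first so row order cannot leak into predictions.

## Known limitations

* The generator's drift is a monotone cohort shift; calendar-time drift
  within a user's own series is not modelled.
* Heuristic fold evaluation pairs user-level heuristics with the user-cut
  fold plan and assessment-level heuristics with the time-cut plan; other
  pairings are defensible but would blur the level comparison.
* `time_cut` uses equal-count contiguous blocks rather than calendar
  months (a `calendar` mode would need externally meaningful period
  boundaries); block boundaries therefore never straddle identical
  `t_next` values deterministically only thanks to the id tie-break.
* With very small datasets (tens of instances) the random forest's fold
  scores are noisy and the final-score ranking is close to arbitrary; the
  pipeline warns through the rank table's sd rather than refusing.
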