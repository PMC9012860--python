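# Methods

## Problem

Pharmacoepidemiologic studies on secondary data (prescription registers,
claims) must turn a list of fill dates into periods of drug exposure.
When the prescribed daily dose is missing, the duration of each filled
prescription has to be estimated.  This package implements a data-driven
estimator of those durations — the Sessa Empirical Estimator (SEE) —
together with the synthetic cohort generator and the exposure-status
validation used to characterise it, and a fixed-assumption comparator
(researcher-defined duration, RDD: one dispensed unit per day).

## The estimator

Let g be the "temporal distance" (gap, in days) between two consecutive
fills of the same drug by the same patient.  The working assumption is
that the dispensed amount is consumed between fills, so gaps carry
information about durations.  The algorithm:

1. **ECDF trimming.**  Pool all gaps and keep the lower 80% of their
   empirical CDF.  The cutoff is the smallest observed gap value g* with
   ECDF(g*) ≥ 0.8; every gap ≤ g* is retained (ties included), so the
   retained fraction is ≥ 80%.  This removes the artificially long gaps
   of stoppers/re-starters and hospitalisation blackouts.
2. **One random pair per patient.**  Among each patient's retained gaps,
   one is kept, chosen uniformly at random.  This stops frequent fillers
   (small amounts dispensed often) from dominating the estimate.
   Patients whose every gap exceeded the cutoff drop out of fitting.
3. **Standardise and cluster.**  The sampled gaps are standardised
   (sample mean/SD, n−1 denominator) and clustered with k-means
   (squared-Euclidean, Lloyd, 50 random restarts, best inertia kept).
   K is chosen over 2..10 (capped at one less than the number of
   distinct values) by maximising the average silhouette width; ties go
   to the smaller K.
4. **Cluster medians as durations.**  Each cluster's estimated duration
   is the empirical median of its member gaps on the original day scale.
   The median of the empirical distribution equals the median of its
   density, so no kernel/bandwidth choice is introduced.
5. **End of supply.**  Every fill with a following fill is assigned to
   the nearest cluster center (its gap standardised with the fitted
   mean/SD; gaps above the trimming cutoff included, so very long gaps
   receive the largest cluster's median).  End of supply = fill date +
   assigned duration, rounded to whole days (half away from zero).

**Last fills.**  A patient's final fill has no following gap, but an
exposure query needs a duration for it.  It inherits the cluster of the
patient's most recent assigned fill; a patient with no assigned gap at
all receives the median of the cluster medians, rounded to the nearest
day.  This rule is a package choice — any rule is necessarily a
convention, since the data end there.

**Degenerate inputs.**  If the sampled gaps have zero variance, or fewer
distinct values than k_min, the model collapses to a single cluster whose
median is the common/median value.  Undefined metric ratios downstream
are reported as NaN, never coerced to 0, so degenerate runs are visible.

## Synthetic cohorts

The generator emulates a single-drug register extract: 1000 patients by
default, a 730-day window, everyone starting with a 30-day fill on day 0
and at least one refill, refill durations uniform on {30, 60, 90} days
(1/2/3 months at 30 days/month, matching the 30-day initial fill), and
no carry-over.  Six adherence trajectories drive refill timing; the next
fill occurs at the previous end of supply plus a nonnegative delay:

| group | share | delay after a supply of d days |
|---|---|---|
| high | 0.100 | U(0, d(1/0.95 − 1)) — ≈95% of days covered |
| medium | 0.093 | U(0, 2d(1/a − 1)), a ~ U(0.50, 0.90) per patient |
| declining | 0.236 | as medium with a falling linearly 0.95 → 0.40 over the window |
| intermittent | 0.093 | alternating 90-day phases, a = 0.95 / 0.50 |
| partial_dropoff | 0.379 | high until a change point ~ U(180, 540) d, then as medium with a ~ U(0.50, 0.90) — adherence partially drops off, refilling continues |
| non_persistent | 0.099 | 1 or 2 refills (equal probability) with high-style delays, then none |

The delay for the medium family has mean d(1/a − 1), so realised
availability matches the target a in expectation.  Group shares are the
realized composition of the reference simulation study, renormalised.
Delays are rounded to whole days (register resolution).  A refill that
would land past the window end is not generated; one RNG stream per
cohort is split per patient (`numpy` SeedSequence), so cohorts are
bit-reproducible from the config seed.

The generator emits a dispensed `quantity` (one unit per day of true
duration, optionally perturbed by ±`quantity_noise_days`) so the RDD
comparator can be exercised synthetically.

What it does **not** emulate: stockpiling/carry-over, dose titration,
switching, hospitalisation gaps, seasonal patterns, or register-specific
artefacts.  Passing tests therefore show correct behaviour under these
idealised fill-timing patterns, not performance on any particular
real-world register.

## Truth conventions for exposure

Two conventions are implemented, and the distinction matters:

- **Supply-based** (`true_exposure_timelines`, `compute_cma`): each fill
  covers `[fill, fill + true_duration)`; refill delays are uncovered.
  This is the availability convention behind CMA-style adherence
  summaries (it is what "50% adherence" means for the medium group).
- **Consumption-stretching** (`stretched_exposure_timelines`, the
  evaluation default): the dispensed amount is consumed over the whole
  interval to the next fill (e.g. by taking less than the nominal daily
  dose), so the patient stays exposed across the refill delay; the final
  fill contributes its nominal duration.  This matches the assumption
  that previously filled treatment is consumed before the next fill is
  started, and the plasma-concentration notion of being "recently
  exposed".

Under the stretching convention, a cohort's truth prevalence at random
dates is high (~90%): practically only post-discontinuation tails are
unexposed.  The resulting confusion matrix is strongly imbalanced —
near-perfect PPV/specificity, and an NPV diluted by false negatives —
which is why the class-balanced re-analysis is part of the evaluation.
All timelines are merged unions of half-open day intervals; membership
is `start ≤ day < end`.

## Evaluation

One uniform random date per patient inside the half-open window; each
patient contributes one confusion-matrix cell (exposed truth vs exposed
estimate at that date).  Ten metrics are computed: accuracy,
sensitivity/recall, specificity, PPV/precision, NPV, balanced accuracy,
Cohen's kappa (marginal-product chance agreement), and F1.
Duration error is |true − assigned| per fill, summarised as median and
IQR per cell and pooled over TP/TN/FN (the FP cell is typically nearly
empty).

**Balancing.**  `balanced_subsample` down-samples the truly exposed
individuals (TP ∪ FN) to the size of the unexposed class and recomputes
the metrics (default mode `truth_class`).  Down-sampling only the TP
cell (mode `tp_only`, also provided) balances raw counts but cannot
change NPV = TN/(TN+FN) by construction; shrinking FN alongside TP is
what makes the predictive values respond to balancing.

**Event-date sensitivity.**  Register-style validation has truth only on
dates of known exposure (e.g. detectable plasma concentration), so only
sensitivity is assessable.  `draw_truth_events` samples one truly
exposed day per patient; an event is detected if an estimated exposure
interval intersects ±`tolerance_days` around it (half-life slack;
default 0).

## Reproducibility and problem sizes

A single global seed fans out to per-stage 31-bit seeds (simulation,
estimator, random dates, balancing, events) via `SeedSequence`, so full
runs are byte-reproducible and stages independently re-runnable.  The
shipped replication uses the full design size — 1000 patients, five
seeds averaged (a few seconds per replicate) — and the property checks
use 50 replicates of 120-patient single-trajectory cohorts and 200
random small clustering instances against an exhaustive-partition
silhouette oracle.

## Known limitations

- **Silhouette on discretised gaps.**  Register dates are whole days; on
  cohorts whose gaps take very few distinct values (e.g. a purely
  high-adherence cohort: 30, 31, 32, 60..63, 90..95), the average
  silhouette is maximised by micro-clusters of identical values
  (score ≈ 1), so K can exceed the number of underlying durations even
  though every cluster median still sits within a couple of days of a
  true duration.  Mixed-trajectory cohorts disperse the gap values and
  the effect disappears (K = 3 is selected at the default design).
- **Cluster medians under-cover dispersed gaps.**  SEE durations are
  in-cluster medians, so roughly half the gaps in a cluster outlast
  their assigned duration; with the delay generators above ~13% of
  gap-days go uncovered, bounding sensitivity near 86% under the
  stretching convention.  How close cluster medians sit to the nominal
  durations — and hence the size of the duration error — is governed
  entirely by the delay dispersion of the fill-timing process.
- The estimator is single-drug: no joint modelling across drugs, no
  covariate-dependent durations, no grace-period episode stitching
  beyond the interval union.
- The last-fill duration rule and the same-day-duplicate merge (sum
  quantities) are conventions; registers and other implementations may
  differ.
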