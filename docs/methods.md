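# Methods

This note documents the models, rules and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## Droplet digital PCR quantification

A ddPCR reaction is partitioned into ~20,000 droplets of volume
*V<sub>d</sub>* = 0.85 nL (the QX200 partition volume; configurable).  With
*k* of *n* droplets positive, the mean copies per droplet is the Poisson
occupancy estimate

> λ = −ln(1 − k/n)

giving λ/V<sub>d</sub> copies/µL of reaction and λ/V<sub>d</sub> ·
V<sub>rxn</sub> copies per reaction (V<sub>rxn</sub> = 22 µL).  Copies per
mL of plasma then follow from the sample geometry: only *t* µL of the
*e* = 22 µL bisulfite eluate enter a reaction, and the eluate derives from
*p* mL of plasma, so

> copies/mL = copies<sub>rxn</sub> · (e/t) / p.

A fully positive well (k = n) is reported as saturated; no concentration is
emitted for it, and the TriMeth total for that sample omits it (the marker
still counts positive for calling, since its droplet count exceeds one).

### Thresholding

Published descriptions of automated ddPCR thresholding vary; this package
uses a deterministic, scale-equivariant rule derived per plate and channel
from that plate's control wells:

* negative center = median amplitude of the negative reference well;
* positive center = median of the upper class of a two-means split of the
  positive control (centers initialised at the min and max amplitude);
* threshold = max(neg + 0.4·(pos − neg), neg + 7·MAD(neg)).

The 0.4 interpolation places the cutoff well below the positive cluster
(tolerating partial-amplification "rain" that sags downward), while the
7·MAD floor keeps it clear of the negative noise band even when the
dynamic range is compressed.  If the positive control's upper cluster is
separated from the negative center by less than four times the negative
MAD, the plate is declared unanalyzable (control failure) rather than
thresholded badly.  Droplets exactly at the threshold count negative, so a
single borderline droplet cannot create a marker call.

The negative reference is the negative-control well, except on channels
reading the CF (cytosine-free region) assay: the negative control carries
unmethylated carrier DNA, which is genuine CF template, so CF channels are
referenced against the no-template control instead.

## Quality control

Three gates, applied per sample; any failure excludes the sample and every
triggered rule is reported:

| metric | rule | default |
|---|---|---|
| droplet count | every well of the sample ≥ min_droplets | 10,000 |
| leucocyte contamination | PBC copies ≤ cutoff × CF copies (pre-conversion) | 10% |
| CF signal after conversion | > 0 copies required | — |

The PBC cutoff is relative to the CF-measured DNA amount because an
absolute cutoff would misbehave across the wide range of cfDNA inputs.
Purification efficiency (CPP1 spike-in recovery, median ≈ 92% in plasma
workflows) and bisulfite recovery (CF after / CF before, median ≈ 51%) are
reported but are not exclusion criteria; efficiencies above 100% are
flagged as over-recovery.  Bisulfite recovery is computed as
after/before — the only direction consistent with recoveries below 100%.

## TriMeth calling

A marker is positive when **more than one** droplet is positive (≥ 2),
guarding against isolated false-positive droplets; a sample is ctDNA
positive when **at least 2 of the 3** markers (C9orf50, KCNQ5, CLIP4) are
positive.  The overall TriMeth concentration is the sum of the three
marker copies/mL, which preserves the total count of methylated molecules.
Samples failing QC are *not evaluable* (neither positive nor negative) and
are excluded from detection rates and dynamics groups.

## Survival analytics

Times are measured in months as days/30.4375 from the inclusion date.
RFS events are recurrence or cancer-attributed death; an explicit
non-cancer death without prior recurrence censors RFS at death (deaths of
unrecorded cause are attributed to the cancer).  OS events are deaths of
any cause.  Event-free patients are censored at the data cutoff
(2023-07-01 by default).

* Kaplan–Meier curves use the product-limit estimator with plain Greenwood
  95% intervals, S² Σ d/(n(n−d)), clipped to [0, 1]; landmark queries
  default to 24 months.
* The two-group log-rank test is computed directly from the risk tables
  (hypergeometric variance); it reproduces lifelines' statistic to
  numerical precision.  Its p-value is asymptotic: at very small samples
  (≈10 subjects) it can differ from the exact permutation p by up to
  ~0.05–0.07, which is the discreteness scale of a 252-atom permutation
  distribution; agreement tightens to ~0.02 by about 10 subjects per
  group.  This is a property of asymptotic inference, not of the
  implementation.
* Cox proportional-hazards models (lifelines, Efron tie handling, Wald
  intervals) report one hazard ratio per non-reference level; the
  reference is the first category, and callers can fix the level order
  explicitly (the pipeline uses "not detected" as reference).  The
  multivariable model admits candidates whose univariable p < 0.05.  A
  covariate level without events produces a flagged estimate (monotone
  likelihood) rather than a crash; if the fit fails to converge it is
  retried with a small ridge penalty and flagged.
* ROC analysis scores the TriMeth copies/mL (or any marker score) against
  recurrence status at end of follow-up; AUC is the trapezoidal area.
* Contingency-table associations use Pearson's chi-square without
  continuity correction.

## Study design

The required number of events for a two-sided log-rank comparison is
Schoenfeld's

> d = (z<sub>1−α/2</sub> + z<sub>power</sub>)² / (p(1−p) (ln HR)²)

with p the ctDNA-positive prevalence.  Events convert to patients by the
probability of an event within the minimum follow-up under exponential
RFS: hazard ln 2 / median in the negative group, scaled by the HR in
positives, mixed by prevalence.  Under the default assumptions (α = 0.05,
power 0.80, HR 5.4, prevalence 15%, median RFS 30 months, 18-month
follow-up) this yields 21.65 → 22 events, event probability 0.423, and 52
patients.  The 18-month follow-up convention is a documented modelling
choice: accrual/follow-up parameters of online calculators vary, and this
exponential formulation reproduces the designed cohort size exactly.

`simulate_power` checks the design by Monte Carlo: Bernoulli(prevalence)
group labels, exponential event times, administrative censoring at the
minimum follow-up, two-sided log-rank at level α.  At n = 52 the empirical
power is ≈ 0.94 — Schoenfeld's local approximation is conservative for
hazard ratios far from 1 with unbalanced groups — and with equal hazards
the rejection rate calibrates to the nominal 5%.

## Synthetic-data generator

The generator is the package's test bed: it emulates the statistical
structure the analysis assumes, with defaults set to the observed study
conditions.

* **Droplet counts** per well: normal, median 20,978, SD 909 (matching the
  reported IQR 20,230–21,456), rounded.
* **Amplitudes**: Gaussian negative cluster (1000 ± 60 a.u.) and positive
  cluster (8000 ± 300 a.u.).  Rain is modelled as 5% of *occupied*
  droplets displaced into a uniform band between the clusters (partial
  amplification), plus a 10⁻⁵ per-droplet background rate among empty
  droplets.  The background rain produces the occasional single
  false-positive droplet that the >1-droplet marker rule exists to absorb;
  a band containing a fixed percentage of *all* droplets would swamp
  single-molecule signals and was rejected.
* **Concentrations**: positive samples draw a total copies/mL from a
  log-normal with median 30 and σ(log) = 1 — producing single-digit
  droplet counts near the calling boundary in the low tail — with ±25%
  log-normal marker-to-marker variation; negative samples carry zero.
  True copies/mL refer to the measurable (post-conversion) concentration,
  so the droplet model inverts the quantification chain exactly and
  ground truth is recoverable.
* **QC metrics**: purification efficiency and bisulfite recovery are
  logit-normal around medians 92% and 51%; QC failures are injected at a
  5% rate, uniformly one of low-droplets / PBC contamination / missing CF.
* **Serial statuses**: per-timepoint positivity 56/37/25/15% with a
  Gaussian copula (ρ = 0.7) across timepoints, so marginals are exact and
  all four status-transition groups occur.
* **Outcomes**: exponential RFS with 30-month median for an all-negative
  patient, hazard multiplied by 2.54 for positivity after one chemotherapy
  cycle and 6.22 for postoperative positivity; OS is RFS plus an
  exponential post-recurrence survival (median 8 months); follow-up is
  uniform on 23.5–28.5 months before the fixed cutoff.

Everything is fully determined by the seed.  What the generator does *not*
emulate: covariate–status correlation structure (covariates are drawn
independently at roughly the observed marginal frequencies), plate/batch
effects, droplet-volume variation, bisulfite-conversion errors at the
sequence level, and non-cancer mortality.  Passing tests therefore show
that the pipeline recovers the truth of *this* generative model, not that
the assay performs identically on real plasma.

A counts-level fast path (`simulate_call_table`) draws marker droplet
counts directly (binomial occupancy plus Poisson background) without
per-droplet amplitudes; it shares the cohort and concentration models and
is used for large-cohort calibration of the calling rule, where full
amplitude simulation would be needlessly heavy.

## Problem sizes used in the test suite

Unit tests run a shared 16-patient synthetic study end to end; calibration
checks use 300–1,000-patient cohorts through the counts-level path;
parameter-recovery checks use 200 replicates of 500-patient cohorts
(hazard-ratio coverage) and 500 simulated samples at 50 copies/mL
(concentration recovery); the power simulation uses 5,000 replicates.

## Known limitations

* The thresholding rule is a documented stand-in for proprietary
  instrument software; thresholds on real exports may differ, though any
  deterministic, scale-equivariant rule with the same guard rails should
  classify clean two-cluster data identically.
* Saturated wells are reported but not re-quantified; dilution-series
  handling is out of scope.
* No Poisson confidence intervals on concentrations; no multi-dye colour
  compensation; no competing-risks or time-varying-covariate survival
  models.
* Log-rank p-values are asymptotic (see above) — at fewer than ~10
  subjects per group, treat them as approximate.
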