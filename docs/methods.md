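# Methods

This note documents the statistical procedures implemented in
`hippoprofiler`, the choices made where the underlying analysis convention
was genuinely open, and what the synthetic-data generator does and does not
emulate.

## Robust statistics convention

Every spread statistic in the package is the **raw median absolute
deviation**, `MAD(x) = median(|x − median(x)|)`, with no 1.4826
normal-consistency factor. The 2-MAD outlier rules and the modified Z′ are
defined on this scale, so applying the consistency factor anywhere would
silently change every threshold. Outlier rules use strict inequalities
(`> 2·MAD`), which makes the all-equal case (MAD = 0, deviations 0) retain
everything, and they are applied once on the original group statistics —
never iteratively re-trimmed.

## Feature curation

Near-constant features (sample variance below `variance_threshold`,
default 1e-8) are dropped first. Correlation trimming is then greedy and
deterministic: while any retained pair exceeds `correlation_threshold`
(default 0.9) in absolute Pearson correlation, the feature with the largest
mean absolute correlation to the other retained features is dropped (ties
broken by column order) and correlations are reassessed. This is the common
redundancy-removal scheme of profiling toolkits; it is seed-free and
idempotent (curating a curated matrix is a no-op). The thresholds are
config keys surfaced in the run manifest; the exact retained-feature count
depends on the data and is not a reproduction target.

## Vehicle normalization

Each retained feature is mapped to `(x − median_ctrl) / MAD_ctrl` where the
control set is vehicle (DMSO)-treated wells of the wild-type genotype,
computed per plate when several plates are present (plate-effect
containment; single-plate inputs are unaffected). Features with zero
control MAD carry no usable control spread and are dropped with a report.
The transform is invariant to shifting and positively rescaling a feature,
so downstream statistics inherit affine invariance.

## Correlation distance, clustering, uniformity

Well–well distance is `1 − Pearson r` across retained features (range
[0, 2]); zero-variance profiles have no defined distance and are rejected
with an explicit error. Pearson rather than Spearman is used because the
features are already robust-normalized continuous scores; this is exposed
as a design choice rather than buried. Clustering is complete linkage on
the distance matrix (scipy), whose merge heights equal the maximum
cross-cluster pairwise distance — asserted against brute force in the test
suite. PCA runs on the normalized matrix with no second scaling pass, since
normalization already puts features on a common robust scale; dose
trajectories connect per-(genotype, treatment) centroids from the vehicle
centroid (dose 0) upward in concentration.

Uniformity of a well is defined on *the other* members of its group
(self-distance is identically 0 and would only dilute the statistic);
singleton groups are omitted with a report. Both `mean_like_distance` and
`uniformity = 1 − mean_like_distance` are emitted, so either orientation of
"enhanced uniformity" can be plotted; comparisons in this package use the
latter, where larger means more uniform. A one-sided permutation test
(group labels shuffled between two well sets, default 200 permutations)
compares group uniformity.

## Modified robust Z′ and dependency adjustment

    Z′_mod = 1 − (MAD_treat + MAD_ctrl) / |median_treat − median_ctrl|

Three numerical decisions:

* **Absolute median difference.** The flattened one-line form of the
  equation does not show |·|, but the classical Z′-factor this modifies is
  defined on the absolute mean difference; without it the score's sign
  would flip with effect direction meaninglessly.
* **Tied medians → undefined sentinel (NaN), not −∞.** A tie means no
  separation; the feature is not disrupted, and propagating −∞ would poison
  the dependency subtraction. Sentinel rows still count as *scored* in
  percent-disrupted summaries.
* **Clamping before subtraction.** Dependency adjustment computes
  `z_WT − z_KO` after raising both scores (including sentinels) to a floor
  of −10. Near-tie denominators produce arbitrarily negative scores that
  would otherwise dominate the difference; the floor bounds their influence
  while preserving sign. By default only features with discriminatory
  potential in wild type (`z_WT > 0`) are reported; classification is
  `dependent` iff the adjusted score is > 0.

Treated groups are always compared against **their own genotype's** vehicle
wells, so dependency contrasts are not confounded by baseline morphological
differences between genotypes. Disruption calling is the deterministic
`Z′ > 0` rule; no multiple-testing layer is added, and the null call rate
of that rule under replicate noise is measured empirically (it is a
property of median/MAD sampling variation at the given well count, roughly
a quarter of null features at 4 wells/arm — the acceptance script reports
the value it measures).

## Localization analysis

Cells must have strictly positive nuclear and cytoplasmic intensity to
contribute a ratio (the weakest faithful reading of "detectable" signal;
the threshold is a config key). The cell–cell contact window is the
**closed** interval [45, 55] percent — boundary cells are retained. Ratio
computation and contact filtering commute, and per-well medians are robust
to a minority of extreme cells. Percent-of-vehicle divides each well's
median ratio by the **mean** of same-genotype vehicle-well medians (mean
mirrors common percent-of-control practice; switchable to median). The
2-MAD well rule then flags outlier wells within each genotype × treatment ×
concentration group; groups with fewer than 3 wells pass through with a
warning.

## Growth quantification

2D tracks are fit with a bounded logistic `L/(1 + exp(−k(t − t0)))` using
deterministic initialization (L from the series maximum, t0 from the
half-maximum crossing, k from a logit-transform pre-fit) — no random
restarts, so fits are reproducible. The slope statistic is the curve's
maximal derivative `L·k/4` (units per hour), the standard single-number
growth rate for sigmoidal confluency data; k alone is also reported. A
series with a negative overall linear trend is outside the model (k > 0 by
construction); it receives the negative straight-line slope with
`fit_ok = False`, which normalization then clips to 0 — shrinking cultures
score zero growth rather than spurious small positive rates. Normalization
divides by the mean vehicle slope statistic per genotype.

Spheroid trimming pools **like-treated wells within a biological
replicate** at each time-point (pooling across treatments would conflate
treatment effects with artefacts; all-wells pooling is available as an
option). Wells with strictly more than 50% trimmed time-points are
excluded — exactly half is retained. Growth is `area(168 h)/area(24 h)`
within each well; if an anchor time-point is trimmed, the nearest unmasked
point within ±4 h is used (logged), otherwise the well is skipped with a
report. Sensitivity is `response − mean reference response` per treatment ×
concentration, with `response = 100·(1 − normalized growth)`; negative
sensitivity means less growth reduction than the reference genotype.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
with defaults mirroring the profiled study design: two genotypes (wild type
and a YAP knockout), six inhibitors — three selective TEAD inhibitors and
three non-selective YAP/TAZ inhibitors — at a 1.1/3.3/10 µM dose triplet,
three biological replicate wells per condition and four technical wells per
biological replicate in the localization assay.

* **Feature matrices**: unit-variance baseline features built from shared
  latent factors per block with loading √`block_rho` (default 0.95, so the
  redundant blocks sit above the 0.9 curation threshold and curation
  retains roughly one feature per block, ~10–12% of inputs, the same order
  as real Cell Painting curation). Treatment shifts affected features by
  `effect_size` (default 6) × the MAD of a standard normal × a log-linear
  dose scale running from 0.5 at the lowest configured dose to 1.0 at the
  highest (monotone dose trajectories without asserting a pharmacology;
  single-dose treatments scale by 1). Dependent features (fraction 0.5 of
  affected) receive no shift in the knockout — all-or-none by default,
  giving unambiguous classification ground truth; a continuous
  `ko_attenuation` is exposed. Outlier wells (rate 0.02) get a large
  constant added to every feature, the failure mode the scalar 2-MAD rule
  addresses.
* **Cell tables**: lognormal cytoplasmic intensities; per-cell N:C ratios
  lognormal around a per-well level whose median is `baseline × 
  ratio_effect^dose_scale` (default top-dose effect 0.5); contact percent
  uniform on [0, 100], so the 45–55 window retains 10% in expectation.
* **Growth tracks**: logistic curves per genotype (spheroid areas on a 12-h
  grid through 168 h — the 24 h and 168 h anchors always present — or
  confluency on a 4-h grid through 72 h) times lognormal noise, with spike
  artefacts (× 5) at recorded time-points. Treatment scales k down by
  `growth_inhibition × dose_scale`.

Not emulated: image formation and segmentation error beyond tabular spikes,
plate-position (edge) effects, batch drift between biological replicates,
non-monotone dose–response, and correlations between assays (the three
tables are generated independently). Passing recovery tests therefore shows
the *estimators* behave correctly under the assumed structure, not that the
assumed structure captures every pathology of real imaging data.

All generator randomness derives from one integer seed with a fixed
substream per table type, so identical configurations reproduce
byte-identical CSVs; ground truth (affected features, dependency labels,
outlier locations, true logistic parameters, true well ratios) is written
alongside in a documented key-value text file.

## Problem sizes and degenerate inputs

Simulation-based checks run at the planted-recovery design (one drug, one
dose, 8 wells/arm, 40 features over 100–200 replicate simulations) and the
default study design for end-to-end runs; these sizes give binomial error
small enough for the recall and calibration statements being tested.
Degenerate inputs are contracts, not crashes: header-only files, missing
columns and duplicated feature names raise named schema errors; all-dropped
feature sets, absent vehicle wells and sub-replicate groups raise explicit
configuration errors; groups too small for a rule (outlier removal with
< 3 wells, trimming with < 3 wells at a time-point) pass through with a
logged warning rather than silently filtering.

## Known limitations

* The greedy correlation trim is order-dependent by design (documented
  tie-break); a different deterministic order could retain a different but
  equally valid feature subset.
* Dependency classification of truly *independent* affected features is a
  near-coin-flip by construction (their adjusted score is centred on 0);
  only the *dependent* class carries a recovery guarantee.
* The logistic fit assumes a single sigmoidal phase; biphasic or
  oscillating confluency series will fit poorly (flagged via `fit_ok`).
* Percent-of-vehicle requires vehicle wells per genotype and plate; there
  is no cross-plate borrowing.
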