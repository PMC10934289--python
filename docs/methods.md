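# Methods

This note documents the models, parameter choices, and numerical conventions
behind `imuperf`, and what the synthetic-data generator does and does not
emulate.

## Signal model and feature extraction

All features derive from the vertical (z) channel of a head-worn tri-axial
accelerometer sampled at 26 Hz.  Accelerations are gravity-inclusive: a
standing participant reads ≈9.81 m·s⁻² on z, and STS peak values of
~11–14 m·s⁻² are peaks of the raw vertical channel, not of a gravity-removed
signal.  Each test opens with a 10 s static lead-in from which the baseline
mean and SD of the vertical channel are measured.

**Filtering.** Peak and onset detection run on a 4th-order zero-phase
Butterworth low-pass copy of the signal — 5 Hz for STS/TUG and 3 Hz for gait
(cadence ≈2 Hz; both cutoffs leave headroom below the 13 Hz Nyquist limit and
are configurable).  Peak *amplitudes* are always read back from the raw
channel at the detected indices, so reported accelerations are unattenuated.

**Onset/termination.** Motion onset is the first excursion of the filtered
signal beyond `max(4·baseline SD, 0.5 m·s⁻²)` sustained for ≥3 samples,
backtracked to where the excursion leaves a `max(2·baseline SD, 0.02 m·s⁻²)`
noise band, and reported at the midpoint between the last quiet and first
active sample.  The midpoint convention removes most of the late bias of a
threshold crossing; the 0.02 m·s⁻² backtrack floor keeps the search out of
the filter's pre-ringing when the baseline is noiseless.  TUG termination
applies the same rule backwards from the trace end, with its own baseline
from the final 5 s static tail.  On synthetic traces this recovers TUG
duration with a mean absolute error of ~1 sample at noise SD 0.05 m·s⁻²
(~1.6 samples at 0.1 m·s⁻²).

**Peaks.** Local maxima with a prominence floor and a minimum spacing;
when two candidates are closer than the spacing floor the higher one wins,
then the earlier.  Defaults: separation 1.0 s / prominence 1.0 m·s⁻² for STS
(repetitions take >2 s in this population), 0.3 s / 0.3 m·s⁻² for steps
(cadence ~0.5 s/step and much smaller head-level step accelerations).
Prominence-based detection makes the peak set invariant to constant offsets,
and peak counts are monotone non-increasing in both thresholds.

**Per-test features.**

* STS: peaks within `[onset, onset+30 s)`; count and mean raw amplitude.
  Zero peaks yield count 0 and a missing mean.
* Gait: step peaks between onset and the last shuttle mark.  Step duration is
  the mean of successive peak-time differences.  Step length is the shuttle
  length divided by steps per shuttle, averaged unweighted across shuttles by
  default (a steps-weighted mean is available); a step landing exactly on a
  shuttle boundary closes that shuttle — the one deliberate exception to the
  package-wide half-open `[start, end)` interval convention, since the
  completing step belongs to the shuttle it completes.  Shuttle boundary
  times are annotations: a head-worn signal cannot localize the 10 m line,
  so the generator (or the operator) supplies them.
* 6MWT distance: `full shuttles × 10 m + partial metres` — the partial
  distance is likewise an annotation.
* TUG: termination − onset, in seconds.

## Statistical battery

Per variable and grouping: Shapiro–Wilk per group at α = 0.05 (a constant
sample is reported as non-normal); if all groups pass, one-way ANOVA with
η²p = SS_between/(SS_between+SS_within) and a Tukey–Kramer post hoc (the
harmonic-mean form valid for unequal group sizes); otherwise Mann–Whitney U
(two groups; exact for small tie-free samples, else normal approximation
with tie correction) or Kruskal–Wallis (three or more, tie-corrected, χ²
reference with k−1 df).  All tests two-sided at α = 0.05; η²p is labelled
small/medium/large at 0.01/0.06/0.14.  Missing values are excluded listwise
per variable.  No multiple-testing correction is applied across variables.

Proportions across k groups use the Pearson χ² test of homogeneity on the
2×k table without continuity correction (a Yates-corrected variant is
exposed as an option).  Published contingency tables are re-analysed through
`reconstruct_counts`, which converts printed percentages and group sizes to
integer counts by half-away-from-zero rounding and flags groups whose
reconstructed count re-prints more than 0.05 percentage points away — under
this reconstruction the five published χ² statistics (4.82, 0.54, 10.82,
3.83, 3.46) reproduce to two decimals, which is why the uncorrected Pearson
form is the default.  One published value (sex proportions, χ² = 1.57) is
not reproducible from the printed numbers — the printed female percentages
reconstruct to a different total than the reported cohort composition — and
is therefore not asserted anywhere.

## Clustering and the performance score

Lloyd K-means with k distinct data points as random initial centroids,
Euclidean assignment, mean-update refinement until the assignment is a fixed
point (or inertia improves by <1e-6), empty clusters re-seeded at the
farthest point, and the best of 50 restarts by inertia.  The number of
clusters is the argmax over k = 2..8 of the mean silhouette coefficient
(ties to smaller k; singleton clusters score 0); a best silhouette below
0.25 raises a weak-structure warning.

Features enter K-means in raw units by default.  The walk distance
(hundreds of metres against seconds-or-smaller scales elsewhere) then
dominates the Euclidean geometry, which matches both the published raw-unit
score equation and the distance-dominated separation of the published
clusters; a z-score option exists and its state is recorded on the model.

With k = 3, clusters are ranked by centroid 6MWT distance (ascending →
LPP, IPP, HPP; the ranking feature is configurable); other k get generic
ordered labels.  The performance score is ordinary least squares of the
numeric level code — LPP = 0, IPP = 1, HPP = 2, an inference from the
published per-level score means near 0/1/2 — on the seven raw-unit features.
The published equation's coefficients are available as
`reference_equation()`; its sign pattern (e.g. the small negative weight on
STS count) is taken as published, not rationalized.  Rank-deficient designs
are rejected, naming the collinear features.

## Synthetic data

`generate_trace` builds each test as baseline (9.81 m·s⁻² + Gaussian noise)
plus one raised-cosine pulse per motion event — width 0.6 s for STS/TUG
events and 0.25 s for steps; only peak locations and amplitudes matter
downstream, so the pulse shape is a free choice.  Event centers snap to the
sample grid by default so ground-truth peak values are exactly realized.
Gyroscope and horizontal channels carry zero-mean noise only; no feature
consumes them.  The TUG trace is a stand pulse, walking steps, and a sit
pulse; its ground-truth duration runs from stand-pulse start to sit-pulse
end.  Walker position in the gait model advances one step length per step
peak, which defines the shuttle-mark annotations.

`generate_cohort` draws each participant's features from per-group
independent Gaussians truncated at physiologic floors by resampling (never
clipping, to avoid point masses), rounds STS counts to integers, and draws
faller and Fried-phenotype labels from per-group probabilities.  The
packaged default recipe (`data/synthetic_cohort.yaml`) defines three latent
performance groups of 22/39/23 participants with feature means at the scale
reported for this population (6MWT 325/430/515 m, STS 8–12.4, TUG 5.7–10.5 s)
and label probabilities matching the published per-level faller and
phenotype percentages.

The within-group SDs describe spread *within* a performance cluster and are
deliberately tighter than whole-cohort SDs (e.g. 18 m for walk distance):
real performance groups produced by K-means partitioning have hard
boundaries, and emulating them with full overlapping Gaussians at marginal
SDs would destroy the very cluster structure the groups represent.  The
result is a somewhat idealized cohort — synthetic clusters are cleaner than
real data — so passing selection tests demonstrate that the pipeline
recovers a three-group structure where one exists, not that three groups
would emerge from any real population.  Other known simplifications: no
double support or turning dynamics in gait, no sensor drift or bias, feature
independence within groups (real parameters are correlated), and no
covariance between demographics and features.

## Problem sizes and tolerances

Test-suite and acceptance runs use: 100 seeded cohorts (n = 84) for cluster
selection; 100 seeded traces at noise SD 0.05 m·s⁻² for recovery (criteria:
step-duration mean within 1/26 s, TUG duration within 2 samples on average);
1000 null replicates per dispatch branch for type-I calibration (expected
0.05 within two binomial SEs); exhaustive bipartition at n = 12 as the
K-means oracle; and 26-step hand-built traces for shuttle arithmetic.
Synthetic walks in the recovery checks cover 150 m rather than a full
six-minute distance — the estimators see identical per-step structure either
way, and the shorter traces keep the suite fast.
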