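# Methods

`mzmarker` implements a Random-Forest biomarker screen for binary-class
feature tables derived from binned MALDI mass spectra, together with a
synthetic-cohort generator that reproduces the statistical structure the
screen assumes. This note records the models, the tunable parameters and
the design choices made where the procedure left the design open.

## The screening procedure

The input is an intensity matrix: one row per replicate spectrum
(typically five per patient), one column per nominal m/z channel, every
row tied to a patient and every patient to one of two classes (`case` =
weight gain, `control` = eutrophic).

1. **Normalization.** Each vector is divided by its own maximum
   intensity (base-peak scaling). All-zero rows are kept with a warning
   rather than dropped, since dropping would silently unbalance
   replicate counts per patient.
2. **Partitioning.** Patients — never individual replicate vectors —
   are split, stratified per class: `floor(0.2 n)` patients per class go
   to a held-out test partition, the rest form the fit partition. The
   fit partition is reshuffled into 10 train/validation experiments
   (train `floor(0.8 n)` per class, validation the remainder, so 82 fit
   patients split 65 + 17). Replicates always follow their patient, and
   `PartitionPlan.assert_no_leakage` re-checks the disjointness on every
   run.
3. **Dependency reduction.** Channels that are linear combinations of
   earlier channels are found by Gauss-Jordan elimination (ascending
   m/z, partial row pivoting) and grouped with the channels they depend
   on; each group keeps only its maximum-median member. See below.
4. **Forest-size grid search.** For each (vector length, tree count)
   cell, one forest per experiment is trained on the top-`length`
   channels of a baseline importance ranking; the tree count maximizing
   mean validation f1 (ties: accuracy, then fewer trees) is selected per
   length. Lengths the ranking loop visits but the grid does not are
   served by the nearest visited length — no parametric curve is fitted
   to the grid.
5. **Iterative importance ranking.** At each iteration one forest per
   experiment is trained on the surviving channels; channels are ranked
   by the mean of per-forest importances (each normalized to sum one;
   ties broken toward lower m/z) and the top
   `max(1, floor(0.9 x length))` survive, down to length 1. The
   f1-optimal iteration (ties toward the smaller length) defines the
   discriminant feature set.
6. **Marker criterion.** A channel j with positive-class empirical CDF
   P, negative-class CDF Q and positive-class median m_j is a marker
   when `delta_j = Q(m_j) - P(m_j) > beta` (default beta = 0.4,
   constrained to (0, 0.5)) and Q >= P at every observed value above
   m_j. Because empirical CDFs are step functions, checking dominance on
   the union of observed values above m_j is exact — no grid is
   involved.
7. **Diagnosis classifier and final test.** A forest is trained on all
   fit vectors restricted to the selected channels; held-out patients
   are scored by majority vote over their replicate predictions (even
   splits vote positive — a deliberate screening bias; a per-vector mode
   is available). Metrics: sensitivity Tp/(Tp+Fn), specificity
   Tn/(Tn+Fp), precision Tp/(Tp+Fp), f1 the harmonic mean of precision
   and sensitivity, and accuracy the *balanced* form
   (sensitivity+specificity)/2 — not (Tp+Tn)/total. Undefined metrics
   (zero denominators) are reported as NaN, never as a silent zero.

## Gauss-Jordan dependency reduction

Elimination proceeds column by column in ascending m/z with partial
(maximum-magnitude) row pivoting. A column whose entries after
elimination all fall at or below `pivot_tolerance x max|original
column|` (relative tolerance, default 1e-8) is dependent; its reduced
entries on the pivot rows are its coefficients over the pivot columns.
The reduced row-echelon form is canonical, so group contents are
invariant under row permutation.

Grouping convention (the procedure's one genuinely open point): every
pivot column keys a group; a dependent column joins the group of the
pivot carrying its largest absolute coefficient (ties toward lower m/z);
all-zero columns join the first pivot's group. Groups therefore
partition the channel set, the number of groups equals the numerical
column rank at the stated tolerance, and the representative re-selected
per group (maximum median across all vectors, ties toward lower m/z)
is what the learning stages see. Eliminated channels stay reachable
through `expand_to_group` so the annotation stage can match their ions.

Two practical notes. First, any matrix with more channels than rows
has column rank at most the row count, so on a 900 x 1,752 cohort the
elimination necessarily removes at least 852 channels regardless of
planted structure — the planted dependency groups are still recovered
exactly, because their members reduce against their generator alone.
Second, floating-point elimination accumulates roundoff over many pivot
steps; on large matrices the detected rank can fall somewhat below the
SVD numerical rank. On matrices up to 100 x 100 with well-separated
spectra the two agree exactly (this is tested); the reduction is a
screening device, not a rank certification.

By default only fit-partition rows feed the elimination, so held-out
patients cannot influence feature grouping. `reduction_rows="all"`
(and `marker_rows="all"`) reproduce the variant in which every vector
enters, which is how an archived-study reproduction would run it.

## The synthetic cohort generator

The generator emulates a two-group plasma MALDI study: by default
90 + 90 patients, 5 replicate spectra each, 1,752 integer m/z channels
starting at 250 (900 rows x 1,752 columns).

* **Baseline.** Log-normal intensities. The per-channel log-location
  declines linearly from 3.0 to 0.5 across the m/z range (plasma MALDI
  intensity decays with mass) with channel-to-channel roughness of
  sd 0.8. Log-space noise is the sum of a patient-level effect
  (sd 0.45, shared by a patient's replicates) and a replicate-level
  effect (sd 0.15), so replicates are correlated and patient-grouped
  partitioning is load-bearing. Both effects are truncated at 2 sd,
  reflecting the bounded dynamic range of detector intensities; with an
  unbounded log-normal tail, the single largest observed value of a
  channel falls in the negative class in a sizable fraction of cohorts,
  which no location shift can prevent and which would break the tail
  dominance that planted markers are supposed to satisfy.
* **Base peaks.** Four channels (m/z 656, 657, 672, 673) get a high
  (log-location 7.5), nearly constant (noise scaled by 0.05) intensity,
  emulating the dominant matrix-cluster peaks that carry the per-vector
  maximum; this keeps base-peak normalization stable, as it is in real
  spectra.
* **Markers.** Five channels (m/z 263, 278, 299, 308, 389 — the
  low-mass metabolite range) are pinned to a strong baseline
  (log-location 4.5). Each *case* patient expresses each marker channel
  independently with probability `marker_prevalence` (default 0.85);
  expressing patients have the planted shift added to all their
  replicate vectors. Controls never express. The planted shift is
  stated in units of the channel's *baseline scale*, defined as the
  empirical standard deviation of the channel's own unshifted values —
  a shift of 3 is exactly three baseline standard deviations of the
  data as generated. Partial prevalence is what makes single markers
  imperfect classifiers: a fully expressed three-sigma shift on a
  bounded log-normal baseline is individually almost separable at the
  patient level, and the f1 curve then plateaus at 1.0 for one- or
  two-channel sets, which no ranking procedure could distinguish. With
  85% prevalence the f1 optimum genuinely needs most of the planted
  panel, the CDF gap at the case median stays near 0.48 (> beta = 0.4),
  and the negative CDF dominates above the median.
* **Dependency groups.** Five groups, each a generator channel pinned
  to log-location 4.0 with four members that are exact scalar multiples
  (coefficients 0.8, 0.6, 0.45, 0.3), i.e. 20 planted dependent
  channels. Coefficients below one guarantee the generator is its
  group's maximum-median member and is what the reduction retains.
* **Cohort labels.** Subjects are drawn with heights ~ N(1.66, 0.09) m
  and class-conditional BMIs (controls ~ N(22.3, 2.0) clipped to the
  eutrophic band, cases ~ N(33.3, 6.0) clipped to >= 25.1); weight is
  derived and the class label re-derived through the WHO categories, so
  labels and anthropometrics are consistent by construction. WHO cut
  points are implemented as half-open intervals [18, 25), [25, 30),
  [30, 35), [35, 40), >= 40; below 18 is an explicit out-of-study
  sentinel, never a silent eutrophic.

Everything is deterministic given the spec's seed; identical spec +
seed is bit-identical. The generator writes the same delimited format
the loader reads, with a JSON ground-truth sidecar.

**What the generator does not emulate:** isotope envelopes and peak
shapes (channels are already-binned features), m/z-dependent
calibration drift, batch effects, missing replicates (available only
as uniform random row dropout), covariate structure such as age or
sex, and correlated marker expression (each marker is expressed
independently per patient). Passing the planted-recovery tests
therefore shows the machinery is sound under the assumed noise model,
not that the screen is robust to every artifact of real plasma data.

## Mass annotation

Monoisotopic masses are summed from most-abundant-isotope atomic
masses; positive-mode adduct deltas ([M+H]+, [M+Na]+, [M+K]+,
[M+NH4]+, [M+H-2H2O]+) include the loss of one electron per charge.
Theoretical adduct masses are reported at 4 decimals and ppm errors —
(measured - theoretical)/theoretical x 1e6 — are computed against the
4-decimal value, keeping match tables self-consistent at reporting
precision. Displayed ppm values are truncated toward zero at two
decimals (1.798 -> 1.79), the convention under which the reference
table's error column is reproduced exactly; internal comparisons use
full precision. Candidate matching accepts any (compound, adduct) pair
within a tolerance (default 2 ppm), sorted by absolute error.

Of the five reference plasma metabolites shipped in the local compound
table, four (dihydrobiopterin C9H13N5O3 + K, CMPF C12H16O5 + Na,
carboxy-LTB4 C20H30O6 + Na, argininosuccinate C10H18N4O6 + NH4)
reproduce their reference theoretical masses to all four decimals under
electron-inclusive arithmetic. The PGB2 entry does not: its reference
theoretical mass (299.2017 for the doubly dehydrated protonated ion)
differs by ~3.8 ppm from monoisotopic arithmetic on C20H30O4, so that
row is annotated only through its printed mass pair, not derived.

## Problem sizes and numerical choices

* Default pivot tolerance 1e-8 (relative); configurable.
* Grid searches in the worked analysis and the recovery tests use a
  deliberately small grid (lengths {16, 128}, trees {10, 20}): on the
  synthetic cohort validation f1 is flat in tree count well below the
  default grid's upper end, and the small grid keeps a 20-seed
  end-to-end study at the scale of a coffee break on one core.
* Recovery is assessed over 20 seeds (median of the number of planted
  markers inside the f1-optimal set; median held-out balanced
  accuracy); the null control uses 50 zero-shift seeds.
* Random-forest hyperparameters other than tree count stay at library
  defaults and are recorded in the run log implicitly via the tree
  count and seeds; all randomness flows from one master seed through
  named substreams (split, experiments, grid, ranking, final).
* SVM solver variants in the comparison harness: the quadratic
  programming (SMO-family) solver behind `SVC(kernel="linear")` and the
  coordinate-descent solver behind `LinearSVC` — two genuinely
  different optimization algorithms for the same linear decision
  function, mirroring a two-solver SVM comparison.

## Known limitations

* The marker criterion applies no multiple-testing control; it is a
  fixed threshold rule by design.
* The dominance clause is sensitive to single extreme values in small
  samples — one negative-class outlier above the positive maximum
  vetoes a channel. That is faithful to the definition; users screening
  noisy data may prefer to inspect `delta_j` directly.
* Gauss-Jordan rank detection on matrices with thousands of columns is
  subject to floating-point drift (see above).
* Importance-based ranking inherits Random-Forest biases (correlated
  channels share importance; the representative chosen by the
  reduction, not the ranking, decides which member of a dependency
  group is visible).
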