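# Methods

`braillemvpa` implements a cross-condition generalization analysis for
braille letter representations: decoding letter identity from neural
patterns either *within* the stimulated hand (sensitive to hand-dependent,
sensory codes plus hand-independent, perceptual codes) or *across* hands
(train on one hand, test on the other; sensitive to perceptual codes
only), with the entrywise difference isolating the sensory component.
Everything runs end to end on a synthetic-data generator that emulates the
statistical structure of the study design, so every stage is testable
without any neural recordings.

## Experimental design emulated

Eight braille letters (B, C, D, L, M, N, V, Z) are presented to the left
or right index finger — 16 conditions.  Two further letters (E, O) are
catch targets; catch trials are carried through containers but excluded
from every analysis.  One fMRI run holds 80 regular + 5 catch + 22 null
trials (107 total; 500-ms stimulus, 2500-ms ISI); one EEG session holds
2720 regular + 541 catch trials (170 repetitions per condition; 500-ms
stimulus; 500/1100-ms ISI after regular/catch trials).  The printed catch
spacing rule (one catch per 5–7 regular trials) is arithmetically
incompatible with those totals (it admits at most ~453 catch trials), so
the schedule generator treats totals as authoritative and spreads catch
and null trials as evenly as the counts allow, recording the realized gap
range and any soft violation in the schedule metadata.

## Generative model of the synthetic data

An epoch of channel data is

    x(t) = noise(t) + 1[t in sensory window] * a_s * P[hand, letter]
                    + 1[t in perceptual window] * a_p * Q[letter]

* `P` patterns are drawn independently per (hand, letter): a code that
  never generalizes across hands.
* `Q` patterns are shared across hands and shaped to a planted letter
  geometry: the geometry matrix is treated as squared Euclidean
  dissimilarity, embedded by classical MDS (negative eigenvalues clipped)
  and rotated into channel space by a random orthonormal basis, so pairwise
  `Q` distances reproduce the geometry exactly.  The default geometry is
  the pin-overlap (Hamming) distance between the 6-dot braille codes of
  the eight letters, which *is* a squared Euclidean metric on binary
  vectors, so the embedding is exact.
* Noise is Gaussian, spatially correlated with an exponential falloff over
  sensor distance (length scale 0.05 m on a standard 10-10 montage, 63
  channels by default), temporally white by default; an AR(1) knob exists
  for stress tests because real EEG is autocorrelated.  Temporal whiteness
  keeps the null calibration exact: with no planted code, decoding is
  unbiased at 50% at every time point.

Defaults place the sensory onset at 80 ms and the perceptual onset at
180 ms (each lasting 420 ms), with amplitudes `a_s = 0.25`, `a_p = 0.2`
relative to unit per-channel noise SD — values chosen once so that
desk-scale cohorts produce decoding accuracies between chance and ceiling,
the regime the analyses are designed for.  ROI pattern generators mix the
two codes per region (`mix=1` purely hand-dependent, `mix=0` purely
hand-independent); the default ROI set gives tactile regions `mix=1`,
sighted-reading regions `mix=0`, and LOC 0.5, emulating the expected
sensory/perceptual topography with LOC as the region carrying both.
Behavioral ratings are a linear monotone rescaling of the latent geometry
onto the 1–7 scale plus Gaussian noise, rounded and clipped.

What the generator does **not** emulate: biophysical forward models
(leadfields, hemodynamics), eye/muscle artifacts, inter-subject anatomical
variability, or session-level drifts.  Passing tests therefore demonstrate
that the analysis code recovers planted structure under its own stated
assumptions, not that it would behave identically on real recordings.

One consequence of the fixed per-subject `P` draws is worth noting: at
high sensory amplitude, across-hand decoding during the sensory-only
window is not noise-like at the single-subject level — each subject
carries a persistent pseudo-bias (the trained discriminant has a fixed,
random alignment with the other hand's patterns) that only averages to
chance across condition pairs and subjects.  Group analyses therefore need
enough pairs and subjects for this bias to cancel, which is why the
dissociation validation below uses the full 8-letter set and cohorts of
15.

## Preprocessing

Baseline correction subtracts the per-trial, per-channel mean of the
100-ms prestimulus window.  Multivariate noise normalization whitens
channel patterns by Σ^(-1/2), with Σ estimated within condition per time
point (demeaned within condition), averaged over time points and
conditions, and regularized by analytic Ledoit–Wolf shrinkage toward
scaled identity (via scikit-learn); fixed shrinkage intensities and the
unregularized estimator are available.  Normalization is applied once to
the full epoch set before cross-validation, mirroring its place as a
preprocessing step in the source procedure; the covariance is estimated
without reference to letter labels beyond within-condition demeaning, so
train/test leakage through the whitener is second-order.  An alternative
per-fold estimation was considered and rejected: with 4 pseudo-trials per
class per fold the fold-wise covariance is ill-conditioned, and the
whitener would change between folds, conflating preprocessing with the
classifier.

Pseudo-trial binning raises SNR before classification: trials of one
condition are randomly assigned to disjoint bins of size
floor(n/5) (34 for 170 repetitions, 68 for 340) and averaged, yielding
five pseudo-trials; leftovers are dropped, membership is recorded for
audit.  fMRI run patterns are binned the same way into five pseudo-runs
(bins of 2 for 10 runs, 5 for 25).

## Decoding

For every letter pair, a soft-margin linear C-SVC (C = 1, the customary
library default; no feature scaling beyond noise normalization) is trained
on four pseudo-trials per letter and tested on the held-out fifth,
five-fold leave-one-pseudo-trial-out.  Within-hand uses one hand for both
partitions (28 pairs × 2 hands for 8 letters); across-hand draws the
held-out fold from the other hand, using the same fold skeleton, and
averages the two train→test directions.  Time-resolved decoding repeats
the whole procedure per sample and over binning iterations (100 in the
reference procedure) with fresh random bin assignments, averaging over
pairs, folds, iterations, and hands/directions.  Accuracy is percent
correct against a 50% chance level; matrices are symmetric with an
undefined diagonal.

Because one run solves up to millions of 8-sample SVMs, the dual problems
are solved by a vectorized SMO (maximal-violating-pair selection, exact
two-variable updates, gap tolerance 1e-4) batched over problems — the
same algorithm and stopping rule as libsvm-style solvers, roughly 60×
faster than per-problem library calls at this problem size.  The test
suite verifies agreement with `sklearn.svm.SVC` problem-by-problem: the
(unique) weight vector and optimal primal objective match to solver
tolerance; the intercept is compared through predictions because it is
non-unique when no free support vector exists, in which case both engines
return points of the same optimal interval.

## Searchlights

Volumetric: for each in-mask voxel, the decoding scheme runs on the
voxels inside a sphere of radius 4 voxel units (inclusive, center
included), truncated at grid and mask boundaries; the accuracy is stored
at the center.  Sensor-space: for each channel, decoding uses its k = 4
nearest channels by Euclidean montage distance — read literally as
*surrounding*, i.e. excluding the center channel itself; an
`include_center` flag provides the inclusive variant.  Per-sample
accuracies are mean-pooled into 10-ms bins *after* decoding (not by
resampling the data first).

## RSA

Pairwise decoding accuracy is interpreted as dissimilarity, arranged into
8×8 RDMs (hands/directions already averaged, diagonal undefined), as are
participant-averaged ratings.  RDMs are compared by Spearman's R over the
28 lower-triangle entries with average-rank tie handling; zero-variance
triangles yield an undefined (NaN) correlation.  The group pipeline keeps
neural RDMs subject-specific against one participant-averaged behavioral
RDM, producing one R per subject per ROI or time point.  The time-resolved
"sensory" RSA curve defaults to the within-hand RDM (not the
within-minus-across difference); both are available since the choice is
genuinely open.

## Statistics

Group significance per time point/ROI: one-tailed Wilcoxon signed-rank
tests against chance (50% for accuracies, 0 for difference scores and
correlations; a two-tailed flag exists), corrected across tests by
Benjamini–Hochberg FDR at q = 0.05 (statsmodels).  Zeros follow the Pratt
policy (ranked, then discarded), ties get average ranks; the exact
permutation null (dynamic program over doubled ranks, identical to 2^n
sign enumeration) is used up to n = 25 non-zero differences and a
continuity-corrected normal approximation above.  A fully degenerate
sample (all values at chance) reports p = 1.

Onset latency is the earliest post-stimulus time beginning k consecutive
FDR-significant points (k = 50 at 1-ms resolution; scaled proportionally
on coarser grids, e.g. k = 5 at 10 ms).  Confidence intervals come from
resampling the participant pool with replacement (1000 resamples in the
reference procedure), recomputing the Wilcoxon + FDR trace and onset per
resample — recomputing rather than reusing the original significance mask,
the statistically coherent choice — and taking 2.5/97.5 percentiles over
defined onsets; undefined resamples are excluded and counted.  Inside the
bootstrap, duplicated subjects create rank ties; the vectorized inner loop
scores tie-averaged statistics against the no-tie exact reference
distribution (columns containing exact zeros fall back to the per-column
exact test), a documented approximation that keeps 1000-resample runs in
seconds.  Latency differences are bootstrapped pairwise (same resampled
subjects in both conditions); the one-tailed p is the proportion of
resampled differences ≤ 0.  Percentile (not BCa) intervals are used for
reproducibility with 1000 resamples.

## Validation scales

Unit and property tests run on reduced designs (2–4 letters, 8–32
channels, 100-Hz sampling).  The package-level validations use:

* **Null calibration** — 20 noise-only subjects at the full printed
  session composition, 100 Hz over (-100, 390) ms (50 points), 10 binning
  iterations: grand-average within-hand accuracy within 50 ± 1%; plus 50
  smaller null cohorts (11 subjects, 4 letters, 40 repetitions, one
  iteration) for the onset false-positive rate of the k-consecutive
  criterion (k = 5 at 10-ms resolution).
* **Dissociation recovery** — 50 cohorts of 15 subjects, 8 letters, 20
  repetitions, 32 channels, sensory/perceptual amplitudes 0.4/0.6,
  onsets planted at 80/180 ms: recovered group onsets within ±2 bins,
  within-hand before across-hand, paired-bootstrap latency-difference
  p < 0.05.  The cohort size and amplitudes were chosen (before freezing
  the test) so the across-hand pseudo-bias described above cancels
  reliably; smaller cohorts or stronger sensory amplitudes leave a few
  percent of cohorts with inconclusive latency tests.
* **Oracle equivalence** — exact Wilcoxon vs full sign enumeration,
  BH vs the textbook step-up rule, onset detection vs a sliding-window
  scan, sphere/k-NN neighborhoods vs brute-force distance scans.
* **RSA recovery** — noiseless ratings recover the planted geometry at
  R = 1 exactly; decoding-derived across-hand RDMs reach R ≈ 0.97 at
  moderate SNR (exact R = 1 is a ceiling-free, infinite-data limit:
  accuracy saturation and tie-structure jitter keep finite runs slightly
  below it); R is invariant under monotone transforms by construction.

## Numerical choices and degenerate inputs

Decision ties at the SVM boundary (decision value exactly 0) count as the
negative class, deterministically.  Baseline windows are half-open
[start, stop).  Whitening rejects singular covariances when shrinkage is
disabled.  Binning requires at least one full bin; conditions unable to
fill the requested pseudo-trial count are rejected rather than padded.
RDM construction rejects missing pairs.  `fdr_bh` requires p-values in
(0, 1]; group traces clip exact-zero approximations to the smallest
positive float.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (per-subject children in cohort
order, split again per stage), so every pipeline stage is reproducible
bit-for-bit; HDF5 outputs disable object timestamps and the volumetric
searchlight map is written as uncompressed NIfTI so manifest hashes are
rerun-stable.

## Known limitations

* The generator targets statistical structure, not realism; absolute
  accuracies and latencies are not comparable to real recordings, only
  the qualitative ordering of effects is.
* SPM-style voxel-level FWE cluster inference is out of scope; volumetric
  maps get a cluster-forming threshold report only.
* The per-fold noise-normalization variant is not implemented (see
  Preprocessing); sensitivity to this choice on real data is untested.
* fMRI pseudo-run binning defaults to a single randomization (the
  reference procedure names none); a knob exposes re-randomization.
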