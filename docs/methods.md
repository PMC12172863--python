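# Methods

`sefmap` delineates the cortical area that responds to median-nerve
stimulation from MEG somatosensory evoked fields (SEFs).  Because clinical
MEG/MRI data cannot be shipped, the package pairs the analysis pipeline
with a fully synthetic workbench that emulates the acquisition it was
designed for; every reported number is computed by running the pipeline on
that workbench.

## The delineation pipeline

Given an evoked response **b**(t) over 306 channels, the pipeline is:

1. **sLORETA.** With lead field *L* (channels × sources), assumed white
   noise covariance σ²*I* and whitened gain *G* = *L*/σ, the minimum-norm
   kernel is

       W = Gᵀ (G Gᵀ + λ² · tr(G Gᵀ)/n_chan · I)⁻¹

   and the standardized estimate at source *j* is (W b)_j / √(W L)_jj.
   Standardization by the resolution-matrix diagonal gives zero
   localization error for noiseless point sources; the suite verifies
   100/100 exact hits on the ico-3 workbench at λ² = 10⁻⁶.  The default
   λ² = 1/9 corresponds to a nominal amplitude SNR of 3; σ is estimated as
   the median per-channel standard deviation over the evoked baseline.

2. **Anatomical spatial filter.** Each source's time course is replaced by
   the mean over the sources within a 5 mm Euclidean ball that carry the
   same parcellation label (self included).  Averaging (rather than a
   median or a mask) was chosen as the simplest linear denoiser; the
   radius and the label-respect flag are configuration parameters.

3. **Windowed SVD.** The source × time matrix restricted to the closed
   [15, 60] ms post-stimulus window is factored X = U Σ Vᵀ.  The first
   left singular vector u₁ is the dominant spatial mode, the first right
   singular vector v₁ the dominant temporal mode; Σ₁²/ΣΣᵢ² is the variance
   it explains.  SVD signs are fixed by making the largest-|entry| of each
   temporal mode positive, so loadings are reproducible.

4. **Thresholding.** The activation region is the set of sources with
   |u₁| ≥ 0.8 · max|u₁|.  The fraction-of-max reading (rather than a count
   percentile) is the default because it makes the region monotonically
   more focal as the threshold rises; a `quantile` semantics is also
   implemented.  The region's peak time is the time of max |v₁|; its
   centroid is the mean member position, labelled via the nearest vertex.

The pipeline is deterministic and invariant to positive rescaling and to
sign flips of the evoked data.

## The synthetic workbench

* **Cortex.** Two mirror-image icospheres (10·4^s + 2 vertices each),
  radius 35 mm, centres ±39 mm along x, radially perturbed by a smooth
  two-harmonic angular sinusoid of amplitude 5 mm standing in for gyri and
  sulci.  One source per vertex, oriented along the area-weighted outward
  surface normal.  The working resolutions are ico-3 (1,284 sources) for
  fast tests and ico-4 (5,124) for cohort runs; ico-5 reproduces the
  clinical 10,242 per hemisphere / 20,484 total.
* **Parcellation.** Four contiguous angular bands per hemisphere —
  precentral gyrus, central sulcus, postcentral gyrus, postcentral sulcus,
  anterior → posterior — each 0.19 rad wide in the band coordinate
  ψ = atan2(−y, z), restricted to lateral-pole cosines in [−0.75, 0.75];
  everything else is `other`.  The four labels cover ≈ 9.2 % of sources,
  matching the ≈ 9 % chance level of random anatomical agreement.
* **Forward model.** Closed-form field of a current dipole in a spherical
  conductor (head radius 85 mm, centred at the origin).  This replaces a
  patient-specific BEM; it is exact for the spherical geometry and
  standard for MEG simulation.  The helmet is a Fibonacci lattice of 102
  upper-hemisphere sites at 110 mm, each with one radial magnetometer and
  two orthogonal planar gradiometers (difference of two point field
  evaluations 17 mm apart, divided by the baseline).  Radial sources are
  magnetically silent in a spherical conductor, so orientations within 5°
  of head-centre radial are tilted to exactly 5° off radial before the
  lead field is built; without this the sLORETA standardization would be
  ill-posed.
* **Evoked activity.** A contiguous patch (default 50 sources) seeded
  uniformly in the postcentral gyrus ∪ central sulcus contralateral to the
  stimulated side and grown breadth-first within the sensorimotor labels —
  the simulated activation *is* somatosensory cortex, so it never leaks
  into `other` tissue.  Per-source peak moments taper with distance from
  the seed and sum to 50 nA·m (clinically reported moments span roughly
  20–135 nA·m).  The waveform is a causal pair of Gaussian deflections at
  20 ms (width 3 ms) and 35 ms (width 6 ms), unit peak.
* **Epochs.** 1 kHz sampling, half-open window [−50, 250) ms → exactly
  300 samples with the stimulus at sample 50; per-patient epoch counts
  drawn from Normal(197, 31) truncated to [160, 230].  Noise is white
  Gaussian, identical variance on every channel, scaled so that the
  noiseless gradiometer peak RMS divided by the expected residual noise in
  the average (σ/√n) equals the requested evoked SNR (default 5).

What the generator does **not** emulate: correlated brain noise,
cardiac/ocular artifacts, line noise, head movement, filtering artifacts,
realistic conductor geometry, or folded-cortex lead-field complexity.
Passing tests therefore demonstrate the pipeline's correctness and its
statistical behaviour under controlled conditions, not clinical
performance on real recordings.

## Evaluation machinery

* **Dipole comparator.** Equivalent current dipoles are grid-searched over
  the source positions with a free 3-vector moment solved by least squares
  at every sample of the 20 ± 5 ms (P20m), 40 ± 5 ms (P40m) and
  max-gradiometer-RMS (PMaxm) windows; the (sample, position) pair with the
  highest GOF = 100·(1 − ‖b−b̂‖²/‖b‖²) wins.  In a spherical conductor the
  radial moment component is silent, making the 3×3 normal matrix exactly
  rank-2; the moment is solved with a pseudo-inverse, i.e. in the
  observable tangential subspace.  Dipoles farther than 9 mm (inclusive)
  from any contralateral sensorimotor source are rejected.  No nonlinear
  refinement is performed; the comparator stays deterministic.
* **Metrics.** Atlas overlap (percentage of region members carrying a
  sensorimotor label, either hemisphere), overlap with a 3 cm³ sphere
  (radius (3V/4π)^⅓ ≈ 8.95 mm) centred on each accepted dipole, centroid
  distance, and nearest-vertex anatomical projection.
* **Permutation null.** Size-matched contiguous patches grown from seed
  vertices drawn uniformly over all sources (10,000 draws by default),
  summarized by the median; `beats_chance` is a strict comparison of the
  observed metric against that median.  Null patches are contiguous, not
  scattered, so the null preserves the spatial granularity of a real
  region.  The mean null atlas overlap reproduces the ROI source fraction
  (≈ 9.2 %) within Monte-Carlo error.
* **Calibration caveat.** When the observed region is itself a random
  patch, `beats_chance` fires with probability ½ only for metrics whose
  null is continuous.  Atlas overlap has a large atom at 0 (most random
  patches miss the 9 % ROI entirely), so the null median is 0 and the
  strict comparison fires with probability ≈ 0.31 — a conservative bias
  inherent to median-plus-strict-inequality on discrete metrics, not an
  implementation artifact.  The calibration test therefore uses a
  continuous geometric metric (patch-centroid distance to a fixed
  reference point), for which the measured rate is ≈ 0.48.
* **Cohort statistics.** Binomial significance of the per-patient success
  count in two modes: a conventional one-sided tail P(X ≥ k), and an
  "all-success mass" p₀ⁿ that reproduces the headline values printed in
  clinical reports of this analysis (0.05⁵⁸ ≈ 3.5×10⁻⁷⁶, 0.05⁵⁰ ≈
  8.8×10⁻⁶⁶) even when successes are 57/58 or 49/50; both are reported and
  the discrepancy is deliberate.  Wilcoxon signed-rank is exact (sign-flip
  enumeration via a subset-sum table, midranks doubled to stay integral)
  up to 25 nonzero differences, normal approximation with tie correction
  beyond.  The anatomical-location contingency table (5 categories ×
  methods) is tested with Pearson χ², zero-count categories dropped.  No
  multiple-testing correction is applied across dipole kinds by default.

## Numerical choices and tie-breaks

* Baseline interval [−50, 0) ms, half-open (the stimulus sample is
  excluded); analysis windows [15, 60] ms and dipole windows closed.
* Argmax ties (RMS peak, temporal-mode peak) resolve to the earliest
  sample; nearest-vertex ties to the lowest index; patch-growth ties
  within a breadth-first ring to ascending distance from the seed, then
  ascending vertex id.
* All randomness flows through `numpy.random.default_rng` seeds;
  per-patient sub-seeds derive from a master seed via `SeedSequence`.

## Problem sizes used in the shipped checks

Source-space counts are verified at ico-5; exact-localization and oracle
checks run on ico-3; the cohort recovery, permutation-null expectation
(10,000 draws) and calibration (200 replicates × 201-draw nulls) run on
ico-4 with 20 patients at SNR 5.  These sizes were chosen so the whole
evaluation reruns from scratch in about a minute on one core while keeping
every Monte-Carlo tolerance meaningful.

## Known limitations

* The spherical conductor makes near-radial sources weakly visible at
  best; the 5° orientation tilt is a pragmatic floor, not physiology.
* The parcellation is an angular-band stand-in: label geometry is exact
  and configurable, but it has no per-subject anatomical variability.
* Atlas-overlap `beats_chance` is conservative (see the calibration
  caveat) — a region that overlaps the ROI at all beats a zero median.
* The Wilcoxon between-task comparison pairs two independent synthetic
  cohorts truncated to a common length; it mirrors the clinical
  between-task test in form only.
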