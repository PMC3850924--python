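# Methods

## The prediction model

The classifier operates on the amplitude distribution of reflex-window
EMG. Its pipeline, per training configuration:

1. **Range fitting.** All reflex-window amplitudes of all training
   signals at the selected sites are pooled; *Rg* = (min, max), *μ* and
   *σ* (population convention, ddof = 0) are computed, and the histogram
   range is frozen to *rg* = (*μ−σ*, *μ+σ*). The restriction is a feature
   -selection device: raw EMG has a wide range whose extreme bins carry
   ≈1/1000 of the mass, so a histogram over *rg* needs only 30 bins.
   The range is fitted **once per training configuration** and reused for
   every validation/test query, so no query information leaks into the
   feature definition.
2. **Features.** Each signal's window is binned into 30 uniform bins over
   *rg*: bin index ⌊(x − rg.lo)/width⌋, samples below *rg* clipped into
   bin 0 and samples at or above its upper edge into bin 29, counts
   normalised to probabilities. Clipping (rather than discarding)
   conserves the sample count and keeps every histogram normalised; a
   discard-and-renormalise mode exists behind `clip=False`.
   Amplitudes are signed by default — the raw distribution is the
   feature; a `rectify` option histograms |amplitude| instead for users
   whose acquisition chain rectifies. Likewise the pre-stimulation
   quiescence check (RMS of the 200 ms before the stimulus against a
   limit) only *flags* traces; exclusion is a separate pipeline option
   (`prestim_rms_limit`), since no universal exclusion rule exists.
3. **Profiles.** A training subject is the bin-wise mean of its signal
   histograms over the selected sites (4 signals per site). Query signals
   are *not* averaged: each signal is assessed individually against the
   averaged training profiles. This asymmetry is the scheme's defining
   structure — per-signal votes give the confidence scale.
4. **kNN vote.** Euclidean distance over the 30 probability coordinates;
   the k = 5 nearest training subjects vote. Per-signal patient
   probability l_qj^p = (#patient neighbours)/k · 100. Distance ties at
   the k-th neighbour are broken by training subject id (lexicographic),
   making predictions independent of profile storage order.
5. **Aggregation.** l_q^p is the mean of l_qj^p over all assessed signals
   (all repetitions of all selected sites pooled into one vote — no
   per-site hierarchy); the subject is a patient iff l_q^p ≥ 50%. The
   "≥" realises the clinical tie-break: an exactly split vote is called
   patient, because a missed patient is costlier than a false alarm.

## Validation protocol

Data is split 70/15/15 into TR/V/TE with exact balance over the eight
group × gender × age-class cells (age classes split at 50 years, with 50
itself in the elder class). Within each cell the requested fractions are
rounded by the largest-remainder method — for the canonical 280-subject
cohort (35 per cell) this yields 25/5/5 per cell, i.e. 200/40/40 — and a
configuration in which a positive fraction would receive zero subjects in
some cell is rejected.

Model selection then uses V only:

* **Site evaluation.** Each site separately, across per-group training
  sizes {12, 24, 32, 48, 60, 80, 100} with 10 random balanced subsets per
  size (one when the size equals the full TR; each subset takes exactly a
  quarter of its subjects from every stratum, hence sizes divisible by 4).
  A site's *best performance* is the maximum over sizes of its mean rate;
  sites below 75% are discarded.
* **Site combination.** All non-empty subsets of the retained sites are
  evaluated on the same grid. The winner maximises best performance; ties
  go to the higher grid-wide mean rate, then the smaller set.
* **Subset selection.** For the winning site set, the candidate with the
  highest r wins; ties prefer the smaller |r_h − r_p|, then the smaller
  draw index, then the smaller size. r is never traded for balance —
  balance only breaks ties — but any candidate with |r_h − r_p| > 30
  points is flagged in the report for human review.
* **Final test.** The selected configuration is retrained and evaluated
  on TE exactly once. Every evaluation checks training/evaluation
  disjointness and records itself in an audit log; a full run asserts the
  log contains exactly one TE access, as the last entry.

## Synthetic cohorts

The generator emulates the statistical structure the classifier consumes,
not the biophysics of motor units:

* A trace is 1000 ms of zero-mean Gaussian baseline noise
  (SD 0.05 a.u.) at 2000 Hz including 200 ms pre-stimulation; with
  probability `burst_probability` (default 1.0 — recordings are made at
  1.5× the pain threshold precisely so a reflex occurs on most
  stimulations) a reflex burst is added inside the 60–180 ms window:
  white noise scaled by a smooth Hann envelope and by the subject's
  *reflex gain*.
* The gain is drawn once per subject × site from N(m, τ²), τ = 0.15,
  floored just above zero, and shared by the site's four repetitions —
  the repetitions are correlated realisations of one subject, which is
  what profile averaging exploits. Healthy subjects have m = 1 at every
  site; patients have m = 1 + `effect_size`·τ at the informative sites
  (default {3, 9, 10}) and m = 1 elsewhere. `effect_size` is therefore
  the standardized between-subject difference (Cohen's d) in reflex-window
  amplitude dispersion, and because the baseline noise floor (0.05) is
  small relative to the burst RMS, the measured d of per-subject window
  RMS tracks the knob closely (within a few percent at large n; the test
  asserts 10% at 200 subjects/group, where sampling error of d no longer
  dominates). A `mode="dispersion"` variant widens the patient gain
  distribution instead of shifting it, for sensitivity analyses.
* Ages are uniform within the age class (20–49 / 50–80), cells are
  exactly balanced, and all randomness flows from a single seed recorded
  in the spec, so cohorts are reproducible.
* A per-subject scalar biomarker (log-normal, patients shifted by 0.3 log
  units at SD 0.5) provides heavily overlapping class distributions for
  the percentile-cutoff baseline; the defaults make a p95 cut keep nearly
  all healthy subjects while missing most patients.

What passing tests on these cohorts shows — and what it does not: the
pipeline recovers class structure of the kind it assumes (a scale/dispersion
difference in window amplitudes localised at specific sites) and is
correctly calibrated when no structure exists. Real EMG has
non-Gaussian bursts, habituation across repetitions, age- and
gender-dependent reflex thresholds and inter-site correlations, none of
which the generator reproduces; performance numbers on synthetic cohorts
therefore validate the machinery, not clinical accuracy.

## Study sizes and statistical design of the checks

* The *null calibration* check runs 20 cohorts at effect 0 (one site,
  80 training / 40 test subjects each) and requires the pooled accuracy
  of the 800 predictions to stay inside the 95% binomial band around 50%
  (±3.5 points). Given the model, test predictions are independent and
  label-independent, so the band is exact (slightly conservative).
* The *signal recovery* check runs the full protocol (ten sites, all
  seven training sizes, ten subsets) on twenty 280-subject cohorts with
  informative sites {9, 10}. The effect size for this study is 3.0. The
  choice is dictated by the decision geometry: a subject-level
  standardized separation d gives an intrinsic (Bayes) single-site
  accuracy of Φ(d/2) — about 84% at d = 2, which sits too close to the
  75% site-retention threshold for a 40-subject validation set to clear
  reliably, no matter the classifier. At d = 3 the single-site ceiling is
  ≈93% and two-site ≈98%, so retention of both informative sites and
  ≥90% mean test accuracy are properties of the method rather than of
  seed luck. The check requires both sites retained in ≥18/20 seeds and
  mean test accuracy ≥ 90%.
* The kNN path is verified against an exhaustive sort of all distances
  (200 random instances up to 200 profiles) and against
  scikit-learn's `NearestNeighbors` on tie-free instances.

## Numerical choices

* Population σ (ddof = 0) for the pooled range; at pooled-sample sizes of
  ~10⁵ the distinction from the sample convention is negligible, but one
  convention must be fixed for reproducibility.
* Samples exactly on an interior bin edge go to the right bin; the range
  maximum is clipped into the last bin. Degenerate ranges (σ = 0) are
  rejected rather than silently widened.
* Histograms store exact `counts/total` fractions; profile averaging does
  not renormalise (the mean of normalised vectors is normalised), so
  identical inputs average to themselves bit-for-bit.
* Empirical percentiles use the linear-interpolation (type-7) convention
  of `numpy.percentile`; baseline queries are labelled patient on strict
  inequality with the critical value.
* Prediction rates are exact rationals (`fractions.Fraction`) rendered as
  floats; selection rules compare them lexicographically, so ties are
  decided exactly, not within a float tolerance.
* Trace amplitudes are serialized with 17 significant digits, which
  round-trips IEEE-754 doubles exactly; cohort equality after a
  write/load cycle is bit-exact.

## Known limitations

* Histograms are fixed-bin; adaptive histograms or kernel density
  estimates are out of scope, as are alternative features (RMS, latency,
  spectral moments) and classifiers.
* k and the bin count are configuration values (defaults 5 and 30); the
  leave-one-out selection that motivated those defaults is not re-run
  automatically.
* The splitter rejects demographically unbalanced cohorts instead of
  rebalancing them; the model's validation logic assumes balance.
* The scalar biomarker baseline uses a generic synthetic value; computing
  real reflex-receptive-field areas is out of scope.
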