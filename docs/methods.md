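# Methods

## Problem and pipeline

`megconn` implements a resting-state connectivity analysis for source-space
MEG in a two-group child cohort (e.g. very-low-birth-weight vs full-term
children): continuous 90-region time series are cleaned, epoched and
quality-controlled; each epoch is band-passed into canonical frequency bands
and converted to an analytic signal; phase synchronisation between every
region pair is estimated with the weighted phase lag index (wPLI); and
group contrasts or continuous associations (IQ-like and behaviour scores,
postnatal nutrient intakes) are tested at the network level with the
network-based statistic (NBS), a permutation test that controls the
family-wise error rate over connected supra-threshold subnetworks.

Because raw clinical MEG cohorts of this kind cannot be shared, the package
pairs the analysis with a synthetic cohort generator that plants known
coupling structure; every stage of the pipeline is validated against that
ground truth.

## Preprocessing

* **Broadband cleaning** (`preclean`): spectrum-domain notches at 60 and
  120 Hz (DFT bins within ±1 Hz zeroed; zero-phase and free of IIR ringing)
  followed by a fourth-order two-pass (zero-phase) Butterworth band-pass at
  1–150 Hz. If the sampling rate cannot support the 150 Hz edge, the edge is
  clipped to 0.45×rate with a warning.
* **Epoching**: non-overlapping 10 s epochs; the trailing remainder is
  discarded.
* **Artefact exclusion**: epochs with head-motion deviation strictly greater
  than 5 mm from the recording median, or any sample strictly beyond an
  absolute amplitude limit, are dropped. Boundary values (exactly 5 mm,
  exactly at the amplitude limit) are retained, since only values *beyond*
  the limits are artefactual by definition. The amplitude limit defaults to
  2 units to match sensor-style ±2 pT screening, but is configurable (and
  can be disabled) for source-space data whose simulation units are not
  comparable to sensor fields; the packaged demo config uses 10 simulation
  units. Missing motion values count as exclusions and are logged.
* **Inclusion rule**: a subject enters analysis only with ≥ 6 surviving
  epochs (1 min of data).
* **Band-limited analytic signal** (`band_analytic`): per band, a windowed-
  sinc (Hamming) FIR applied twice ('same'-mode convolution with the odd
  symmetric kernel is exactly zero-phase, two passes give the squared
  magnitude response), then the Hilbert transform. The tap count is the
  larger of 3 cycles of the band's low edge and what yields a one-pass
  transition width of about half of min(low edge, band width), floored at
  1 Hz — narrow low bands (theta) therefore get long filters (661 taps at
  300 Hz) and >90 % of filtered white-noise power falls inside the band,
  while high bands (gamma 65–80 Hz) get kernels short enough to reach full
  passband gain. A number of edge samples equal to the filter order is
  trimmed from both ends of every epoch to keep filter/Hilbert transients
  out of the connectivity estimate; epochs must be at least 3× the filter
  order long.

Frequency bands: theta 4–7, alpha 8–14, beta 15–29, low gamma 30–55, gamma
65–80 Hz. (Some sources quote alpha as 8–12 Hz in summaries; the 8–14 Hz
definition used in the originating methods is adopted as canonical.)

## wPLI estimator

For analytic signals z_i, z_j, with cross-spectral samples
X_t = z_i(t)·conj(z_j(t)):

    wPLI = |Σ_t Im X_t| / Σ_t |Im X_t|  ∈ [0, 1]

Phase differences are weighted by the magnitude of the imaginary
cross-spectrum, so instantaneous (zero-lag) mixing — volume conduction /
field spread — contributes nothing. Choices:

* the standard wPLI is used, not the debiased wPLI² (which can be negative
  and would break the documented 0–1 range);
* wPLI is computed within each 10 s epoch over time samples, then averaged
  arithmetically across epochs (pooling samples before the ratio is
  deliberately rejected);
* a zero denominator (pure zero-lag or silent input) defines wPLI = 0 ("no
  phase locking") and is logged; numerically the cutoff is a 1e-12 relative
  tolerance against the cross-spectrum magnitude, because floating-point
  rounding leaves ~1e-16 imaginary residue even for identical signals;
* Im X_t is evaluated with explicit real arithmetic so that swapping the two
  signals is an exact negation and wPLI is exactly symmetric;
* the matrix diagonal is fixed at 0 and excluded from all statistics.

The ratio estimator is positively biased at finite sample size (independent
signals give small positive wPLI, shrinking with epoch length); the tests
characterise this rather than hide it, and all group inference is on
*differences* across subjects, which the common bias cancels.

## Network-based statistic

1. Each unique edge (upper triangle; 4005 edges for 90 regions) is z-scored
   across participants (sample SD, ddof = 1). Zero-variance edges are set to
   zero and flagged. The z-scoring axis is per edge across participants —
   the only orientation compatible with an edge-wise GLM.
2. At every edge, ordinary least squares of the z-scored wPLI on
   [intercept, predictor, covariates] (default covariates: age at scan and
   sex; categorical covariates are dummy-coded dropping the first level).
   The t statistic of the predictor is the edge statistic. In group-contrast
   mode the predictor is a binary indicator (the coded level is
   configurable), making the GLM a covariate-adjusted two-sample t-test;
   with no covariates it reproduces the classical pooled-variance two-sample
   t exactly. Rows with missing values are dropped listwise with logged
   counts. Rank-deficient designs are rejected naming the columns.
3. The primary threshold is the (1 − f) quantile of the *observed*
   direction-signed t values, with f the target edge fraction (default 0.01:
   40 of 4005 edges for 90 regions; at least one edge is always kept, and
   ties at the cut are all retained and logged). The threshold is a fixed
   numeric t value: re-deriving the quantile inside each permutation would
   guarantee supra-threshold edges in every permutation by construction, so
   the same numeric threshold is re-applied unchanged in the null.
4. Connected components of the supra-threshold graph are the candidate
   networks; the component statistic is its extent (edge count), matching
   how such networks are conventionally reported (edges, nodes).
5. Null distribution: group labels are permuted directly in a pure group
   contrast; with covariates present, or for continuous predictors,
   Freedman–Lane permutation is used (permute the residuals of the reduced,
   covariates-only model, add back its fitted values, refit the full model) —
   plain label permutation is not exchangeable under nuisance covariates.
   When the number of distinct group assignments is no larger than the
   requested permutation count, the null is enumerated exhaustively
   (excluding the observed assignment). Each observed component receives
   p_corr = (1 + #{null max extent ≥ extent}) / (1 + n_permutations), so the
   observed statistic is part of its own null and p ≥ 1/(1+N). One-sided
   tests are run separately per direction. Bands are tested independently
   without cross-band correction.

Permutation defaults: 5000 permutations, α = 0.05, target edge fraction
0.01, with everything reproducible from a single seed.

## Synthetic cohort generator

The generator emulates what source reconstruction would deliver for a
two-group cohort, plus the accompanying clinical bookkeeping. Defaults are
the emulated study's conditions: 37 + 27 subjects, 90 regions, 30 × 10 s
epochs, all five bands, 90° planted phase lag. The sampling rate defaults to
300 Hz — half the original 600 Hz acquisition — keeping the 65–80 Hz band
well below Nyquist at desk-scale runtime (configurable).

* **Carriers**: each region × band component is white noise band-passed with
  the same FIR designs as the analysis path and scaled to unit variance.
  Band-limited noise (not pure sinusoids) keeps instantaneous phase
  non-degenerate; pure tones would make wPLI trivially 1 and hide estimator
  bugs.
* **Planted coupling**: an edge (i → j, band) with group coupling κ replaces
  region j's band component with κ·delay(c_i) + sqrt(1 − κ²)·own, where the
  delay is band_centre⁻¹·(phase lag / 2π) seconds rounded to whole samples
  (an error if it rounds to zero — the lag is then unrepresentable at that
  rate). Each region may be the target of at most one planted edge per band.
* **Noise and field spread**: independent broadband Gaussian noise of SD
  `noise_sd` (default 0.5 against unit-variance carriers — there is no
  published SNR for source series, so this moderate value is exposed rather
  than asserted as physiological); optional instantaneous mixing
  (1 − s)·own + s·uniform mixture of the other regions emulates field
  spread, which wPLI should ignore.
* **Metadata**: sex and age are drawn independently of group by default
  (configurable to test covariate adjustment). Outcome scores follow
  β0 + β1·κ + covariate terms + Gaussian residual; defaults are an IQ-like
  score (mean 100, residual SD 13) and a BASC-like T-score (mean 50, SD 10)
  with zero planted linkage. Daily macronutrient/energy intakes for
  postnatal days 1–29 use the reported day 9–29 cohort means/SDs (protein
  3.6 ± 0.5, lipid 4.9 ± 1.1, carbohydrate 11.9 ± 1.3 g/kg/day, energy
  105.6 ± 14.9 kcal/kg/day); days 1–8 ramp up from near zero (parenteral-
  feeding establishment) and are generated but ignored by the day 9–29
  summariser. Per-epoch head-motion traces are |N(2, 1)| mm, matching the
  reported ~2 mm median motion. Everything is deterministic given the spec
  seed (per-subject streams are spawned from it).

What the generator does **not** emulate: sensor-level physics (no forward /
inverse model, no realistic head geometry or leakage topology — field spread
is uniform), realistic demographic joint distributions, non-stationarity,
1/f spectral shape, or cross-frequency structure. Passing tests therefore
demonstrate correctness of the estimators and inference machinery under a
controlled oscillatory model, not performance on real MEG.

## Verification suites and problem sizes

Chosen once as desk-scale study conditions and documented here:

* **Null FWER calibration**: 200 synthetic null cohorts (10+10 subjects, 30
  regions, 5 epochs, alpha band), one-sided group contrast with 500
  permutations at α = 0.05; the fraction of cohorts with any significant
  component must not exceed 0.05 + 2 binomial SE.
* **Exhaustive-permutation oracle**: 4+4 subjects — all 70 group assignments
  enumerated; NBS p-values must match the enumeration exactly.
* **Planted-network recovery**: 6-edge alpha star, κ = 0.75 vs 0.25,
  20+20 subjects, 20 replicates; a significant component with edge Jaccard
  ≥ 0.5 against ground truth must appear in ≥ 80 % of replicates. (With a
  1 % edge fraction on 30 regions, 4 edges are supra-threshold, so a perfect
  recovery has Jaccard 4/6 ≈ 0.67; a star is used so that any planted subset
  stays connected.)
* **Component extraction**: 1000 random graphs of ≤ 20 nodes against a
  breadth-first-search oracle; the union-find used inside the permutation
  loop is additionally checked against the public networkx-based extraction.
* **Zero-lag immunity**: field-spread mixing at strength 0.3 on independent
  pairs over 200 seeds must not raise mean wPLI by more than 2 SE of the
  paired difference.

`scripts/acceptance.py` re-runs the same suites at reduced replicate counts
(100 null cohorts, 10 recovery replicates, 100 immunity seeds) plus the
worked analytic examples, and writes every quantity as JSON.

## Numerical choices and edge cases

* Zero-variance edges: z-score 0, t forced to 0 (never supra-threshold).
* Threshold ties keep all tied edges; the supra count may exceed the target
  and is logged.
* Exactly-at-limit QC values are retained (see boundary semantics above).
* Connectivity files are validated on read (symmetry to 1e-9, range [0, 1],
  zero diagonal, finiteness) with the offending cell named.
* Percentages in intake summaries round half away from zero to integer
  percent, matching clinical-table style.
* Demographics dispatch: Pearson chi-square without continuity correction
  for categorical variables — the plain Σ(O−E)²/E statistic on the supplied
  contingency table, with no category collapsing or exact-test fallback, so
  values may differ from published tables whose handling of sparse
  categories is undocumented; Shapiro-Wilk at α = 0.05 per group decides
  two-tailed pooled-variance t-test (both normal) vs two-sided
  Mann-Whitney U; groups with < 3 continuous observations skip the variable
  with a warning.

## Known limitations

* The pipeline starts at source-space region series; beamforming, ICA
  artefact removal and MRI co-registration are out of scope.
* The uniform field-spread model has no spatial structure; it tests
  zero-lag immunity, not realistic leakage geometry.
* wPLI's finite-sample positive bias means absolute connectivity values are
  comparable only at matched epoch counts/lengths.
* The atlas fixture ships approximate region centroids for export and
  labelling, not a volumetric parcellation.
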