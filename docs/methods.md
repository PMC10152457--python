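# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the pipeline, in the order the data flows through it.

## Synthetic phantoms

Real FTIR tissue images are the intended input, but every stage is
developed and verified against synthetic phantoms with known ground truth.
A phantom pixel's spectrum is

  A(ν) = Σᵢ aᵢ·exp(−(ν−cᵢ)²/2σᵢ²) + p(t) + paraffin(ν) + ε(ν),

i.e. a per-class sum of Gaussian absorbance bands, a low-order polynomial
baseline drift in the normalised grid coordinate t ∈ [0, 1], paraffin
CH-deformation contamination (bands at 1378 and 1462 cm⁻¹, inside the
masked 1350–1500 cm⁻¹ interval), and independent zero-mean Gaussian channel
noise. Gaussian band shapes and additive white noise are the simplest
forms consistent with condensed-phase mid-IR spectra and detector noise;
they are adequate for property testing but deliberately omit what real
tissue data contains: correlated (pink) noise, scattering baselines,
resonant-Mie band distortions, pixel-to-pixel thickness variation and
partial-volume mixing at region boundaries. Passing tests on phantoms
therefore demonstrates correctness of the *algorithmics* — gating,
baseline geometry, ranking, voting, fold bookkeeping — not clinical-grade
performance on tissue.

The default seven-class roster (OSCC, CS, BL, ML, NS, SM, LYM) shares a
soft-tissue scaffold (Amide I 1650 cm⁻¹, amplitude 1.0 AU, σ 16; Amide II
1540, 0.62, 13; CH deformation 1455; Amide III/phosphate 1240; carbohydrate
1080) and adds two or three class-specific bands of amplitude 0.08–0.22 AU
in the spectral neighbourhoods where such tissues plausibly differ (amide
shoulders 1510–1570 cm⁻¹, carbonyl region ~1700 cm⁻¹). These are
engineering choices that create pairwise-distinguishable classes; they are
not reconstructions of real tissue chemistry. The default channel noise is
σ = 0.02 AU, i.e. 2% of the Amide I peak — a realistic detector-noise
scale for imaging FTIR. Quality-gate violators are planted by rescaling
whole pixel spectra so the Amide I value falls below 0.1 (half of them) or
above 2 AU (the other half), exercising both gate branches; non-planted
pixels are guaranteed inside the window so the planted count is exact for
any spec.

Default wavenumber grid: 900–1800 cm⁻¹ inclusive at 4 cm⁻¹ (226 channels),
matching a 4 cm⁻¹ instrument resolution; full-range 900–3800 generation is
available through the spec. Generation is bit-reproducible given the spec
(seed included).

## Preprocessing

* **Quality gate.** A pixel is removed iff its absorbance at the channel
  nearest 1650 cm⁻¹ is < 0.1 or > 2 AU — strict inequalities, so boundary
  values are kept. Nearest-channel lookup is the simplest deterministic
  reading of "peak centre 1650 cm⁻¹"; a ±window maximum could be
  substituted but is not the default.
* **Truncation and paraffin omission.** Channels outside 900–1800 cm⁻¹ are
  dropped from storage; channels in the closed interval [1350, 1500] are
  masked from analysis but retained for display (ratio images). On the
  default grid this leaves 188 analysis channels (226 − 38).
* **Rubber band.** The baseline is the greatest convex minorant of the
  (ν, A) points — computed by Andrew's monotone-chain lower hull, O(n) after
  the grid is sorted — and is subtracted per pixel. It is computed on the
  full retained range *including* the paraffin channels: the hull is more
  stable on a contiguous range, and the paraffin region is excluded from
  analysis, not from correction. Residuals within 1e-12 of zero are
  clamped to exactly zero: below double precision there is no signal, and
  leaving such residuals in place lets numerically meaningless but
  perfectly ordered values (e.g. far Gaussian tails) masquerade as
  discriminative channels in noise-free data.
* **Vector normalisation.** Unit Euclidean norm over analysis channels
  only, so paraffin intensity cannot influence the tissue-spectrum scale;
  masked channels are scaled by the same factor for display consistency.
  Zero norm raises (a dead pixel that escaped the gate).

The order — gate, truncate/mask, baseline, normalise — is fixed and
asserted by a provenance regression test.

## Metrics and ranking

* **Ratio guard.** A ratio is undefined when |A(ν_den)| < ε with
  ε = 1e-6 on the vector-normalised scale; undefined ratios are excluded
  from that metric's PDF and scoring rather than imputed (imputation would
  fabricate density mass at arbitrary values). Committee metrics abstain
  on undefined ratios at prediction time, mirroring the training-side
  exclusion.
* **PDF estimator.** Gaussian KDE with Silverman's bandwidth on the robust
  spread min(sd, IQR/1.34), evaluated on a fixed 512-point grid spanning
  the central 99.9% of training ratios (padded by 3 bandwidths),
  renormalised to unit mass, linearly interpolated at evaluation time with
  a density floor of 1e-12 to avoid zero likelihoods. When the training
  ratios are spread-free the bandwidth falls back to 1e-3 × the ratio
  magnitude (relative, not absolute), so a point-mass class still resolves
  differences at the scale its ratios actually live on. A
  Freedman–Diaconis histogram estimator is available via configuration.
* **Both orderings** of each pair are kept as distinct metrics, and AUC is
  oriented (max(a, 1−a)) for ranking: a PDF-based committee is
  direction-free, and reciprocal pairs legitimately appear side by side in
  top-five lists.
* **Ties** in AUC are broken by (lower numerator wavenumber, then lower
  denominator wavenumber) for run-to-run determinism.
* **Implementation.** AUC uses the rank-sum identity with average ranks
  (exactly the ties-½ pair-counting convention; verified against an
  exhaustive oracle). The exhaustive scan over all n(n−1) pairs is
  vectorised: one sort per pair column, with per-class rank sums
  accumulated in sorted order; undefined ratios are mapped to +inf, which
  leaves the ranks of defined values identical to their excluded-case
  ranks, so per-column exclusion costs nothing. The batch path is tested
  for exact agreement with the scalar scorer, including ties and
  undefined entries.

## Committee classification

Per metric, the ratio's class likelihoods (PDF evaluations) are multiplied
by the class prior (uniform by default — training is class-balanced by
design) and normalised into a posterior; the committee output is the mean
of the per-metric posteriors over all non-abstaining metrics in the union
of the per-class top-k committees (k = 5 default). Mean-of-posteriors is
the simplest committee-voting rule that yields calibrated-looking,
normalised probabilities; a log-likelihood-sum combination is available
via `combination="loglik"`. Ties in the argmax take the first class in
model order. The confidence value is max probability / sum of
probabilities, which equals the maximum probability once the vector is
normalised; for a seven-class model it lies in [1/7, 1]. If every metric
abstains the spectrum is unclassifiable and its pixel is labelled
"excluded".

Models serialise to a single JSON container (classes, priors, metric
wavenumbers, PDF grids, metadata); Python's shortest-round-trip float
representation makes the round trip bit-exact, which a prediction-identity
test asserts.

## Evaluation protocol

* Equal per-image sampling (without replacement) guards against any one
  image dominating the model.
* Folds are stratified on class × patient cells: within each cell,
  shuffled indices are dealt round-robin with a rotating starting fold, so
  every fold holds within ±1 spectrum of its proportional share of every
  cell. Five folds by default.
* Inside each training fold, spectra are split 50/50 (class-stratified)
  into a PDF-fitting half and an AUC-scoring half — three-stage separation
  (fit / rank / evaluate) with only five folds available. The held-out
  fold is touched only by the final committee.
* Reported uncertainties are the sample standard deviation of per-fold
  estimates; sensitivity and specificity are one-vs-rest percentages
  derived from the multi-class confusion matrix. An "excluded" prediction
  counts against its true class.
* A label-permutation null (shuffle labels, rerun the whole CV) is part of
  the acceptance checks: with exchangeable labels mean sensitivity must
  collapse to 100/7 %, which guards against leakage between the three
  stages.

## Imaging

Pseudo-colour maps use a hue-maximally-spaced palette (≥ 20° separation up
to ~12 classes); pixel colour is the class base colour with HSV saturation
scaled linearly by confidence (a gamma option reshapes the curve), value
preserved, excluded pixels black. The class is recoverable from the hue
wherever confidence is non-negligible. Ratio images require the requested
wavenumbers to sit on the stored grid (within half a grid step) and flag
masked or undefined pixels as NaN.

## Problem sizes used in the test suite

The full default configuration (three 21×21 phantom images, 188 analysis
channels, 35,156 metrics ranked per fold) is exercised once in the
cross-validation recovery check. Protocol-level properties that need many
repeated runs — the label-permutation null (10 runs) and noise
monotonicity (20 runs) — use a reduced phantom (16 cm⁻¹ grid, 10×10
images, two images) whose per-run cost is a fraction of a second; the
planted-signal identification study (20 replicates) uses an 8 cm⁻¹ grid
(8,742 candidate pairs per replicate). These sizes are the package's
choice of a thorough-but-routine desk experiment; all of them scale up by
changing the phantom spec.

## Known limitations

* The committee's probabilities are raw averaged posteriors, not
  calibrated (no Platt/isotonic step) — by design.
* Redundancy among top metrics is not penalised (no mRMR-style selection);
  metrics are ranked individually, so top-five lists are often reciprocal
  and near-duplicate pairs. That mirrors how tightly grouped
  discriminating wavenumbers are reported in this field.
* No scattering corrections (resonant Mie/EMSC) or atmospheric
  compensation: the intended inputs are paraffin-embedded sections, where
  refractive-index matching makes scattering correction unnecessary, and
  the phantoms do not simulate such artefacts.
* Phantom "patients" are one-per-image; real patient effects (shared
  chemistry across images of one patient) are not emulated, so the
  patient-stratification machinery is exercised structurally, not
  biologically.
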