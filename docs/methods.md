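# Methods

## The generative model

A synthetic serum spectrum on the wavenumber grid ν̃ (default 400–1800 cm⁻¹
at 1 cm⁻¹, 1401 points; the instrument resolution of such systems varies,
so the grid is configurable) is

    y(ν̃) = s_subj · Σ_k a_k m_k(g) L(ν̃; c_k, w_k)  +  b(ν̃)  +  B(ν̃)  +  ε(ν̃)  +  spikes

with

* `L(ν̃; c, w) = 1 / (1 + ((ν̃−c)/w)²)` — unit-height Lorentzian, the
  standard Raman line shape; default band positions follow common serum
  assignments (phenylalanine ~1004, carotenoid ~1157, amide III ~1250,
  CH₂ deformation ~1450, amide I ~1655 cm⁻¹, …). Positions, widths (HWHM
  6–14 cm⁻¹) and amplitudes are configuration, not fixed truth.
* `m_k(g)` — per-class multiplier of band k. A band with unequal
  multipliers carries the disease signal; the defaults plant moderate,
  graded effects (both disease classes separate well from healthy, cancer
  vs benign is hardest), the qualitative difficulty pattern serum screening
  studies report.
* `s_subj = exp(N(0, σ_subj))`, default σ_subj = 0.05 — a multiplicative
  per-subject latent factor. It correlates the 15 replicate scans of one
  serum sample, which is what makes subject-level and spectrum-level data
  splitting genuinely different.
* `b(ν̃)` — random per-spectrum polynomial (default order 3, coefficient
  scale 30 counts) emulating fluorescence-like baseline drift.
* `B(ν̃)` — smooth container-background shape (slope + 3 broad Gaussians,
  deterministic given the seed), scaled by `background_amplitude`
  (default 150 counts): the cryotube contributes its own scatter, which the
  acquisition protocol estimates from dedicated background scans.
* `ε ~ N(0, σ)` with default σ = 8 counts, and cosmic-ray spikes:
  Poisson(0.3)-many single-pixel positive excursions of amplitude
  |N(0, 600)| per spectrum.

Replicate structure: every subject contributes `sessions ×
scans_per_session` spectra (default 3 × 5 = 15, the study design). Each
subject draws from an independent seed substream keyed by (group, index),
so enlarging a cohort never reshuffles existing subjects. The external
verification set uses disjoint substreams of the same parameters; its
emitted labels are `unknown` (blinded) with the truth held separately.

What the generator does *not* emulate: wavenumber miscalibration,
photobleaching kinetics, detector nonlinearity, session-level drift, and
any real biochemical covariance between bands. Passing tests therefore
demonstrate the pipeline's statistical machinery, not clinical performance
on real serum.

## Preprocessing

Per spectrum, most-local artefact first:

1. **Despiking.** Residuals from a rolling median (window 5) are
   standardised by 1.4826·MAD; points beyond z = 8 robust SDs are replaced
   by linear interpolation across the flagged run. If MAD = 0 (noise-free
   input: the median filter reproduces most points exactly) the z-score is
   degenerate and nothing is flagged. Cosmic rays are single- or few-pixel
   events, hence the small window.
2. **Background subtraction.** Pointwise subtraction of the mean of the
   replicate container scans.
3. **Smoothing.** Whittaker smoother: minimise Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)²,
   solved as a sparse pentadiagonal system; λ defaults to 10³ on the
   1 cm⁻¹ grid (λ = 0 returns the input). The "automatic weighting" is an
   IRLS loop: weights wᵢ = 1/(1 + (rᵢ/2.385s)²) (Cauchy) with
   s = 1.4826·MAD of the residuals, iterated (max 10 passes) until the
   largest weight change < 10⁻³. This down-weights outlying points the
   despiker missed. The weighting rule is a design choice; any robust
   reweighting would serve.
4. **Baseline.** Modified polynomial fitting: fit an order-5 polynomial
   (on the axis scaled to [−1, 1]; the fit is a precomputed hat-matrix
   application), clip the working spectrum to the fit, refit until the
   largest change between successive fits < 10⁻⁶ of the input range or 100
   iterations; subtract the final fit. Non-convergence returns the best
   iterate. Order 5 trades flexibility against absorbing broad bands.
5. **Normalization.** Divide by the trapezoidal integral over ν̃ (area per
   cm⁻¹), so every spectrum has unit area; a plain intensity-sum mode is
   available since "area" admits both readings. Negative post-baseline
   values are retained — clipping would bias the area. A non-positive area
   aborts with a diagnostic, as it signals a failed baseline fit.

Smoothing before baseline correction follows the order the chain lists the
steps in; both orders are defensible and the stage functions compose freely.

Two interactions worth knowing:

* **Closure.** Area normalization redistributes intensity: raising three
  bands by 1.5× in one class *lowers* that class's normalized intensity
  everywhere else. Group differences can therefore cross zero on a band
  shoulder, and "recovering a planted region" is judged by its apex and
  the majority of in-band points, not every shoulder point.
* **Edge absorption.** A band near a grid edge has slowly-varying
  Lorentzian tails there, which the polynomial baseline treats as baseline.
  Measured on the default chain, a differential band at 1655 cm⁻¹ (145 cm⁻¹
  from the 1800 cm⁻¹ edge) retains only ~1% apex group difference after
  preprocessing versus ~18% for an interior band of equal raw effect. The
  recovery experiments plant differential bands in the interior for this
  reason.

## Feature selection

Per wavenumber, one-way fixed-effects ANOVA: F = MS_between/MS_within on
(k−1, N−k) df, p from the upper F tail (for two groups F = t² of the pooled
t test). Selection repeats the test over `n_repeats` = 100 random
subsamples — within each subject, a fraction (default 0.7) of their spectra
— and keeps wavenumbers significant (α = 0.05) in **strictly more than**
`min_hits` = 70 repeats. The boundary rule is configurable. Each repeat
uses its own seed substream, so hit counts are independent of repeat order
and extending the repeat count extends, never reshuffles, earlier repeats.

For exchangeable spectra the chance of >70/100 hits at α = 0.05 is below
10⁻⁶ per wavenumber (binomial tail; the repeats share data, so this is an
approximation), and on null cohorts of independent spectra the selected set
is empty in practice. **Limitation:** the resampling unit is the spectrum,
so between-subject heterogeneity (the latent factor) is *not* resampled;
a chance imbalance in subject scales persists in every repeat and can push
null wavenumbers past the threshold. A `unit="subject_mean"` mode
(averaging each subject's subsampled spectra before testing) reduces but
does not remove this, for the same reason. This inflation is inherent to
stability selection on clustered data and is why the classifier's hold-out
splits default to the subject level. Pairwise two-group ANOVA is the
default; a three-group mode serves the multiclass feature set. No
multiple-testing correction is applied — the stability threshold is the
only filter.

## Classification and evaluation

Features are the selected wavenumbers' intensities, z-scored with
training-fold statistics. The RBF-SVM's (C, γ) are chosen by inner
stratified 5-fold cross-validated accuracy over C ∈ {0.1, 1, 10, 100},
γ ∈ {10⁻³…10} (log-spaced); exact accuracy ties are broken by
cross-validated log-loss, because the worst underfit settings can win an
accuracy tie while their Platt probability calibration degenerates to a
flat 0.5. Probabilities are Platt-scaled; for three classes, pairwise
models are combined by probability coupling. Ties in the probability
argmax go to the lexicographically first class label.

The outer loop draws stratified 70/30 train/test splits, repeated
(default 50×), and records sensitivity (diseased class positive: cancer
over benign over healthy), specificity, accuracy and AUC per repeat,
summarised as mean ± SD. AUC is the empirical nonparametric (Mann–Whitney)
area, ties counted ½. Splitting defaults to the **subject** level — all 15
replicate scans of a serum sample stay together, which is the leakage-free
design — with a spectrum-level mode provided because splitting "all
spectra" is how such studies often report; spectrum-level numbers are
optimistic under within-subject correlation. Feature selection likewise
defaults to *inside* each training fold (recomputed per repeat); a
precomputed-mask mode reproduces selection-on-all-data designs. A repeat
whose test part lost a class is skipped and counted.

External validation trains an ensemble of multiclass models on random
subject-level 70% draws (the ensemble size is configurable, letting the
per-sample vote count be spectra × models); every model predicts every
blinded spectrum, the per-class counts accumulate per sample, and the
sample takes the majority class — ties are flagged, never silently
resolved. Truth is attached only after voting.

## Problem sizes and numerical choices

The test-suite and acceptance-script experiments run on a 4 cm⁻¹ grid (351
points) with 10–15 subjects per group and 5–10 hold-out repeats; the
structural-count checks generate the full 120-subject × 15-scan cohort.
These sizes were chosen as the smallest at which the stochastic properties
under test are comfortably stable across seeds. Determinism: every
stochastic component takes an explicit seed and derives per-unit
substreams; a pipeline rerun with the same configuration writes
byte-identical metric tables, and the run manifest records the
configuration hash, derived stage seeds, decision flags (split unit,
selection placement, threshold boundary rule) and per-artefact checksums.

Degenerate inputs are errors, not guesses: non-finite intensities and
non-monotone axes are rejected at construction, all-flagged despiking
aborts, a single-class training set aborts, an empty feature mask aborts,
and all-zero vote counts abort.

## Known limitations

* Clinical values from real cohorts are not reproducible here; the
  synthetic generator defines its own ground truth.
* Accuracy can legitimately fall outside the [min(sens, spec), max(...)]
  interval only when aggregated across differing splits; per-repeat the
  standard confusion-matrix identities hold, and this package reports
  per-repeat metrics only.
* Stability selection on clustered spectra is anti-conservative (above).
* The Whittaker weighting rule and the polynomial order are stand-ins for
  unspecified vendor routines; both are explicit configuration.
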