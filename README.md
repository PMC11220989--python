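# ramanscreen

Serum Raman spectroscopy is a label-free candidate for noninvasive cancer
screening: serum's proteins, lipids and metabolites produce a fingerprint
of vibrational bands over 400–1800 cm⁻¹, and disease shifts the relative
band intensities subtly enough that a classifier, not the eye, has to find
them. `ramanscreen` implements the complete analysis pipeline of a
three-class serum screening study (healthy controls, benign lung lesions,
lung cancer) as a tested, reusable Python library:

* **Synthetic cohort generation** — Lorentzian serum bands with
  class-dependent intensity multipliers, a per-subject latent scale factor
  correlating the 3 sessions × 5 scans = 15 replicate spectra per serum
  sample, container background, polynomial baseline drift, shot-like noise
  and cosmic-ray spikes, all reproducible from one seed with ground truth
  attached.
* **Chemometric preprocessing** — cosmic-ray removal (rolling-median
  despiking), mean container-background subtraction, automatic-weighted
  least-squares smoothing (an iteratively reweighted Whittaker smoother
  minimising Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²), iterative (modified) polynomial
  baseline fitting, and total-area normalization (trapezoidal ∫I dν̃ = 1).
* **Stability feature selection** — at every wavenumber a one-way ANOVA
  F = MS_between/MS_within across the compared groups, repeated over 100
  random subject-stratified subsamples; a wavenumber is an SVM feature only
  when p < 0.05 in strictly more than 70 of the 100 repeats.
* **RBF-SVM classification** — soft-margin SVM with Gaussian kernel,
  (C, γ) chosen by inner 5-fold cross-validated accuracy, evaluated by
  stratified 70/30 hold-out repeated 50 times; sensitivity, specificity,
  accuracy and nonparametric (Mann–Whitney) AUC reported as mean ± SD.
* **Sample-level majority voting** — each blinded serum sample's replicate
  spectra are predicted individually (three-class probabilities via
  pairwise coupling) and the sample is assigned the class with the most
  spectrum-level votes.

## Worked example

`examples/` contains one narrative script per capability. Feature
selection plus repeated hold-out on a synthetic 8-vs-8-subject cohort
(`examples/04_classification.py`) prints:

```
cancer_vs_healthy: auc=1.000±0.001, sensitivity=0.973±0.021, specificity=0.977±0.045, accuracy=0.975±0.020 (10 repeats)
```

i.e. across ten subject-level 70/30 hold-out repeats, 97.3% of held-out
cancer spectra were called cancer, 97.7% of healthy spectra were called
healthy, and a random cancer spectrum outranked a random healthy one with
probability ≈1. Blinded external validation
(`examples/05_external_validation.py`) votes each sample from its 45
spectrum-level predictions (15 scans × 3 models):

```
reference verification table: 15/15 samples voted correctly
  ext_cancer_002   benign:  0 cancer: 45 healthy:  0  -> cancer   (true cancer) ok
```

The first line replays the bundled reference verification table
(`ramanscreen.datasets`): 15 published per-sample vote-count triplets whose
majority votes all match the unblinded classes.

A full run — simulate → preprocess → select → evaluate → external
validation → report, with a manifest of seeds and artefact checksums — is
one call (`ramanscreen.run_all(RunConfig(...))`) or one shell command:

```
ramanscreen run-all --config run.yaml
```

where `run.yaml` holds the `RunConfig` fields (cohort sizes, grid,
preprocessing, selection, classifier, split plan, output directory, seed).

## Layout

```
src/ramanscreen/
  spectra_io.py       data model (grid, spectrum, cohort) + CSV dialects
  synthetic_cohort.py generator with ground truth
  preprocess.py       despike / background / smooth / baseline / normalize
  select_features.py  ANOVA + stability selection
  classify.py         RBF-SVM, grid search, repeated hold-out
  evaluate_report.py  metrics, ROC/AUC, majority voting, report rendering
  pipeline.py         end-to-end orchestration + manifest
  cli.py              thin command-line layer
  datasets.py         bundled reference verification vote table
docs/methods.md       models, assumptions, parameter choices, limitations
examples/             one runnable narrative script per capability
```
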