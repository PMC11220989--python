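"""Pairwise RBF-SVM evaluation with repeated 70/30 hold-out.

Outer level: stratified subject-level 70/30 splits, repeated; inner level:
grid search over (C, gamma) by 5-fold cross-validated accuracy on the
training part only.  Feature selection runs inside each training fold, so
no information from held-out subjects leaks into the features.
"""

import ramanscreen as rs
from ramanscreen.synthetic_cohort import generate_background_scans

grid = rs.default_grid(step=4.0)
config = rs.CohortConfig(
    n_per_group={"healthy": 8, "benign": 0, "cancer": 8}, noise_sd=5.0, seed=11
)
cohort, _ = rs.generate_cohort(config, grid)
background = rs.mean_background(generate_background_scans(config, grid))
clean = rs.preprocess_set(cohort, background)

summary = rs.repeated_holdout(
    clean,
    rs.ClassifierSpec(C_grid=(1.0, 10.0, 100.0), gamma_grid=(0.01, 0.1)),
    rs.SplitPlan(train_fraction=0.7, n_repeats=10, unit="subject", seed=3),
    selection=rs.SelectionSpec(n_repeats=50, min_hits=35),
    comparison=("cancer", "healthy"),
)

print(summary)
for name in ("auc", "sensitivity", "specificity", "accuracy"):
    print(f"  {name:12s} {summary.mean(name):.3f} ± {summary.sd(name):.3f}")

# Mean ± SD across the hold-out repeats.  Sensitivity is the fraction of
# held-out cancer spectra called cancer; AUC is the probability that a
# random cancer spectrum gets a higher cancer-probability than a random
# healthy one.  Subject-level splitting keeps all 15 replicate scans of a
# serum sample on one side of the split.
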