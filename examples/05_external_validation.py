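"""Blinded external validation by spectrum votes and sample-level majority.

Every spectrum of each blinded serum sample is predicted by an ensemble of
three-class RBF-SVMs; the sample is assigned the class receiving the most
spectrum-level predictions.  Truth is attached only after voting.

Also replays the bundled reference verification table: 15 published
per-sample count triplets whose majority votes must all match the
unblinded classes.
"""

import ramanscreen as rs
from ramanscreen.datasets import REFERENCE_EXTERNAL_VOTES
from ramanscreen.synthetic_cohort import generate_background_scans

# -- reference worked example ----------------------------------------------
correct = 0
for sample, healthy, benign, cancer, true_class in REFERENCE_EXTERNAL_VOTES:
    predicted, _ = rs.majority_vote({"healthy": healthy, "benign": benign, "cancer": cancer})
    correct += predicted == true_class
print(f"reference verification table: {correct}/15 samples voted correctly")

# -- synthetic blinded external set ----------------------------------------
grid = rs.default_grid(step=4.0)
config = rs.CohortConfig(
    n_per_group={"healthy": 6, "benign": 6, "cancer": 6}, noise_sd=4.0, seed=19
)
cohort, _ = rs.generate_cohort(config, grid)
external, ext_truth = rs.generate_external_set(
    config, grid, {"healthy": 2, "benign": 2, "cancer": 2}
)
background = rs.mean_background(generate_background_scans(config, grid))
cohort_pp = rs.preprocess_set(cohort, background)
external_pp = rs.preprocess_set(external, background)

mask = rs.stability_select(
    cohort_pp, ("healthy", "benign", "cancer"), n_repeats=50, min_hits=35, seed=2
)
models = rs.train_holdout_ensemble(
    cohort_pp, mask,
    rs.ClassifierSpec(C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1)),
    n_models=3, seed=5,
)
votes = rs.external_validate(models, external_pp, mask, ext_truth.labels)

print(f"\nblinded synthetic external set ({len(votes)} samples, "
      f"{3 * config.scans_per_subject} votes each):")
for v in votes:
    counts = " ".join(f"{c}:{n:3d}" for c, n in sorted(v.counts.items()))
    flag = "ok" if v.correct else "WRONG"
    print(f"  {v.sample_id:16s} {counts}  -> {v.predicted:8s} (true {v.true_class}) {flag}")

# Majority voting turns per-scan predictions into a per-sample call: a
# sample is misclassified only if most of its 45 votes go to a wrong class,
# which makes the sample-level decision far more robust than any single scan.
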