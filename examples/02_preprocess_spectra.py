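"""Run the chemometric preprocessing chain on raw synthetic spectra.

Order of operations: cosmic-ray removal -> container-background
subtraction -> iteratively reweighted Whittaker smoothing -> iterative
polynomial baseline correction -> total-area normalization.
"""

import numpy as np

import ramanscreen as rs
from ramanscreen.synthetic_cohort import generate_background_scans

grid = rs.default_grid(step=2.0)
config = rs.CohortConfig(n_per_group={"healthy": 3, "benign": 0, "cancer": 3}, seed=7)
cohort, _ = rs.generate_cohort(config, grid)

background = rs.mean_background(generate_background_scans(config, grid))
clean = rs.preprocess_set(cohort, background, rs.PreprocessConfig())

raw = cohort.intensity_matrix()
out = clean.intensity_matrix()
areas = np.trapezoid(out, grid.values, axis=1)

print(f"preprocessed {len(clean)} spectra on {len(grid)} grid points")
print(f"raw intensity range:          {raw.min():9.1f} .. {raw.max():9.1f} counts")
print(f"normalized intensity range:   {out.min():9.6f} .. {out.max():9.6f} per cm^-1")
print(f"total area after normalization: min {areas.min():.12f}, max {areas.max():.12f}")

# Every spectrum now integrates to exactly 1 over the wavenumber axis, so
# acquisition-to-acquisition intensity differences (laser power, focus) are
# gone and only the spectral *shape* remains for the statistics.
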