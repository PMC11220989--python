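"""Generate a synthetic serum-Raman screening cohort.

Builds a three-class cohort (healthy / benign lung lesion / lung cancer)
with the replicate structure of a serum screening study — every subject's
serum sample is scanned 5 times in each of 3 sessions — plus container
background, baseline drift, noise and cosmic-ray spikes.
"""

import ramanscreen as rs

grid = rs.default_grid()  # 400-1800 cm^-1 at 1 cm^-1: 1401 points
config = rs.CohortConfig(
    n_per_group={"healthy": 5, "benign": 5, "cancer": 5}, seed=42
)
cohort, truth = rs.generate_cohort(config, grid)

print(f"grid: {grid.min:.0f}-{grid.max:.0f} cm^-1, {len(grid)} points")
print(f"subjects: {len(cohort.subjects())} ({config.n_per_group})")
print(f"spectra: {len(cohort)} = subjects x {config.sessions} sessions x "
      f"{config.scans_per_session} scans")
print(f"differential bands (planted disease signal): {truth.differential_wavenumbers}")
print(f"spectra carrying cosmic-ray spikes: {len(truth.spike_positions)}")

# The printed counts mirror the screening design: 15 replicate spectra per
# serum sample, and a known set of wavenumbers where the class labels
# actually change the spectrum -- the ground truth later stages must recover.
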