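import numpy as np
import pytest

import ramanscreen as rs
from ramanscreen.synthetic_cohort import generate_background_scans


@pytest.fixture(scope="session")
def coarse_grid() -> rs.WavenumberGrid:
    """400-1800 cm^-1 at 4 cm^-1 (351 points) — fast stand-in for the 1 cm^-1 grid."""
    return rs.default_grid(step=4.0)


@pytest.fixture(scope="session")
def tiny_cohort(coarse_grid):
    """2 subjects per class, full 3x5 replicate structure."""
    cfg = rs.CohortConfig(n_per_group={"healthy": 2, "benign": 2, "cancer": 2}, seed=7)
    sset, truth = rs.generate_cohort(cfg, coarse_grid)
    return cfg, sset, truth


@pytest.fixture(scope="session")
def preprocessed_pair(coarse_grid):
    """Preprocessed two-class cohort with the default (moderate) class effects."""
    cfg = rs.CohortConfig(
        n_per_group={"healthy": 6, "benign": 0, "cancer": 6}, seed=21, noise_sd=5.0
    )
    sset, truth = rs.generate_cohort(cfg, coarse_grid)
    bg = rs.mean_background(generate_background_scans(cfg, coarse_grid))
    return cfg, rs.preprocess_set(sset, bg), truth


def make_spectrum(values, subject="s1", group="healthy", session=1, scan=1) -> rs.Spectrum:
    return rs.Spectrum(subject, group, session, scan, np.asarray(values, dtype=float))
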