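"""Bundled reference data.

``REFERENCE_EXTERNAL_VOTES`` is a published worked example of sample-level
majority voting from a three-class serum-Raman lung screening study: for
each of 15 blinded verification samples (5 healthy controls, 5 benign lung
lesions, 5 lung cancers), the number of spectrum-level predictions each
class received (1500 predictions per sample), together with the unblinded
true class.  It exercises the voting rule end to end: feeding each count
triplet to :func:`ramanscreen.evaluate_report.majority_vote` must recover
the true class for all 15 samples.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_EXTERNAL_VOTES", "load_reference_votes"]

# (sample, healthy votes, benign votes, cancer votes, true class)
REFERENCE_EXTERNAL_VOTES: list[tuple[int, int, int, int, str]] = [
    (1, 990, 307, 203, "healthy"),
    (2, 985, 375, 140, "healthy"),
    (3, 989, 313, 198, "healthy"),
    (4, 994, 200, 306, "healthy"),
    (5, 997, 300, 203, "healthy"),
    (6, 237, 911, 352, "benign"),
    (7, 319, 949, 232, "benign"),
    (8, 212, 982, 306, "benign"),
    (9, 345, 986, 169, "benign"),
    (10, 299, 982, 219, "benign"),
    (11, 98, 695, 707, "cancer"),
    (12, 235, 294, 971, "cancer"),
    (13, 208, 316, 976, "cancer"),
    (14, 276, 266, 958, "cancer"),
    (15, 203, 488, 809, "cancer"),
]


def load_reference_votes() -> pd.DataFrame:
    """Reference external-verification vote counts as a tidy table."""
    return pd.DataFrame(
        REFERENCE_EXTERNAL_VOTES,
        columns=["sample", "healthy", "benign", "cancer", "true_class"],
    )
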