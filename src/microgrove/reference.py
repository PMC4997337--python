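"""Published three-profile maternal factor table used in worked examples.

Level counts per maternal profile from a large urban birth cohort
(N = 1,258 mothers; three latent profiles of sizes 609/474/175).  Per-item
denominators vary because item missingness differs; the reconstruction pads
each class with missing rows so column percentages recompute exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PROFILE_SIZES", "PROFILE_TABLE_COUNTS", "reconstruct_profile_data"]

PROFILE_SIZES = {1: 609, 2: 474, 3: 175}

# item -> level -> (count in profile 1, profile 2, profile 3)
PROFILE_TABLE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "maternal_race": {
        "African American": (609, 77, 92),
        "Caucasian/Other": (0, 397, 83),
    },
    "married": {
        "Yes": (293, 445, 35),
        "No": (316, 29, 140),
    },
    "mode_of_delivery": {
        "Vaginal": (364, 315, 105),
        "C-section": (242, 157, 67),
    },
    "breastfeeding_nsv": {
        "None": (266, 90, 145),
        "Mixed": (171, 205, 5),
        "Exclusive": (14, 123, 0),
    },
    "indoor_pets_nsv": {
        "Yes": (51, 204, 66),
        "No": (400, 214, 84),
    },
    "ets_nsv": {
        "Yes": (51, 18, 130),
        "No": (400, 401, 20),
    },
}


def reconstruct_profile_data() -> tuple[pd.Series, pd.DataFrame]:
    """Per-subject profile assignments and item levels matching the printed
    counts (missing rows padded with NaN per item)."""
    assignments = pd.Series(
        np.repeat(list(PROFILE_SIZES), list(PROFILE_SIZES.values())),
        name="profile",
    )
    offsets = {}
    start = 0
    for cls, size in PROFILE_SIZES.items():
        offsets[cls] = start
        start += size
    n = start
    items = {}
    for item, level_counts in PROFILE_TABLE_COUNTS.items():
        col = np.full(n, np.nan, dtype=object)
        for cls, size in PROFILE_SIZES.items():
            pos = offsets[cls]
            for level, counts in level_counts.items():
                c = counts[cls - 1]
                col[pos:pos + c] = level
                pos += c
        items[item] = col
    return assignments, pd.DataFrame(items)
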