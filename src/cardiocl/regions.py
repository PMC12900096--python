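"""Correspondence between ECG leads and cardiac anatomical regions.

In the retained 8-lead order (II, III, V1, V2, V3, V4, V5, V6) the four
myocardial walls map to lead pairs:

==========  =========  ==================
region      leads      0-based indices
==========  =========  ==================
anterior    V3, V4     (4, 5)
inferior    II, III    (0, 1)
septal      V1, V2     (2, 3)
lateral     V5, V6     (6, 7)
==========  =========  ==================
"""

from __future__ import annotations

import numpy as np

from .io import RETAINED_LEADS

__all__ = ["REGION_NAMES", "REGION_LEADS", "anatomical_grouping",
           "random_grouping"]

#: region index order d = 1..4 used in the loss
REGION_NAMES = ("anterior", "inferior", "septal", "lateral")

REGION_LEADS = {
    "anterior": ("V3", "V4"),
    "inferior": ("II", "III"),
    "septal": ("V1", "V2"),
    "lateral": ("V5", "V6"),
}


def anatomical_grouping() -> tuple[tuple[int, int], ...]:
    """Region -> (lead index pair) in REGION_NAMES order."""
    return tuple(
        tuple(RETAINED_LEADS.index(lead) for lead in REGION_LEADS[name])
        for name in REGION_NAMES)


def random_grouping(rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Random disjoint partition of the 8 leads into 4 pairs (ablation
    arm contrasting anatomy-aware with arbitrary grouping)."""
    perm = rng.permutation(8)
    return tuple((int(perm[2 * d]), int(perm[2 * d + 1])) for d in range(4))
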