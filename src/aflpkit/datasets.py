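"""Bundled example data: a field-survey count table and a synthetic
study-scale scoring matrix.

``field_survey_counts`` is a published count table from a Danish survey of
entomopathogenic *Metarhizium* fungi: isolates recovered from soil at three
localities (Fårevejle, Skibby, Tåstrup), each sampled under three crops
(winter oilseed rape, winter wheat, permanent grass pasture).  It is the
worked input for the chi-square analyses.

``synthetic_survey_matrix`` is a *synthetic* stand-in, generated in code,
with the same summary structure as the survey's deposited AFLP scoring
matrix: 93 isolates x 30 loci, 78 distinct haplotypes of which 11 are
shared among 2-4 isolates spanning multiple areas.  It exercises haplotype
grouping at study scale; it is not the deposited matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BinaryProfileMatrix
from .stats import ContingencyTable

__all__ = ["field_survey_counts", "synthetic_survey_matrix"]

AREAS = ["Faarevejle", "Skibby", "Taastrup"]
CROPS = ["oilseed_rape", "winter_wheat", "grass_pasture"]

# isolate counts (all Metarhizium species pooled) per locality x crop
_SURVEY_COUNTS = [
    [17, 17, 0],   # Fårevejle
    [6, 21, 44],   # Skibby
    [2, 19, 6],    # Tåstrup
]


def field_survey_counts() -> ContingencyTable:
    """The 3 x 3 locality-by-crop isolate count table (132 isolates)."""
    return ContingencyTable(
        row_labels=list(AREAS), col_labels=list(CROPS), counts=np.array(_SURVEY_COUNTS)
    )


def synthetic_survey_matrix(seed: int = 20150930) -> BinaryProfileMatrix:
    """A synthetic 93-isolate x 30-locus scoring matrix (see module docs).

    Construction: 78 distinct random band profiles (band frequency 0.4);
    67 are carried by a single isolate, 8 by pairs, 2 by trios and 1 by
    four isolates (67 + 8*2 + 2*3 + 4 = 93).  Members of each shared
    haplotype are spread
    across areas so that sharing spans localities, as observed in real
    clonal collections.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n_loci, n_haplotypes = 30, 78
    profiles: list[tuple] = []
    seen = set()
    while len(profiles) < n_haplotypes:
        p = tuple((rng.random(n_loci) < 0.4).astype(int))
        if p not in seen and any(p):
            seen.add(p)
            profiles.append(p)
    sizes = [4] + [3] * 2 + [2] * 8 + [1] * 67
    rows, areas, crops = [], [], []
    for h, size in enumerate(sizes):
        for m in range(size):
            rows.append(profiles[h])
            # shared haplotypes span areas; singletons rotate through all cells
            areas.append(AREAS[(h + m) % len(AREAS)])
            crops.append(CROPS[(h + 2 * m) % len(CROPS)])
    order = rng.permutation(len(rows))
    isolate_ids = [f"MF{i + 1:03d}" for i in range(len(rows))]
    calls = pd.DataFrame(
        np.array(rows)[order],
        index=isolate_ids,
        columns=[f"L{j + 1:03d}" for j in range(n_loci)],
    )
    metadata = pd.DataFrame(
        {
            "isolate_id": isolate_ids,
            "area": [areas[i] for i in order],
            "crop": [crops[i] for i in order],
            "origin": "study",
        }
    )
    return BinaryProfileMatrix(calls, metadata=metadata)
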