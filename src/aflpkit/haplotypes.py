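"""Haplotype grouping of isolates with identical AFLP profiles.

In a clonal or predominantly clonal fungus, isolates with identical
presence/absence profiles across all retained loci are interpreted as one
multilocus haplotype (a putative clonal lineage).  Grouping is exact-match
by default; an optional mismatch tolerance (single-linkage closure of the
<= k-mismatch graph) is available for sensitivity analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinaryProfileMatrix, _check_metadata
from .errors import ValidationError

__all__ = ["HaplotypeAssignment", "SharingSummary", "assign_haplotypes", "sharing_summary"]


@dataclass
class HaplotypeAssignment:
    """Isolate -> haplotype mapping, indexed by first occurrence."""

    haplotype_of: dict[str, int]
    profiles: list[np.ndarray]   # representative profile per haplotype
    sizes: list[int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.sizes)

    def members(self, haplotype: int) -> list[str]:
        return [i for i, h in self.haplotype_of.items() if h == haplotype]

    def labels(self, isolate_ids) -> np.ndarray:
        return np.array([self.haplotype_of[i] for i in isolate_ids])


def assign_haplotypes(
    matrix: BinaryProfileMatrix, max_mismatches: int = 0
) -> HaplotypeAssignment:
    """Group isolates by profile identity (default) or <= k mismatches.

    Haplotype indices follow first occurrence in the matrix row order, so
    the assignment is deterministic and independent of locus order.
    """
    if max_mismatches < 0:
        raise ValidationError("max_mismatches must be >= 0")
    ids = matrix.isolate_ids
    X = matrix.calls.to_numpy()

    if max_mismatches == 0:
        seen: dict[bytes, int] = {}
        haplotype_of: dict[str, int] = {}
        profiles: list[np.ndarray] = []
        sizes: list[int] = []
        for row, iso in enumerate(ids):
            key = X[row].tobytes()
            if key not in seen:
                seen[key] = len(profiles)
                profiles.append(X[row].copy())
                sizes.append(0)
            h = seen[key]
            haplotype_of[iso] = h
            sizes[h] += 1
        return HaplotypeAssignment(haplotype_of, profiles, sizes)

    # sensitivity mode: single-linkage components of the <=k-mismatch graph
    n = len(ids)
    mism = (X[:, None, :] != X[None, :, :]).sum(axis=2)
    adj = mism <= max_mismatches
    comp = -np.ones(n, dtype=int)
    next_comp = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = next_comp
        while stack:
            v = stack.pop()
            for w in np.flatnonzero(adj[v]):
                if comp[w] < 0:
                    comp[w] = next_comp
                    stack.append(w)
        next_comp += 1
    haplotype_of = {iso: int(comp[row]) for row, iso in enumerate(ids)}
    profiles = [X[np.flatnonzero(comp == h)[0]].copy() for h in range(next_comp)]
    sizes = [int(np.sum(comp == h)) for h in range(next_comp)]
    return HaplotypeAssignment(haplotype_of, profiles, sizes)


@dataclass
class SharingSummary:
    """Counts of shared vs unique haplotypes and their habitat composition."""

    n_haplotypes: int
    n_shared: int                  # haplotypes with >= 2 members
    n_unique: int
    shared_size_range: tuple[int, int] | None   # (min, max) over shared ones
    n_shared_multi_area: int       # shared haplotypes spanning >1 area
    n_shared_with_external: int    # shared haplotypes incl. external-origin isolates
    composition: pd.DataFrame      # one row per haplotype


def sharing_summary(
    assignment: HaplotypeAssignment, metadata: pd.DataFrame
) -> SharingSummary:
    """Summarize haplotype sharing across areas, crops and origins."""
    isolates = list(assignment.haplotype_of)
    metadata = _check_metadata(metadata, isolates)

    rows = []
    for h in range(assignment.n_haplotypes):
        members = assignment.members(h)
        areas = sorted({str(metadata.loc[m, "area"]) for m in members})
        crops = sorted({str(metadata.loc[m, "crop"]) for m in members})
        origins = {str(metadata.loc[m, "origin"]) for m in members}
        rows.append(
            {
                "haplotype": h,
                "size": len(members),
                "members": ";".join(members),
                "areas": ";".join(areas),
                "crops": ";".join(crops),
                "multi_area": len(areas) > 1,
                "has_external": "external" in origins,
            }
        )
    comp = pd.DataFrame(rows)
    shared = comp[comp["size"] >= 2]
    return SharingSummary(
        n_haplotypes=assignment.n_haplotypes,
        n_shared=int(len(shared)),
        n_unique=int((comp["size"] == 1).sum()),
        shared_size_range=(
            (int(shared["size"].min()), int(shared["size"].max()))
            if len(shared)
            else None
        ),
        n_shared_multi_area=int(shared["multi_area"].sum()),
        n_shared_with_external=int(shared["has_external"].sum()),
        composition=comp,
    )
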