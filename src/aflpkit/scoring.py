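"""Dual-replicate band calling and locus repeatability filtering.

AFLP is a dominant marker system: each fragment-size bin (locus) is scored
only as band present (1) or absent (0).  Because amplified-fragment
reproducibility is a known weakness of the technique, the entire procedure is
run twice per isolate and a band is called present only when both technical
replicates support it:

* present (1) iff ``max(i1, i2) >= t_high`` and ``min(i1, i2) >= t_low``
  with defaults ``t_high = 100`` RFU (confident signal) and ``t_low = 50``
  RFU (minimum distinguishable from background);
* absent (0) otherwise — both below the confident threshold, or either
  replicate below the reliability floor.

The thresholds are inclusive: a signal of exactly 100 counts as confident
and exactly 50 as minimally reliable.

Loci are then filtered on three repeatability criteria before any distance
or clustering analysis: the fraction of isolates with a *strong* replicate
disagreement (one replicate >= t_high, the other < t_low), polymorphism, and
consistency of the plate-control isolate across plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinaryProfileMatrix, IntensityTable
from .errors import ValidationError

__all__ = [
    "ScoringThresholds",
    "LocusQuality",
    "score_band",
    "score_matrix",
    "filter_loci",
]


@dataclass(frozen=True)
class ScoringThresholds:
    """Presence-calling thresholds in relative fluorescence units."""

    t_high: float = 100.0
    t_low: float = 50.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_low <= self.t_high):
            raise ValidationError(
                f"thresholds must satisfy 0 <= t_low <= t_high, got "
                f"t_low={self.t_low}, t_high={self.t_high}"
            )


@dataclass(frozen=True)
class LocusQuality:
    """Per-locus repeatability diagnostics.

    conflict_fraction
        Share of isolates with a strong replicate disagreement at this locus
        (one replicate >= t_high while the other < t_low).  Mid-zone
        disagreements are resolved by the scoring rule itself and do not
        count as conflicts.
    is_polymorphic
        Both call values (0 and 1) observed among the scored isolates.
    control_consistent
        The designated plate-control isolate received identical calls on
        every plate (vacuously true when no control is designated).
    """

    locus_id: str
    conflict_fraction: float
    is_polymorphic: bool
    control_consistent: bool


DEFAULT_THRESHOLDS = ScoringThresholds()


def score_band(i1: float, i2: float, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS) -> int:
    """Call one band from its two replicate intensities.

    Returns 1 iff the stronger replicate reaches ``t_high`` and the weaker
    at least ``t_low``; symmetric in its arguments and monotone in each.
    """
    if i1 < 0 or i2 < 0:
        raise ValidationError(f"intensities must be non-negative, got ({i1}, {i2})")
    hi, lo = (i1, i2) if i1 >= i2 else (i2, i1)
    return int(hi >= thresholds.t_high and lo >= thresholds.t_low)


def _replicate_pivot(table: IntensityTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (rep1, rep2) intensity frames indexed by (isolate, plate) x locus.

    A locus missing from an isolate's records is a zero-intensity band in
    both replicates: fragment tables conventionally omit absent peaks.
    """
    df = table.records
    counts = df.pivot_table(
        index=["isolate_id", "plate_id"],
        columns="locus_id",
        values="intensity",
        aggfunc="size",
        fill_value=0,
    )
    bad = np.argwhere((counts.to_numpy() != 0) & (counts.to_numpy() != 2))
    if len(bad):
        r, c = bad[0]
        iso, plate = counts.index[r]
        raise ValidationError(
            f"isolate {iso!r} has {counts.iat[r, c]} replicate(s) (expected 2) "
            f"at locus {counts.columns[c]!r} on plate {plate!r}"
        )
    loci = list(dict.fromkeys(df["locus_id"]))
    frames = []
    for rep in (1, 2):
        piv = df[df["replicate"] == rep].pivot_table(
            index=["isolate_id", "plate_id"],
            columns="locus_id",
            values="intensity",
            fill_value=0.0,
        )
        frames.append(piv.reindex(columns=loci, fill_value=0.0))
    r1, r2 = frames
    idx = r1.index.union(r2.index)
    return (
        r1.reindex(idx, fill_value=0.0),
        r2.reindex(idx, fill_value=0.0),
    )


def score_matrix(
    table: IntensityTable,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
    control_isolate: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> tuple[BinaryProfileMatrix, list[LocusQuality]]:
    """Score every isolate x locus call and compute per-locus quality.

    Non-control isolates must appear on exactly one plate.  The control
    isolate (if designated) is scored on its lexicographically first plate
    for the output matrix; its per-plate calls feed ``control_consistent``.
    """
    rep1, rep2 = _replicate_pivot(table)
    loci = list(rep1.columns)
    a1, a2 = rep1.to_numpy(), rep2.to_numpy()
    hi = np.maximum(a1, a2)
    lo = np.minimum(a1, a2)
    calls = ((hi >= thresholds.t_high) & (lo >= thresholds.t_low)).astype(np.int8)
    conflicts = (hi >= thresholds.t_high) & (lo < thresholds.t_low)

    pairs = list(rep1.index)  # (isolate, plate)
    by_isolate: dict[str, list[int]] = {}
    for row, (iso, _plate) in enumerate(pairs):
        by_isolate.setdefault(iso, []).append(row)
    for iso, rows in by_isolate.items():
        if len(rows) > 1 and iso != control_isolate:
            plates = sorted(pairs[r][1] for r in rows)
            raise ValidationError(
                f"isolate {iso!r} appears on multiple plates {plates}; only the "
                "designated control isolate may (pass control_isolate=...)"
            )
    if control_isolate is not None and control_isolate not in by_isolate:
        raise ValidationError(f"control isolate {control_isolate!r} not in table")

    # one row per isolate, input order; control uses its first plate
    order = [iso for iso in table.isolate_ids if iso in by_isolate]
    home_rows = []
    for iso in order:
        rows = by_isolate[iso]
        rows.sort(key=lambda r: pairs[r][1])
        home_rows.append(rows[0])
    home_rows = np.asarray(home_rows)
    matrix = BinaryProfileMatrix(
        pd.DataFrame(calls[home_rows], index=order, columns=loci),
        metadata=metadata,
    )

    n_iso = len(order)
    conflict_fraction = conflicts[home_rows].sum(axis=0) / n_iso
    poly = np.array(
        [len(np.unique(calls[home_rows, j])) == 2 for j in range(len(loci))]
    )
    if control_isolate is not None:
        ctrl_rows = by_isolate[control_isolate]
        ctrl_calls = calls[ctrl_rows]
        control_ok = (ctrl_calls == ctrl_calls[0]).all(axis=0)
    else:
        control_ok = np.ones(len(loci), dtype=bool)

    quality = [
        LocusQuality(
            locus_id=loc,
            conflict_fraction=float(conflict_fraction[j]),
            is_polymorphic=bool(poly[j]),
            control_consistent=bool(control_ok[j]),
        )
        for j, loc in enumerate(loci)
    ]
    return matrix, quality


def filter_loci(
    matrix: BinaryProfileMatrix,
    quality: list[LocusQuality],
    max_conflict: float = 0.05,
    require_polymorphic: bool = True,
    require_control_consistent: bool = True,
) -> BinaryProfileMatrix:
    """Retain repeatable, informative loci; isolate set and locus order kept."""
    qual_by_locus = {q.locus_id: q for q in quality}
    missing = [l for l in matrix.locus_ids if l not in qual_by_locus]
    if missing:
        raise ValidationError(f"quality records missing for locus/loci {missing[:5]}")
    keep = []
    for locus in matrix.locus_ids:
        q = qual_by_locus[locus]
        if q.conflict_fraction > max_conflict:
            continue
        if require_polymorphic and not q.is_polymorphic:
            continue
        if require_control_consistent and not q.control_consistent:
            continue
        keep.append(locus)
    if not keep:
        raise ValidationError(
            "locus filter removed every locus; relax max_conflict or the "
            "polymorphism/control requirements"
        )
    return matrix.select_loci(keep)


def quality_report(quality: list[LocusQuality]) -> pd.DataFrame:
    """Locus-quality diagnostics as a tidy frame (for the TSV report)."""
    return pd.DataFrame(
        {
            "locus_id": [q.locus_id for q in quality],
            "conflict_fraction": [q.conflict_fraction for q in quality],
            "is_polymorphic": [int(q.is_polymorphic) for q in quality],
            "control_consistent": [int(q.control_consistent) for q in quality],
        }
    )
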