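"""In-memory containers for AFLP fragment data.

Two containers carry the pipeline state: :class:`IntensityTable` holds raw
per-band fluorescence signals (one row per isolate x technical replicate x
plate x locus, in relative fluorescence units, RFU), and
:class:`BinaryProfileMatrix` holds the 0/1 presence calls derived from them
together with per-isolate metadata (area, crop, origin).

A single *plate-control* isolate may legitimately appear on several 96-well
plates — that is its purpose, detecting plate-specific variation — so record
uniqueness is keyed on (isolate, replicate, plate, locus).  Every other
isolate is expected on exactly one plate; the scoring step enforces that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

INTENSITY_COLUMNS = ("isolate_id", "replicate", "plate_id", "locus_id", "intensity")
METADATA_COLUMNS = ("isolate_id", "area", "crop", "origin")


@dataclass
class IntensityTable:
    """Raw fragment-analysis signals, one record per band measurement.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``isolate_id, replicate, plate_id, locus_id, intensity``.
        ``replicate`` is 1 or 2 (dual technical replicates of the whole
        AFLP procedure); ``intensity`` is a non-negative RFU value.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INTENSITY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"intensity table missing column(s): {missing}")
        self.records = self.records.loc[:, list(INTENSITY_COLUMNS)].reset_index(drop=True)
        self.records["replicate"] = self.records["replicate"].astype(int)
        self.records["intensity"] = self.records["intensity"].astype(float)
        self.validate()

    def validate(self) -> None:
        df = self.records
        bad_rep = df.loc[~df["replicate"].isin((1, 2))]
        if len(bad_rep):
            raise ValidationError(
                f"replicate must be 1 or 2; offending rows {bad_rep.index.tolist()[:5]}"
            )
        neg = df.loc[df["intensity"] < 0]
        if len(neg):
            keys = neg[["isolate_id", "locus_id"]].values.tolist()[:5]
            raise ValidationError(f"negative intensity for {keys}")
        key = ["isolate_id", "replicate", "plate_id", "locus_id"]
        dup = df.loc[df.duplicated(key, keep=False)]
        if len(dup):
            offenders = dup[key].drop_duplicates().values.tolist()[:5]
            raise ValidationError(
                f"duplicate (isolate, replicate, plate, locus) record(s): {offenders}"
            )
        # dual-replicate pairing: replicate 1 and 2 must cover the same loci
        counts = df.pivot_table(
            index=["isolate_id", "plate_id", "locus_id"],
            columns="replicate",
            values="intensity",
            aggfunc="size",
            fill_value=0,
        )
        for rep in (1, 2):
            if rep not in counts.columns:
                counts[rep] = 0
        unpaired = counts[(counts[1] != counts[2])]
        if len(unpaired):
            raise ValidationError(
                "replicate 1/2 loci differ for "
                f"{[tuple(i) for i in unpaired.index[:5]]}"
            )

    @property
    def isolate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["isolate_id"]))

    @property
    def locus_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["locus_id"]))

    @property
    def plate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["plate_id"]))

    def __len__(self) -> int:
        return len(self.records)


def _check_metadata(metadata: pd.DataFrame, isolate_ids) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns and c != "isolate_id"]
    if "isolate_id" in metadata.columns:
        metadata = metadata.set_index("isolate_id")
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].tolist()
        raise ValidationError(f"duplicate metadata rows for isolate(s): {dups}")
    absent = [i for i in isolate_ids if i not in metadata.index]
    if absent:
        raise ValidationError(f"isolate(s) missing metadata: {absent[:5]}")
    return metadata


@dataclass
class BinaryProfileMatrix:
    """Presence/absence calls per isolate x locus, with optional metadata.

    ``calls`` is an isolate-by-locus DataFrame of {0,1}; row order is the
    isolate order, column order the locus order, both preserved by every
    operation in the package.
    """

    calls: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        values = self.calls.to_numpy()
        ok = np.isin(values, (0, 1))
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValidationError(
                f"non-binary entry {values[r, c]!r} at "
                f"(row {self.calls.index[r]!r}, column {self.calls.columns[c]!r})"
            )
        self.calls = self.calls.astype(np.int8)
        if self.calls.index.has_duplicates:
            raise ValidationError("duplicate isolate ids in matrix")
        if self.calls.columns.has_duplicates:
            raise ValidationError("duplicate locus ids in matrix")
        if self.metadata is not None:
            self.metadata = _check_metadata(self.metadata, self.calls.index)

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_isolates(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def profile(self, isolate_id: str) -> np.ndarray:
        return self.calls.loc[isolate_id].to_numpy()

    def select_loci(self, locus_ids) -> "BinaryProfileMatrix":
        return BinaryProfileMatrix(self.calls.loc[:, list(locus_ids)], self.metadata)
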