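"""Pearson chi-square tests of isolate frequency distributions.

Two classical tests cover the survey questions: an r x c contingency test of
homogeneity (are isolate counts distributed independently of area and
crop?), and a one-way goodness-of-fit test of observed counts against a
stated expectation (uniform by default).  Both are plain Pearson statistics
without continuity correction; small expected counts are logged as a
warning but never alter the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "chi2_contingency",
    "chi2_goodness_of_fit",
]

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Non-negative integer counts cross-classified by two factors."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-d array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        if len(self.row_labels) < 2 and len(self.col_labels) < 2:
            raise ValidationError("need at least 2 rows or 2 columns")
        self.counts = self.counts.astype(np.int64)

    @classmethod
    def from_metadata(
        cls, metadata: pd.DataFrame, rows: str = "area", cols: str = "crop"
    ) -> "ContingencyTable":
        """Cross-tabulate isolate metadata into a counts table."""
        tab = pd.crosstab(metadata[rows], metadata[cols])
        return cls(
            row_labels=[str(r) for r in tab.index],
            col_labels=[str(c) for c in tab.columns],
            counts=tab.to_numpy(),
        )

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi2_contingency(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity on an r x c table.

    Expected counts are ``row total x column total / grand total``; an
    all-zero row or column leaves them undefined and is an error.
    """
    counts = table.counts
    if counts.sum() == 0:
        raise ValidationError("contingency table is empty (grand total 0)")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValidationError(
            "all-zero row or column: expected counts undefined; drop it first"
        )
    res = scipy.stats.chi2_contingency(counts, correction=False)
    _warn_small_expected(res.expected_freq)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )


def chi2_goodness_of_fit(counts, expected="uniform") -> ChiSquareResult:
    """Pearson goodness-of-fit of a count vector against expected shares."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValidationError("counts must be a 1-d vector of length >= 2")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValidationError("counts sum to zero")
    k = counts.size
    if isinstance(expected, str) and expected == "uniform":
        probs = np.full(k, 1.0 / k)
    else:
        probs = np.asarray(expected, dtype=float)
        if probs.size != k:
            raise ValidationError("expected probabilities must match counts length")
        if np.any(probs <= 0):
            raise ValidationError("expected probabilities must be positive")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("expected probabilities must sum to 1")
    f_exp = total * probs
    _warn_small_expected(f_exp)
    stat, p = scipy.stats.chisquare(counts, f_exp=f_exp)
    return ChiSquareResult(statistic=float(stat), df=k - 1, p_value=float(p))


def _warn_small_expected(expected: np.ndarray) -> None:
    small = np.asarray(expected) < 5
    if small.any():
        logger.warning(
            "%d expected cell(s) below 5; the chi-square approximation may be "
            "poor (result reported unchanged)",
            int(small.sum()),
        )
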