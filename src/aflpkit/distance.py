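"""Pairwise Dice distances between binary AFLP profiles.

For two presence/absence profiles with ``a`` shared bands, and ``b`` / ``c``
bands private to either profile, the Dice similarity is ``2a / (2a + b + c)``
and the distance is its complement.  Shared absences never contribute — the
appropriate convention for dominant markers, where a missing band carries no
information about allelic state.

Two isolates with all-zero profiles have identical observations and get
distance 0 by default (consistent with exact-profile haplotype grouping);
pass ``zero_policy="error"`` to treat the undefined 0/0 similarity strictly.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .containers import BinaryProfileMatrix
from .errors import ValidationError

__all__ = ["dice_distance", "distance_matrix"]

_METRICS = ("dice", "jaccard")


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-d profile")
    if not np.isin(x, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0/1 entries")
    return x.astype(np.int64)


def dice_distance(x, y, metric: str = "dice", zero_policy: str = "zero") -> float:
    """Dice (default) or Jaccard distance between two binary profiles."""
    x = _check_binary(x, "x")
    y = _check_binary(y, "y")
    if x.size != y.size:
        raise ValidationError(f"profile length mismatch: {x.size} vs {y.size}")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if a + b + c == 0:
        if zero_policy == "error":
            raise ValidationError("distance undefined for two all-zero profiles")
        return 0.0
    if metric == "dice":
        return 1.0 - 2.0 * a / (2.0 * a + b + c)
    if metric == "jaccard":
        return 1.0 - a / (a + b + c)
    raise ValidationError(f"unknown metric {metric!r}; choose from {_METRICS}")


def distance_matrix(
    matrix: BinaryProfileMatrix, metric: str = "dice", zero_policy: str = "zero"
) -> DistanceMatrix:
    """All pairwise distances for a profile matrix, as a validated
    :class:`skbio.DistanceMatrix` (symmetric, zero-diagonal).
    """
    if matrix.n_isolates < 2:
        raise ValidationError("need at least 2 isolates for a distance matrix")
    if matrix.n_loci < 1:
        raise ValidationError("need at least 1 locus for a distance matrix")
    if metric not in _METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {_METRICS}")
    X = matrix.calls.to_numpy().astype(np.float64)
    return DistanceMatrix(
        _pairwise_from_array(X, metric, zero_policy), ids=matrix.isolate_ids
    )


def _pairwise_from_array(X: np.ndarray, metric: str, zero_policy: str) -> np.ndarray:
    """Vectorized pairwise distances on a 0/1 array (isolates x loci)."""
    A = X @ X.T                      # shared presences a_ij
    rows = X.sum(axis=1)             # per-isolate band counts = a + b
    if metric == "dice":
        denom = rows[:, None] + rows[None, :]          # 2a + b + c
        num = 2.0 * A
    else:  # jaccard
        denom = rows[:, None] + rows[None, :] - A      # a + b + c
        num = A
    both_empty = denom == 0
    if both_empty.any() and zero_policy == "error":
        raise ValidationError("distance undefined for two all-zero profiles")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(both_empty, 1.0, num / np.where(both_empty, 1.0, denom))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # exact symmetry against float noise
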