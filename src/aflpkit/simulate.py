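"""Synthetic AFLP fragment-intensity datasets with known ground truth.

The generator emulates the statistical structure of a dual-replicate AFLP
survey of a clonally reproducing fungus:

* a small number of clonal *lineages*, each with a fixed binary band
  profile (band present at a locus with probability ``p_present``);
* isolates drawn from lineages, with rare per-locus flips
  (``mutation_rate``) so most isolates reproduce their lineage profile;
* log-normal band intensities — present bands centred well above the
  confident calling threshold, background signal well below the
  reliability floor — with independent per-replicate dropout, so a truly
  present band can read as background in one replicate but not the other;
* multiplicative plate factors shared by all bands on a 96-well plate,
  plus a designated control isolate re-run on every plate so plate drift
  is detectable downstream;
* area x crop metadata, mixing a uniform draw (weight
  ``1 - association_strength``) with a lineage-specific habitat (weight
  ``association_strength``), so both the no-structure null and habitat-
  associated alternatives can be generated.

Defaults mirror the survey design this package targets: 93 isolates typed
at 230 candidate loci in 3 areas x 3 crops, dual technical replicates and
a shared plate-control isolate, with no habitat association.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import IntensityTable
from .errors import ValidationError
from .stats import ContingencyTable

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "simulate_contingency"]

DEFAULT_AREAS = ["Area1", "Area2", "Area3"]
DEFAULT_CROPS = ["oilseed_rape", "winter_wheat", "grass_pasture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate`.

    Intensity parameters are on the log scale of a log-normal: ``mu_*`` is
    the median intensity in RFU and ``sigma_*`` the log-scale spread.
    """

    n_isolates: int = 93
    n_loci: int = 230
    n_lineages: int = 78
    p_present: float = 0.3
    mutation_rate: float = 0.01
    mu_present: float = 800.0
    sigma_present: float = 0.4
    mu_absent: float = 10.0
    sigma_absent: float = 0.4
    dropout_prob: float = 0.05
    plate_effect_sd: float = 0.1
    n_plates: int = 3
    areas: tuple = tuple(DEFAULT_AREAS)
    crops: tuple = tuple(DEFAULT_CROPS)
    association_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_isolates", "n_loci", "n_lineages", "n_plates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.n_lineages > self.n_isolates:
            raise ValidationError("n_lineages must not exceed n_isolates")
        for name in ("p_present", "mutation_rate", "dropout_prob", "association_strength"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_present", "sigma_absent", "plate_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("mu_present", "mu_absent"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0 (log-normal median)")
        if not self.areas or not self.crops:
            raise ValidationError("areas and crops must be non-empty")


@dataclass
class GroundTruth:
    """What the generator knows and downstream analysis should recover."""

    lineage_of: dict[str, int]
    true_profiles: np.ndarray            # lineage x locus, 0/1
    isolate_profiles: pd.DataFrame       # isolate x locus truth after mutation
    metadata: pd.DataFrame               # isolate_id, area, crop, origin
    control_isolate: str
    plate_of: dict[str, str]


def simulate(config: SimulationConfig) -> tuple[IntensityTable, GroundTruth]:
    """Generate a fragment-intensity table plus its generating truth.

    Deterministic for a fixed seed.  Each isolate carries exactly two
    technical replicates on its assigned plate; the first isolate is the
    plate control and is re-run (both replicates) on every other plate.
    """
    rng = np.random.default_rng(config.seed)
    n, L, K = config.n_isolates, config.n_loci, config.n_lineages

    isolate_ids = [f"ISO{i + 1:03d}" for i in range(n)]
    locus_ids = [f"L{j + 1:04d}" for j in range(L)]
    plate_ids = [f"P{p + 1}" for p in range(config.n_plates)]

    lineage_profiles = (rng.random((K, L)) < config.p_present).astype(np.int8)
    # guarantee every lineage is represented at least once
    lineage_of = np.concatenate(
        [np.arange(K), rng.integers(0, K, size=n - K)]
    )
    flips = rng.random((n, L)) < config.mutation_rate
    truth = np.where(flips, 1 - lineage_profiles[lineage_of], lineage_profiles[lineage_of])

    plate_assign = np.array_split(np.arange(n), config.n_plates)
    plate_of = {}
    for p, rows in enumerate(plate_assign):
        for r in rows:
            plate_of[isolate_ids[r]] = plate_ids[p]
    control = isolate_ids[0]
    plate_factors = np.exp(rng.normal(0.0, config.plate_effect_sd, size=config.n_plates))
    factor_of = dict(zip(plate_ids, plate_factors))

    # habitat: each lineage prefers one (area, crop) cell, round-robin
    cells = [(a, c) for a in config.areas for c in config.crops]
    preferred = [cells[k % len(cells)] for k in range(K)]
    areas = []
    crops = []
    for i in range(n):
        if rng.random() < config.association_strength:
            a, c = preferred[lineage_of[i]]
        else:
            a = config.areas[rng.integers(0, len(config.areas))]
            c = config.crops[rng.integers(0, len(config.crops))]
        areas.append(a)
        crops.append(c)
    metadata = pd.DataFrame(
        {
            "isolate_id": isolate_ids,
            "area": areas,
            "crop": crops,
            "origin": "study",
        }
    )

    log_mu_p, log_mu_a = np.log(config.mu_present), np.log(config.mu_absent)

    def draw_block(profile: np.ndarray, plate: str) -> np.ndarray:
        """Intensities for one isolate on one plate: 2 replicates x L loci."""
        out = np.empty((2, L))
        for rep in range(2):
            z = rng.normal(0.0, 1.0, size=L)
            present = profile.astype(bool)
            dropped = present & (rng.random(L) < config.dropout_prob)
            signal = np.where(
                present & ~dropped,
                np.exp(log_mu_p + config.sigma_present * z),
                np.exp(log_mu_a + config.sigma_absent * z),
            )
            out[rep] = signal * factor_of[plate]
        return out

    rows_iso, rows_rep, rows_plate, rows_locus, rows_int = [], [], [], [], []

    def emit(iso: str, plate: str, block: np.ndarray) -> None:
        for rep in range(2):
            rows_iso.extend([iso] * L)
            rows_rep.extend([rep + 1] * L)
            rows_plate.extend([plate] * L)
            rows_locus.extend(locus_ids)
            rows_int.extend(block[rep])

    for i, iso in enumerate(isolate_ids):
        emit(iso, plate_of[iso], draw_block(truth[i], plate_of[iso]))
    for plate in plate_ids:
        if plate != plate_of[control]:
            emit(control, plate, draw_block(truth[0], plate))

    table = IntensityTable(
        pd.DataFrame(
            {
                "isolate_id": rows_iso,
                "replicate": rows_rep,
                "plate_id": rows_plate,
                "locus_id": rows_locus,
                "intensity": rows_int,
            }
        )
    )
    ground_truth = GroundTruth(
        lineage_of={iso: int(k) for iso, k in zip(isolate_ids, lineage_of)},
        true_profiles=lineage_profiles,
        isolate_profiles=pd.DataFrame(truth, index=isolate_ids, columns=locus_ids),
        metadata=metadata,
        control_isolate=control,
        plate_of=plate_of,
    )
    return table, ground_truth


def simulate_contingency(
    row_probs, col_probs, n: int, association: float = 0.0, seed: int = 0
) -> ContingencyTable:
    """Multinomial r x c count table; ``association=0`` gives independent
    margins (the null of the homogeneity test).

    With association ``a``, cell probabilities mix the independent product
    (weight 1-a) with a coupling that concentrates each row's mass on one
    preferred column (row i -> column i mod c).
    """
    row_probs = np.asarray(row_probs, dtype=float)
    col_probs = np.asarray(col_probs, dtype=float)
    for name, p in (("row_probs", row_probs), ("col_probs", col_probs)):
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} must be non-negative and sum to 1")
    if n < 1:
        raise ValidationError("n must be a positive integer")
    if not (0.0 <= association <= 1.0):
        raise ValidationError("association must be in [0, 1]")
    r, c = row_probs.size, col_probs.size
    P = np.outer(row_probs, col_probs)
    coupled = np.zeros((r, c))
    for i in range(r):
        coupled[i, i % c] = row_probs[i]
    P = (1.0 - association) * P + association * coupled
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, P.ravel()).reshape(r, c)
    return ContingencyTable(
        row_labels=[f"R{i + 1}" for i in range(r)],
        col_labels=[f"C{j + 1}" for j in range(c)],
        counts=counts,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["areas"] = list(d["areas"])
    d["crops"] = list(d["crops"])
    return d
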