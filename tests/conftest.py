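import numpy as np
import pandas as pd
import pytest

from aflpkit import BinaryProfileMatrix, IntensityTable, SimulationConfig, simulate


def make_intensity_table(rows):
    """rows: iterable of (isolate, replicate, plate, locus, intensity)."""
    return IntensityTable(
        pd.DataFrame(
            rows,
            columns=["isolate_id", "replicate", "plate_id", "locus_id", "intensity"],
        )
    )


def dual(iso, plate, locus, i1, i2):
    return [(iso, 1, plate, locus, i1), (iso, 2, plate, locus, i2)]


@pytest.fixture
def small_matrix():
    calls = pd.DataFrame(
        [[1, 1, 0, 1, 0], [1, 0, 0, 1, 1], [0, 1, 1, 0, 0]],
        index=["A", "B", "C"],
        columns=["L1", "L2", "L3", "L4", "L5"],
    )
    return BinaryProfileMatrix(calls)


@pytest.fixture
def metadata3():
    return pd.DataFrame(
        {
            "isolate_id": ["A", "B", "C"],
            "area": ["north", "north", "south"],
            "crop": ["wheat", "rape", "wheat"],
            "origin": ["study", "study", "external"],
        }
    ).set_index("isolate_id")


NOISE_FREE = dict(
    n_isolates=12,
    n_loci=15,
    n_lineages=3,
    mutation_rate=0.0,
    dropout_prob=0.0,
    mu_present=800.0,
    mu_absent=10.0,
    sigma_present=0.05,
    sigma_absent=0.05,
    n_plates=2,
    seed=1,
)


@pytest.fixture
def noise_free_sim():
    cfg = SimulationConfig(**NOISE_FREE)
    table, truth = simulate(cfg)
    return cfg, table, truth


def two_block_matrix(n_per_block=4, n_loci=15):
    """Two isolate blocks differing at every locus (maximal separation)."""
    top = np.tile([1] * n_loci, (n_per_block, 1))
    bottom = np.tile([0] * n_loci, (n_per_block, 1))
    # make bottom block non-empty profiles: invert half the loci instead
    top = np.zeros((n_per_block, n_loci), dtype=int)
    top[:, : n_loci // 2 + 1] = 1
    bottom = 1 - top
    calls = pd.DataFrame(
        np.vstack([top, bottom]),
        index=[f"A{i}" for i in range(n_per_block)]
        + [f"B{i}" for i in range(n_per_block)],
        columns=[f"L{j}" for j in range(n_loci)],
    )
    return BinaryProfileMatrix(calls)
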