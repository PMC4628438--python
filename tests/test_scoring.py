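import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aflpkit import (
    ScoringThresholds,
    ValidationError,
    filter_loci,
    score_band,
    score_matrix,
)
from conftest import dual, make_intensity_table


def prose_rule(i1, i2, t_high=100.0, t_low=50.0):
    """Literal transcription of the published four-branch calling rule,
    with the documented inclusive boundaries (>= at both thresholds)."""
    if i1 >= t_high and i2 >= t_high:
        return 1  # confident in both replicates
    if min(i1, i2) < t_low:
        return 0  # either replicate below the reliability floor
    if max(i1, i2) >= t_high and min(i1, i2) >= t_low:
        return 1  # disagreement: one confident, the other reliable
    return 0  # both below the confident threshold


class TestScoreBand:
    @pytest.mark.parametrize(
        "i1,i2,expected",
        [
            (150, 120, 1),   # both confident
            (150, 60, 1),    # disagreement, weaker still reliable
            (150, 40, 0),    # weaker below the floor
            (90, 95, 0),     # neither confident
            (100, 50, 1),    # inclusive boundaries
            (100, 49, 0),
            (99, 99, 0),
        ],
    )
    def test_examples(self, i1, i2, expected):
        assert score_band(i1, i2) == expected

    def test_closed_form_matches_prose_rule_on_grid(self):
        grid = [0, 49, 50, 51, 99, 100, 101, 500]
        for i1, i2 in itertools.product(grid, grid):
            assert score_band(i1, i2) == prose_rule(i1, i2), (i1, i2)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            score_band(-1, 100)

    @settings(max_examples=200, deadline=None)
    @given(
        i1=st.floats(0, 1000, allow_nan=False),
        i2=st.floats(0, 1000, allow_nan=False),
        bump=st.floats(0, 500, allow_nan=False),
    )
    def test_symmetric_and_monotone(self, i1, i2, bump):
        assert score_band(i1, i2) == score_band(i2, i1)
        # raising either intensity never flips a present call to absent
        assert score_band(i1 + bump, i2) >= score_band(i1, i2)
        assert score_band(i1, i2 + bump) >= score_band(i1, i2)

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            ScoringThresholds(t_high=50, t_low=100)


class TestScoreMatrix:
    def test_all_strong_signals_monomorphic_ones(self):
        rows = []
        for iso in ("A", "B"):
            for locus in ("L1", "L2"):
                rows += dual(iso, "P1", locus, 800, 800)
        matrix, quality = score_matrix(make_intensity_table(rows))
        assert matrix.calls.to_numpy().tolist() == [[1, 1], [1, 1]]
        assert all(not q.is_polymorphic for q in quality)

    def test_polymorphic_locus_and_zero_conflict(self):
        rows = dual("A", "P1", "L1", 800, 800) + dual("B", "P1", "L1", 10, 12)
        matrix, quality = score_matrix(make_intensity_table(rows))
        assert matrix.calls["L1"].tolist() == [1, 0]
        assert quality[0].is_polymorphic
        assert quality[0].conflict_fraction == 0

    def test_strong_disagreement_counts_as_conflict(self):
        rows = dual("A", "P1", "L1", 800, 20) + dual("B", "P1", "L1", 800, 900)
        matrix, quality = score_matrix(make_intensity_table(rows))
        assert matrix.calls.loc["A", "L1"] == 0
        assert quality[0].conflict_fraction == pytest.approx(1 / 2)

    def test_missing_locus_is_zero_intensity(self):
        rows = (
            dual("A", "P1", "L1", 800, 800)
            + dual("A", "P1", "L2", 700, 700)
            + dual("B", "P1", "L1", 600, 600)
        )  # B has no L2 records
        matrix, _ = score_matrix(make_intensity_table(rows))
        assert matrix.calls.loc["B", "L2"] == 0

    def test_control_consistency_across_plates(self):
        rows = (
            dual("CTRL", "P1", "L1", 800, 800)
            + dual("CTRL", "P2", "L1", 10, 10)   # plate drift flips the call
            + dual("B", "P1", "L1", 600, 600)
        )
        _, quality = score_matrix(
            make_intensity_table(rows), control_isolate="CTRL"
        )
        assert not quality[0].control_consistent

    def test_non_control_isolate_on_two_plates_rejected(self):
        rows = dual("A", "P1", "L1", 800, 800) + dual("A", "P2", "L1", 800, 800)
        with pytest.raises(ValidationError, match="multiple plates"):
            score_matrix(make_intensity_table(rows))


class TestFilterLoci:
    def make_scored(self, with_conflict=False):
        rows = []
        specs = {
            "L1": [(800, 800), (10, 10)],
            "L2": [(10, 10), (800, 800)],
            "L3": [(800, 800), (800, 800)],   # monomorphic all-ones
            "L4": [(800, 20), (10, 10)],      # strong conflict in isolate A
        }
        for locus, ((a1, a2), (b1, b2)) in specs.items():
            rows += dual("A", "P1", locus, a1, a2) + dual("B", "P1", locus, b1, b2)
        return score_matrix(make_intensity_table(rows))

    def test_conflicted_locus_dropped_at_zero_tolerance(self):
        matrix, quality = self.make_scored()
        kept = filter_loci(matrix, quality, max_conflict=0.0, require_polymorphic=False)
        assert kept.locus_ids == ["L1", "L2", "L3"]

    def test_monomorphic_locus_dropped(self):
        matrix, quality = self.make_scored()
        kept = filter_loci(matrix, quality, max_conflict=1.0, require_polymorphic=True)
        assert "L3" not in kept.locus_ids

    def test_idempotent(self):
        matrix, quality = self.make_scored()
        once = filter_loci(matrix, quality, max_conflict=0.0)
        again = filter_loci(once, quality, max_conflict=0.0)
        assert once.locus_ids == again.locus_ids

    def test_all_removed_is_error(self):
        matrix, quality = self.make_scored()
        with pytest.raises(ValidationError, match="relax"):
            filter_loci(
                matrix,
                [q.__class__(q.locus_id, 1.0, q.is_polymorphic, q.control_consistent)
                 for q in quality],
                max_conflict=0.0,
            )

    def test_retained_set_matches_per_locus_recount(self):
        """Independent locus-by-locus recount on a noisy simulation."""
        from aflpkit import SimulationConfig, simulate

        cfg = SimulationConfig(
            n_isolates=20, n_loci=30, n_lineages=4, mutation_rate=0.0,
            dropout_prob=0.3, seed=7,
        )
        table, truth = simulate(cfg)
        matrix, quality = score_matrix(table, control_isolate=truth.control_isolate)
        kept = filter_loci(matrix, quality, max_conflict=0.05,
                           require_polymorphic=False,
                           require_control_consistent=False)

        # brute-force recount: per locus, fraction of isolates whose two
        # replicate intensities straddle the thresholds
        df = table.records
        expect = []
        for locus in matrix.locus_ids:
            n_conflict = 0
            for iso in matrix.isolate_ids:
                sub = df[(df.isolate_id == iso) & (df.locus_id == locus)
                         & (df.plate_id == truth.plate_of[iso])]
                i1, i2 = sub.sort_values("replicate")["intensity"].tolist()
                if max(i1, i2) >= 100 and min(i1, i2) < 50:
                    n_conflict += 1
            if n_conflict / matrix.n_isolates <= 0.05:
                expect.append(locus)
        assert kept.locus_ids == expect
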