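"""Fold-change arithmetic and dorsoventral/temporal classification."""

import math

import numpy as np
import pandas as pd
import pytest

from irisgradient import (
    ExpressionTable,
    build_gradient_table,
    build_temporal_table,
    classify_dorsoventral,
    classify_temporal,
    combined_log2_fold_change,
    estimate_cutoffs,
    log2_fold_change,
    map_spots_to_transcripts,
    select_null_spots,
)
from irisgradient.io import load_reference_gradient_table

from conftest import make_expression


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (4.549, 0.272, 4.062),  # published TBX5-transcript day-4 ratio
            (2.527, 0.193, 3.713),  # published HERC2-like day-8 ratio
            (3.0, 3.0, 0.0),
        ],
    )
    def test_defined_values(self, num, den, expected):
        assert log2_fold_change(num, den) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("num, den", [(4.070, 0.0), (0.0, 4.070), (0.0, 0.0)])
    def test_one_sided_zero_is_undefined(self, num, den):
        assert math.isnan(log2_fold_change(num, den))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 2.0)


class TestCombinedLog2FoldChange:
    @pytest.mark.parametrize(
        "d4, d8, v4, v8, expected",
        [
            (4.549, 12.007, 0.272, 0.248, 4.990),  # dorsal TBX5-like
            (0.141, 0.066, 5.052, 7.897, -5.965),  # ventral netrin-1-like
            (5.828, 19.812, 0.331, 0.151, 5.735),
            (0.0, 0.124, 2.200, 3.177, -5.437),  # zero day-4 dorsal, still defined
            (2.0, 3.0, 2.0, 3.0, 0.0),
        ],
    )
    def test_sum_ratio_definition(self, d4, d8, v4, v8, expected):
        assert combined_log2_fold_change(d4, d8, v4, v8) == pytest.approx(
            expected, abs=0.02
        )

    def test_zero_sum_is_undefined(self):
        assert math.isnan(combined_log2_fold_change(0.0, 0.0, 1.0, 1.0))
        assert math.isnan(combined_log2_fold_change(1.0, 1.0, 0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            combined_log2_fold_change(1.0, 1.0, -0.5, 1.0)


@pytest.mark.parametrize("which", ["dorsal", "ventral"])
def test_reference_tables_reproduce_printed_columns(which):
    """Recomputing the three log2 columns from the printed RPKM quadruples
    matches every defined printed value within +-0.02 and reproduces every
    undefined placeholder."""
    ref = load_reference_gradient_table(which)
    assert len(ref) == 50
    for tid, row in ref.iterrows():
        fc4 = log2_fold_change(row["d4"], row["v4"])
        fc8 = log2_fold_change(row["d8"], row["v8"])
        fc = combined_log2_fold_change(row["d4"], row["d8"], row["v4"], row["v8"])
        for printed, recomputed in (
            (row["log2fc4"], fc4),
            (row["log2fc8"], fc8),
            (row["log2fc"], fc),
        ):
            if math.isnan(printed):
                assert math.isnan(recomputed), tid
            else:
                assert recomputed == pytest.approx(printed, abs=0.02), tid
                assert math.copysign(1, recomputed) == math.copysign(1, printed)


def _quads(v4, d4, v8, d8):
    rpkm = {"4dv": v4, "4dd": d4, "8dv": v8, "8dd": d8}
    counts = {k: (1 if v > 0 else 0) for k, v in rpkm.items()}
    return counts, rpkm


class TestClassifyDorsoventral:
    def test_published_exclusive_row(self, study_cutoffs):
        counts, rpkm = _quads(0.0, 2.987, 0.0, 1.296)
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "dorsal_exclusive"

    def test_published_dorsal_up_row(self, study_cutoffs):
        counts, rpkm = _quads(0.272, 4.549, 0.248, 12.007)
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "dorsal_up"

    def test_equal_sides_unclassified(self, study_cutoffs):
        counts, rpkm = _quads(5.0, 5.0, 5.0, 5.0)
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "unclassified"

    def test_sub_cutoff_zero_is_not_exclusive(self, study_cutoffs):
        # dorsal side below its cutoffs: structure alone does not qualify
        counts, rpkm = _quads(0.0, 0.9, 0.0, 0.9)
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "unclassified"

    def test_zero_rpkm_with_reads_is_not_exclusive(self, study_cutoffs):
        # ventral reads exist (so not exclusive) yet ventral RPKM rounds to 0
        counts = {"4dv": 3, "4dd": 100, "8dv": 2, "8dd": 100}
        rpkm = {"4dv": 0.0, "4dd": 5.0, "8dv": 0.0, "8dd": 5.0}
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "dorsal_up"

    def test_inclusive_vs_strict_threshold(self, study_cutoffs):
        counts, rpkm = _quads(2.0, 4.0, 2.0, 4.0)  # exactly 2-fold both days
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "dorsal_up"
        assert (
            classify_dorsoventral(counts, rpkm, study_cutoffs, inclusive=False)
            == "unclassified"
        )

    def test_require_both_sides_flag(self, study_cutoffs):
        counts, rpkm = _quads(0.2, 4.0, 0.2, 4.0)  # ventral below cutoff
        assert classify_dorsoventral(counts, rpkm, study_cutoffs) == "dorsal_up"
        assert (
            classify_dorsoventral(
                counts, rpkm, study_cutoffs, require_both_sides=True
            )
            == "unclassified"
        )

    def test_threshold_monotonicity(self, study_cutoffs):
        """Raising the fold threshold never grows the up-regulated calls."""
        rng = np.random.default_rng(3)
        quads = rng.lognormal(0.5, 1.5, size=(200, 4))
        thresholds = (1.5, 2.0, 4.0, 8.0)
        previous = None
        for thr in thresholds:
            admitted = set()
            for i, q in enumerate(quads):
                counts, rpkm = _quads(*q)
                cls = classify_dorsoventral(
                    counts, rpkm, study_cutoffs, fold_threshold=thr
                )
                if cls in ("dorsal_up", "ventral_up"):
                    admitted.add(i)
            if previous is not None:
                assert admitted <= previous
            previous = admitted

    def test_antisymmetry(self, study_cutoffs):
        """Swapping sides negates defined folds and mirrors the classes."""
        sym_cutoffs = study_cutoffs  # asymmetric cutoffs would break the mirror
        from irisgradient import CutoffSet

        sym_cutoffs = CutoffSet(
            cutoffs={"4dv": 1.0, "4dd": 1.0, "8dv": 1.0, "8dd": 1.0},
            null_transcripts=frozenset(),
        )
        rng = np.random.default_rng(5)
        mirror = {
            "dorsal_up": "ventral_up",
            "ventral_up": "dorsal_up",
            "dorsal_exclusive": "ventral_exclusive",
            "ventral_exclusive": "dorsal_exclusive",
            "unclassified": "unclassified",
        }
        for q in rng.lognormal(0.5, 1.5, size=(100, 4)):
            v4, d4, v8, d8 = q
            counts, rpkm = _quads(v4, d4, v8, d8)
            sw_counts, sw_rpkm = _quads(d4, v4, d8, v8)
            assert classify_dorsoventral(sw_counts, sw_rpkm, sym_cutoffs) == mirror[
                classify_dorsoventral(counts, rpkm, sym_cutoffs)
            ]
            fc = combined_log2_fold_change(d4, d8, v4, v8)
            fc_sw = combined_log2_fold_change(v4, v8, d4, d8)
            assert fc_sw == pytest.approx(-fc, abs=1e-12)

    def test_missing_condition_raises(self, study_cutoffs):
        with pytest.raises(KeyError):
            classify_dorsoventral({"4dv": 1}, {"4dv": 1.0}, study_cutoffs)
        counts, rpkm = _quads(1, 2, 1, 2)
        with pytest.raises(ValueError):
            classify_dorsoventral(counts, rpkm, study_cutoffs, fold_threshold=1.0)


class TestClassifyTemporal:
    CUTS = None

    @pytest.fixture(autouse=True)
    def _cuts(self):
        from irisgradient import CutoffSet

        self.CUTS = CutoffSet(
            cutoffs={c: 1.0 for c in ("4dv", "4dd", "8dv", "8dd")},
            null_transcripts=frozenset(),
        )

    def rpkm(self, d4, d8, v4, v8):
        return {"4dd": d4, "8dd": d8, "4dv": v4, "8dv": v8}

    def test_both_sides_up_at_day4(self):
        assert (
            classify_temporal(self.rpkm(10, 1, 8, 1), self.CUTS) == "day4_up"
        )

    def test_one_side_below_fold_is_neither(self):
        assert classify_temporal(self.rpkm(10, 1, 1.5, 1), self.CUTS) == "neither"

    def test_strict_threshold(self):
        # exactly 2-fold does not pass the strictly-more-than rule
        assert classify_temporal(self.rpkm(4, 2, 4, 2), self.CUTS) == "neither"

    def test_zero_denominator_passes(self):
        assert classify_temporal(self.rpkm(10, 1, 8, 0), self.CUTS) == "day4_up"

    def test_day8_direction(self):
        rp = self.rpkm(1, 10, 1, 8)
        assert classify_temporal(rp, self.CUTS, direction="day8_vs_day4") == "day8_up"
        assert classify_temporal(rp, self.CUTS) == "neither"

    def test_expression_gate_on_day_of_interest(self):
        # big fold but below cutoff at day 4
        assert classify_temporal(self.rpkm(0.9, 0.1, 0.9, 0.1), self.CUTS) == "neither"


class TestBuildGradientTable:
    def test_empty_expression_gives_empty_table(self, study_cutoffs):
        table = build_gradient_table(make_expression({}), study_cutoffs)
        assert table.empty

    def test_planted_transcript_ranks_first(self, study_cutoffs):
        expr = make_expression(
            {
                "plant": (0.5, 64.0, 0.5, 64.0),
                "flat1": (5.0, 5.0, 5.0, 5.0),
                "flat2": (7.0, 6.0, 7.0, 6.0),
            }
        )
        table = build_gradient_table(expr, study_cutoffs)
        assert table.index[0] == "plant"
        assert table.loc["plant", "dv_class"] == "dorsal_up"

    def test_sorting_descending_with_nan_last_and_id_ties(self, study_cutoffs):
        expr = make_expression(
            {
                "b": (1.0, 4.0, 1.0, 4.0),
                "a": (1.0, 4.0, 1.0, 4.0),  # tied combined fold with "b"
                "z": (0.0, 0.0, 1.0, 0.0),  # undefined combined fold
            }
        )
        table = build_gradient_table(expr, study_cutoffs)
        assert list(table.index) == ["a", "b", "z"]

    def test_recovers_planted_structure_end_to_end(self, dataset):
        expr = ExpressionTable.from_libraries(dataset.catalog, dataset.libraries)
        cuts = estimate_cutoffs(
            expr,
            map_spots_to_transcripts(select_null_spots(dataset.spots), dataset.spots),
        )
        table = build_gradient_table(expr, cuts)
        truth = dataset.truth
        planted = truth.index[truth["set_name"] == "dorsal_up_8x"]
        sensitivity = (table.loc[planted, "dv_class"] == "dorsal_up").mean()
        assert sensitivity >= 0.9
        exclusive = truth.index[truth["set_name"] == "dorsal_exclusive"]
        assert (table.loc[exclusive, "dv_class"] == "dorsal_exclusive").all()


def test_temporal_table_classes_are_exclusive(small_dataset):
    expr = ExpressionTable.from_libraries(small_dataset.catalog, small_dataset.libraries)
    cuts = estimate_cutoffs(
        expr,
        map_spots_to_transcripts(
            select_null_spots(small_dataset.spots), small_dataset.spots
        ),
    )
    table = build_temporal_table(expr, cuts)
    assert set(table["day_class"]) <= {"day4_up", "day8_up", "neither"}
    assert table.index.equals(expr.ids)
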