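import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oriquant as oq
from oriquant.peaks import PeakTable, call_all_origins, flag_overlaps, peak_area
from oriquant.profiles import ChromosomeProfile, SmoothedProfileSet

from conftest import flat_profile


def brute_force_walk(values, i0, theta, n_below=3):
    """Independent re-statement of the walk: plain loops, no shortcuts."""
    area = values[i0]
    left = right = i0
    count = 0
    i = i0
    while count < n_below and i > 0:
        i -= 1
        area += values[i]
        if values[i] < theta:
            count += 1
        left = i
    count = 0
    i = i0
    while count < n_below and i < len(values) - 1:
        i += 1
        area += values[i]
        if values[i] < theta:
            count += 1
        right = i
    return area, left, right


def grid_profile(values, chrom="chrA"):
    values = np.asarray(values, dtype=float)
    return ChromosomeProfile(chrom, np.arange(len(values), dtype=np.int64) * 500, values)


class TestPeakArea:
    def test_flat_below_threshold_track(self):
        prof = flat_profile(value=0.5)
        rec = peak_area(prof, 50 * 500, theta=1.0)
        assert rec.area == pytest.approx(7 * 0.5)
        assert rec.left_index == 47 and rec.right_index == 53

    def test_hand_enumerated_peak(self):
        values = [0.3, 0.3, 0.3, 0.4, 1.2, 2.0, 1.2, 0.4, 0.3, 0.3, 0.3, 0.3, 0.3]
        rec = peak_area(grid_profile(values), 5 * 500, theta=1.0)
        assert rec.left_index == 1 and rec.right_index == 9
        assert rec.area == pytest.approx(6.4)

    def test_symmetric_track_symmetric_boundaries(self):
        x = np.arange(41)
        values = 0.5 + 2.0 * np.exp(-((x - 20.0) ** 2) / 8.0)
        rec = peak_area(grid_profile(values), 20 * 500, theta=1.0)
        assert rec.origin_index - rec.left_index == rec.right_index - rec.origin_index

    def test_origin_point_summed_once(self):
        # single spike at the origin over a below-threshold floor
        values = np.full(21, 0.2)
        values[10] = 5.0
        rec = peak_area(grid_profile(values), 10 * 500, theta=1.0)
        assert rec.area == pytest.approx(5.0 + 6 * 0.2)

    def test_nearest_grid_tie_rounds_down(self):
        values = np.arange(21, dtype=float)  # distinguishable values
        rec = peak_area(grid_profile(values), 10 * 500 + 250, theta=100.0)
        assert rec.origin_index == 10  # tie between 10 and 11 falls to 10

    def test_chromosome_end_truncates(self):
        rec = peak_area(flat_profile(n=5, value=0.5), 2 * 500, theta=1.0)
        assert rec.truncated
        assert rec.area == pytest.approx(5 * 0.5)

    def test_masked_origin_carries_no_area(self):
        prof = flat_profile(value=2.0)
        rec = peak_area(prof, 10_000, theta=1.0, masks=[(9_000, 11_000)])
        assert rec.masked and np.isnan(rec.area)

    def test_masked_gap_truncates_walk(self):
        # positions jump 4500 -> 8000: a masked hole in the grid
        pos = np.concatenate([np.arange(0, 5_000, 500), np.arange(8_000, 20_000, 500)])
        prof = ChromosomeProfile("chrA", pos, np.full(len(pos), 0.5))
        rec = peak_area(prof, 4_000, theta=1.0, grid_step=500)
        assert rec.truncated
        assert rec.right_bp == 4_500

    def test_additive_shift_preserves_traversal(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.2, 2.0, size=61)
        base = peak_area(grid_profile(values), 30 * 500, theta=1.0)
        shifted = peak_area(grid_profile(values + 5.0), 30 * 500, theta=6.0)
        assert (shifted.left_index, shifted.right_index) == (base.left_index, base.right_index)
        n_traversed = base.right_index - base.left_index + 1
        assert shifted.area == pytest.approx(base.area + 5.0 * n_traversed)

    def test_consecutive_stop_rule_walks_farther(self):
        # below, above, below, below, below ... : cumulative stops earlier
        values = [0.1] * 10 + [2.0, 0.1, 2.0, 0.1, 0.1, 0.1] + [0.1] * 5
        rec_cum = peak_area(grid_profile(values), 10 * 500, theta=1.0)
        rec_con = peak_area(grid_profile(values), 10 * 500, theta=1.0, stop_rule="consecutive")
        assert rec_con.right_index >= rec_cum.right_index

    def test_exclude_below_option_sums_only_peaks(self):
        values = [0.1, 0.1, 0.1, 2.0, 3.0, 2.0, 0.1, 0.1, 0.1]
        rec = peak_area(grid_profile(values), 4 * 500, theta=1.0, include_below=False)
        assert rec.area == pytest.approx(7.0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.floats(0.0, 4.0), min_size=7, max_size=60),
        origin_frac=st.floats(0.0, 1.0),
        theta=st.floats(0.1, 3.0),
    )
    def test_matches_brute_force_walker(self, values, origin_frac, theta):
        prof = grid_profile(values)
        i0 = int(round(origin_frac * (len(values) - 1)))
        rec = peak_area(prof, int(prof.positions[i0]), theta)
        area, left, right = brute_force_walk(np.asarray(values, float), i0, theta)
        assert rec.area == pytest.approx(area, rel=1e-12, abs=1e-12)
        assert (rec.left_index, rec.right_index) == (left, right)

    def test_area_non_negative_on_non_negative_track(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            values = rng.uniform(0, 3, size=rng.integers(7, 40))
            rec = peak_area(grid_profile(values), int(rng.integers(len(values))) * 500, 1.0)
            assert rec.area >= 0


class TestCallAllOrigins:
    def _profiles(self, small_annotation):
        profs = {
            "chrA": flat_profile("chrA", n=401, value=0.5),
            "chrB": ChromosomeProfile(
                "chrB",
                np.array([p for p in range(0, 150_000, 500)
                          if not (100_000 <= p < 120_000)], dtype=np.int64),
                np.full(260, 0.5),
            ),
        }
        return SmoothedProfileSet(profs, masks=[("chrB", 100_000, 120_000)])

    def test_empty_annotation_empty_table(self):
        ann = oq.GenomeAnnotation([("chrA", 200_000)], {"chrA": 100_000}, [])
        prof = SmoothedProfileSet({"chrA": flat_profile("chrA")})
        assert len(call_all_origins(prof, ann)) == 0

    def test_one_record_per_origin(self, small_annotation):
        table = call_all_origins(self._profiles(small_annotation), small_annotation)
        assert len(table) == 3
        assert len(set(r.origin_id for r in table.records)) == 3

    def test_origin_in_mask_flagged(self, small_annotation):
        ann = oq.GenomeAnnotation(
            small_annotation.chromosomes,
            small_annotation.centromeres,
            small_annotation.origins + [oq.Origin("masked_ori", "chrB", 110_000)],
            small_annotation.masked_intervals,
        )
        table = call_all_origins(self._profiles(small_annotation), ann)
        assert table.by_id()["masked_ori"].masked

    def test_unknown_chromosome_names_origin(self, small_annotation):
        ann = oq.GenomeAnnotation(
            [("chrA", 200_000), ("chrZ", 100_000)],
            {"chrA": 100_000, "chrZ": 50_000},
            [oq.Origin("lost", "chrZ", 10_000)],
        )
        prof = SmoothedProfileSet({"chrA": flat_profile("chrA")})
        with pytest.raises(ValueError, match="lost"):
            call_all_origins(prof, ann)


class TestFlagOverlaps:
    def _table(self, records):
        return PeakTable("g", records, threshold=1.0)

    def _rec(self, oid, left, right, chrom="chrA"):
        return oq.PeakRecord(
            oid, chrom, (left + right) // 2 * 500, (left + right) // 2,
            1.0, left, right, left * 500, right * 500,
        )

    def test_disjoint_not_flagged(self):
        t = flag_overlaps(self._table([self._rec("a", 0, 10), self._rec("b", 50, 60)]))
        assert not any(r.overlapping for r in t.records)

    def test_shared_territory_both_flagged(self):
        t = flag_overlaps(self._table([self._rec("a", 0, 12), self._rec("b", 8, 20)]))
        assert all(r.overlapping for r in t.records)

    def test_only_intersecting_pair_flagged(self):
        t = flag_overlaps(
            self._table(
                [self._rec("a", 0, 10), self._rec("b", 9, 20), self._rec("c", 40, 50)]
            )
        )
        flags = {r.origin_id: r.overlapping for r in t.records}
        assert flags == {"a": True, "b": True, "c": False}

    def test_different_chromosomes_never_overlap(self):
        t = flag_overlaps(
            self._table([self._rec("a", 0, 10, "chrA"), self._rec("b", 5, 15, "chrB")])
        )
        assert not any(r.overlapping for r in t.records)

    def test_brute_force_pairwise_agreement(self):
        rng = np.random.default_rng(4)
        recs = []
        for i in range(30):
            left = int(rng.integers(0, 200))
            recs.append(self._rec(f"o{i}", left, left + int(rng.integers(1, 30))))
        t = flag_overlaps(self._table(recs))
        expected = set()
        for a in recs:
            for b in recs:
                if a.origin_id != b.origin_id and a.left_bp <= b.right_bp and b.left_bp <= a.right_bp:
                    expected.add(a.origin_id)
        assert {r.origin_id for r in t.records if r.overlapping} == expected
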