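"""Raster/occurrence data model: I/O, preprocessing, background sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from nichecast.grids import (
    EnvStack, GeoreferenceError, OccurrenceSet, coastal_mask, dedupe_per_cell,
    extract_swd, read_ascii_grid, read_env_stack, sample_background,
    snap_to_ocean, write_ascii_grid,
)


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path, small_stack):
        path = tmp_path / "alpha.asc"
        vals = np.where(small_stack.valid_mask, small_stack.layer("alpha"),
                        np.nan)
        write_ascii_grid(path, vals, small_stack.extent,
                         small_stack.resolution)
        back, extent, res, _ = read_ascii_grid(path)
        assert extent == small_stack.extent
        assert res == small_stack.resolution
        np.testing.assert_allclose(back[small_stack.valid_mask],
                                   small_stack.layer("alpha")[small_stack.valid_mask],
                                   rtol=1e-6)
        assert np.isnan(back[~small_stack.valid_mask]).all()

    def test_stack_reader_unions_nodata(self, tmp_path):
        a = np.arange(100, dtype=float).reshape(10, 10)
        b = a + 50
        a[2, 3] = np.nan  # nodata in layer 1 only
        write_ascii_grid(tmp_path / "a.asc", a, (0, 10, 0, 10), 1.0)
        write_ascii_grid(tmp_path / "b.asc", b, (0, 10, 0, 10), 1.0)
        stack = read_env_stack([tmp_path / "a.asc", tmp_path / "b.asc"],
                               ["a", "b"])
        assert stack.layer_names == ["a", "b"]
        assert stack.values.shape == (2, 10, 10)
        # the cell is invalid for the whole stack even though layer b has data
        assert not stack.valid_mask[2, 3]
        assert stack.valid_mask.sum() == 99

    def test_mismatched_grids_rejected(self, tmp_path):
        write_ascii_grid(tmp_path / "a.asc", np.zeros((10, 10)),
                         (0, 10, 0, 10), 1.0)
        write_ascii_grid(tmp_path / "b.asc", np.zeros((20, 20)),
                         (0, 10, 0, 10), 0.5)
        with pytest.raises(GeoreferenceError):
            read_env_stack([tmp_path / "a.asc", tmp_path / "b.asc"])


class TestEnvStack:
    def test_extent_shape_consistency_enforced(self):
        with pytest.raises(GeoreferenceError):
            EnvStack(["x"], np.zeros((5, 5)), (0, 10, 0, 10), 1.0,
                     np.ones((5, 5), dtype=bool))

    def test_cell_index_half_open_and_centers(self, small_stack):
        row, col = small_stack.cell_index(0.0, 0.0)
        assert (row, col) == (9, 0)  # bottom-left cell; row 0 is north
        row, col = small_stack.cell_index(0.999, 9.999)
        assert (row, col) == (0, 0)
        lon, lat = small_stack.cell_center(0, 0)
        assert (lon, lat) == (0.5, 9.5)

    def test_longitudes_normalized_to_standard_range(self):
        occ = OccurrenceSet.from_points([350.0, 10.0], [0.0, 0.0])
        np.testing.assert_allclose(occ.longitudes, [-10.0, 10.0])


class TestSnapToOcean:
    def test_ocean_records_unchanged(self, small_stack):
        occ = OccurrenceSet.from_points([0.5, 9.5], [0.5, 9.5])
        out = snap_to_ocean(occ, small_stack)
        pd.testing.assert_frame_equal(out.records, occ.records)

    def test_land_record_moves_to_nearest_ocean_center(self, small_stack):
        # (4.2, 5.2) falls in land cell (row 4, col 4); nearest ocean cell
        # center by great-circle is (3.5, 5.5) i.e. row 4, col 3
        occ = OccurrenceSet.from_points([4.2], [5.2])
        out = snap_to_ocean(occ, small_stack)
        assert (out.longitudes[0], out.latitudes[0]) == (3.5, 5.5)

    def test_equidistant_tie_prefers_smaller_row_then_col(self):
        # single land cell in the middle of a 3x3 all-ocean grid: a record at
        # the exact center. Great-circle distance shrinks east-west spacing
        # by cos(lat), so the two same-latitude neighbours (row 1, cols 0 and
        # 2) are the joint-nearest; the tie resolves to the smaller column.
        valid = np.ones((3, 3), dtype=bool)
        valid[1, 1] = False
        stack = EnvStack(["z"], np.zeros((3, 3)), (0, 3, 0, 3), 1.0, valid)
        occ = OccurrenceSet.from_points([1.5], [1.5])
        out = snap_to_ocean(occ, stack)
        assert (out.longitudes[0], out.latitudes[0]) == (0.5, 1.5)

    def test_idempotent(self, small_stack):
        occ = OccurrenceSet.from_points([4.2, 0.5, 5.4], [5.2, 0.5, 4.6])
        once = snap_to_ocean(occ, small_stack)
        twice = snap_to_ocean(once, small_stack)
        pd.testing.assert_frame_equal(once.records, twice.records)

    def test_no_ocean_raises(self):
        stack = EnvStack(["z"], np.zeros((2, 2)), (0, 2, 0, 2), 1.0,
                         np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            snap_to_ocean(OccurrenceSet.from_points([0.5], [0.5]), stack)


class TestDedupePerCell:
    def test_one_record_per_cell_smallest_id(self, small_stack):
        occ = OccurrenceSet.from_points([2.1, 2.5, 2.9], [3.1, 3.5, 3.9],
                                        ids=[7, 3, 9])
        out = dedupe_per_cell(occ, small_stack)
        assert len(out) == 1
        assert out.records["id"].tolist() == [3]

    def test_distinct_cells_identity(self, small_stack):
        occ = OccurrenceSet.from_points([0.5, 1.5, 2.5], [0.5, 1.5, 2.5])
        assert len(dedupe_per_cell(occ, small_stack)) == 3

    def test_count_matches_brute_force_grouping(self, ocean_stack):
        rng = np.random.default_rng(3)
        lons = rng.uniform(0, 60, 40)
        lats = rng.uniform(0, 60, 40)
        occ = OccurrenceSet.from_points(lons, lats)
        out = dedupe_per_cell(occ, ocean_stack)
        rows, cols = ocean_stack.cell_index(lons, lats)
        assert len(out) == len(set(zip(rows.tolist(), cols.tolist())))


class TestSampleBackground:
    def test_postconditions_and_determinism(self, small_stack):
        box = (2.0, 8.0, 2.0, 8.0)
        bg1 = sample_background(small_stack, 20, box=box, seed=5)
        bg2 = sample_background(small_stack, 20, box=box, seed=5)
        assert bg1.n == 20
        assert small_stack.valid_mask[bg1.rows, bg1.cols].all()
        assert (bg1.lons >= 2).all() and (bg1.lons <= 8).all()
        assert (bg1.lats >= 2).all() and (bg1.lats <= 8).all()
        np.testing.assert_array_equal(bg1.rows, bg2.rows)
        np.testing.assert_array_equal(bg1.cols, bg2.cols)

    def test_insufficient_cells_raises(self, small_stack):
        with pytest.raises(ValueError, match="insufficient"):
            sample_background(small_stack, 1000, seed=0)

    def test_cosine_latitude_law(self, ocean_stack):
        """Band frequencies follow cos(lat): chi-square non-rejection and the
        0.5 ratio between the 60N and equator bands."""
        n = 100_000
        bg = sample_background(ocean_stack, n, seed=11, replace=True)
        counts = np.bincount(bg.rows, minlength=20).astype(float)
        w = np.cos(np.radians(ocean_stack.lat_centers))
        expected = n * w / w.sum()
        assert chisquare(counts, expected).pvalue > 0.01
        top = counts[0] * 20  # 58.5N band
        bottom = counts[-1] * 20  # 1.5N band
        ratio = counts[0] / counts[-1]
        se = ratio * np.sqrt(1 / counts[0] + 1 / counts[-1])
        want = np.cos(np.radians(58.5)) / np.cos(np.radians(1.5))
        assert abs(ratio - want) < 3 * se


class TestExtractSWD:
    def test_values_read_from_cells(self, small_stack):
        occ = OccurrenceSet.from_points([2.5], [3.5])
        swd = extract_swd(occ, small_stack, ["alpha", "beta"], "sp")
        row, col = small_stack.cell_index(2.5, 3.5)
        assert swd.data.loc[0, "alpha"] == small_stack.layer("alpha")[row, col]
        assert swd.layer_names == ["alpha", "beta"]

    def test_land_point_rejected(self, small_stack):
        occ = OccurrenceSet.from_points([4.5], [5.5])
        with pytest.raises(ValueError, match="invalid cell"):
            extract_swd(occ, small_stack)

    def test_csv_round_trip_full_precision(self, tmp_path, small_stack,
                                           occurrences):
        swd = extract_swd(occurrences, small_stack)
        path = tmp_path / "pres.swd"
        swd.to_csv(path)
        from nichecast.grids import SWDTable
        back = SWDTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, swd.data)

    def test_projecting_back_to_cells_is_identity(self, small_stack,
                                                  occurrences):
        swd = extract_swd(occurrences, small_stack)
        r0, c0 = small_stack.cell_index(occurrences.longitudes,
                                        occurrences.latitudes)
        r1, c1 = small_stack.cell_index(swd.data["longitude"],
                                        swd.data["latitude"])
        np.testing.assert_array_equal(r0, r1)
        np.testing.assert_array_equal(c0, c1)


class TestCoastalMask:
    def test_all_ocean_has_no_coast(self, ocean_stack):
        assert not coastal_mask(ocean_stack).any()

    def test_single_land_pixel_chebyshev_square(self):
        valid = np.ones((30, 30), dtype=bool)
        valid[15, 15] = False
        stack = EnvStack(["z"], np.zeros((30, 30)), (0, 30, 0, 30), 1.0,
                         valid)
        mask = coastal_mask(stack, max_pixels=7)
        # brute-force Chebyshev distance oracle
        rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        cheb = np.maximum(np.abs(rr - 15), np.abs(cc - 15))
        expected = (cheb < 7) & valid
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 13 * 13 - 1  # (2*7-1)^2 minus the land pixel

    def test_distance_exactly_seven_excluded(self):
        valid = np.ones((9, 20), dtype=bool)
        valid[:, 0] = False  # western shoreline
        stack = EnvStack(["z"], np.zeros((9, 20)), (0, 20, 0, 9), 1.0, valid)
        mask = coastal_mask(stack, max_pixels=7)
        assert mask[4, 6]   # 6 pixels from shore
        assert not mask[4, 7]  # exactly 7: "less than 7" excludes it
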