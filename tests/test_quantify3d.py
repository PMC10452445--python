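"""3D component labelling, open/closed classification and vessel metrics."""

import math

import numpy as np
import pytest

from octvessel.phantom import truth_summary
from octvessel.quantify3d import (
    LabelVolume,
    classify_open_closed,
    effective_permeability,
    label_components,
    measure_diameter,
    measure_surface_area,
    remove_closed,
    summarize,
    _min_caliper_px,
    _perimeter_px,
)
from octvessel.stack_io import BinaryStack


def _mask(data):
    return BinaryStack(data=np.asarray(data, dtype=bool))


def _flood_fill_components(mask, neighbourhood):
    """Independent scan-order flood fill returning the component count."""
    visited = np.zeros_like(mask, dtype=bool)
    count = 0
    coords = list(zip(*np.nonzero(mask)))
    for start in coords:
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in neighbourhood:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)):
                    if mask[p] and not visited[p]:
                        visited[p] = True
                        stack.append(p)
    return count


def _neighbourhood(connectivity):
    offs = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    if connectivity == 6:
        return [o for o in offs if sum(map(abs, o)) == 1]
    if connectivity == 18:
        return [o for o in offs if sum(map(abs, o)) <= 2]
    return offs


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[0:3, 0:3, 0:3] = True
        data[5:8, 5:8, 5:8] = True
        assert label_components(_mask(data)).n_components == 2

    def test_corner_touch_depends_on_connectivity(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[0:2, 0:2, 0:2] = True
        data[2:4, 2:4, 2:4] = True  # touch only at the (2,2,2) corner
        for conn in (6, 26):
            got = label_components(_mask(data), conn).n_components
            want = _flood_fill_components(data, _neighbourhood(conn))
            assert got == want
        assert label_components(_mask(data), 26).n_components == 1
        assert label_components(_mask(data), 6).n_components == 2

    def test_random_volume_matches_flood_fill(self, rng):
        data = rng.random((6, 7, 5)) > 0.7
        for conn in (6, 18, 26):
            got = label_components(_mask(data), conn).n_components
            assert got == _flood_fill_components(data, _neighbourhood(conn))

    def test_empty_mask_has_no_components(self):
        assert label_components(_mask(np.zeros((3, 3, 3)))).n_components == 0

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="6, 18, 26"):
            label_components(_mask(np.ones((2, 2, 2))), 8)

    def test_voxel_conservation(self, rng):
        data = rng.random((5, 9, 9)) > 0.6
        vol = label_components(_mask(data))
        assert (vol.labels > 0).sum() == data.sum()
        sizes = [(vol.labels == cid).sum() for cid in vol.ids]
        assert sum(sizes) == data.sum()


class TestOpenClosed:
    def test_bottom_anchored_tube_is_open(self):
        data = np.zeros((12, 6, 6), dtype=bool)
        data[0:11, 2:4, 2:4] = True
        vol = label_components(_mask(data))
        assert classify_open_closed(vol) == {1: True}

    def test_floating_blob_is_closed(self):
        data = np.zeros((12, 6, 6), dtype=bool)
        data[5:9, 2:4, 2:4] = True
        vol = label_components(_mask(data))
        assert classify_open_closed(vol) == {1: False}

    def test_phantom_flags_match_truth(self, small_phantom):
        _, truth = small_phantom
        vol = label_components(truth.mask)
        flags = classify_open_closed(vol)
        assert sum(flags.values()) == int(truth.tube_table["open"].sum())
        for _, row in truth.tube_table.iterrows():
            z, y, x = truth.centerlines[int(row.id)][0]
            label = int(vol.labels[int(z), int(round(y)), int(round(x))])
            assert flags[label] == bool(row.open)

    def test_widened_anchor_recovers_dropout(self):
        data = np.zeros((12, 6, 6), dtype=bool)
        data[1:11, 2:4, 2:4] = True  # missing bottom frame
        vol = label_components(_mask(data))
        assert classify_open_closed(vol)[1] is False
        assert classify_open_closed(vol, anchor_frames=2)[1] is True


class TestRemoveClosed:
    def test_counts_partition(self, small_phantom):
        _, truth = small_phantom
        vol = label_components(truth.mask)
        flags = classify_open_closed(vol)
        open_vol = remove_closed(vol)
        assert open_vol.n_components == sum(flags.values())
        assert vol.n_components == sum(flags.values()) + sum(
            not f for f in flags.values()
        )

    def test_all_closed_volume_empties(self):
        data = np.zeros((5, 4, 4), dtype=bool)
        data[2:4, 1:3, 1:3] = True
        vol = remove_closed(label_components(_mask(data)))
        assert vol.n_components == 0
        assert not vol.labels.any()

    def test_equivalent_to_open_only_summary(self, small_phantom):
        _, truth = small_phantom
        vol = label_components(truth.mask)
        a = summarize(remove_closed(vol), open_only=False)
        b = summarize(vol, open_only=True)
        cols = [
            "open",
            "n_voxels",
            "frames_spanned",
            "mean_min_caliper_diameter_um",
            "lateral_surface_area_um2",
        ]
        left = a.records[cols].sort_values("n_voxels").reset_index(drop=True)
        right = b.records[cols].sort_values("n_voxels").reset_index(drop=True)
        assert left.equals(right)


def _tube_volume(radius_px, n_frames, size=24):
    data = np.zeros((n_frames, size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    data[:] = disc
    return label_components(_mask(data))


def _brute_force_caliper(points):
    """Independent fine-angle caliper sweep over pixel centers (+1 px
    footprint, the package's documented convention)."""
    best = math.inf
    for k in range(3600):
        theta = k * math.pi / 3600
        u = (math.cos(theta), math.sin(theta))
        proj = [p[0] * u[0] + p[1] * u[1] for p in points]
        best = min(best, max(proj) - min(proj))
    return best + 1.0


class TestMeasureDiameter:
    def test_straight_circular_tube(self):
        # radius 3 px tube at 10 µm pitch: diameter within one pixel of 60 µm
        vol = _tube_volume(3, 5)
        assert measure_diameter(vol, 1) == pytest.approx(60.0, abs=10.0)

    def test_single_voxel_component(self):
        data = np.zeros((3, 5, 5), dtype=bool)
        data[1, 2, 2] = True
        vol = label_components(_mask(data))
        assert measure_diameter(vol, 1) == pytest.approx(10.0)

    def test_elliptical_cross_section_matches_brute_force(self):
        data = np.zeros((1, 16, 16), dtype=bool)
        yy, xx = np.mgrid[0:16, 0:16]
        data[0] = ((xx - 8) / 5.0) ** 2 + ((yy - 8) / 2.0) ** 2 <= 1.0
        vol = label_components(_mask(data))
        pts = list(zip(*np.nonzero(data[0])))
        expected_px = _brute_force_caliper(pts)
        assert measure_diameter(vol, 1) == pytest.approx(expected_px * 10.0, rel=1e-3)
        # within one pixel of the continuous minor-axis diameter (4 px)
        assert abs(expected_px - 4.0) <= 1.0

    def test_unknown_component_rejected(self):
        vol = _tube_volume(2, 3)
        with pytest.raises(KeyError):
            measure_diameter(vol, 99)

    @pytest.mark.parametrize("radius_px", [2, 3, 4, 5])
    def test_digitized_discs_within_one_pixel(self, radius_px):
        vol = _tube_volume(radius_px, 3)
        d = measure_diameter(vol, 1)
        assert abs(d - 2 * radius_px * 10.0) <= 10.0


class TestMeasureSurfaceArea:
    def test_cylinder_against_analytic_area(self):
        # radius 30 µm (3 px), 20 frames at 10 µm: pi * 60 * 200 um^2
        vol = _tube_volume(3, 20)
        analytic = math.pi * 60.0 * 200.0
        assert measure_surface_area(vol, 1) == pytest.approx(analytic, rel=0.10)

    def test_single_voxel_convention(self):
        data = np.zeros((1, 5, 5), dtype=bool)
        data[0, 2, 2] = True
        vol = label_components(_mask(data))
        single = np.zeros((3, 3), dtype=bool)
        single[1, 1] = True
        expected = _perimeter_px(single, "hybrid") * 10.0 * 10.0
        assert measure_surface_area(vol, 1) == pytest.approx(expected)
        assert expected > 0

    def test_square_perimeter_error_shrinks_with_size(self):
        errors = {}
        for k in [5, 10, 20, 50]:
            frame = np.zeros((k + 10, k + 10), dtype=bool)
            frame[5 : 5 + k, 5 : 5 + k] = True
            est = _perimeter_px(frame, "hybrid")
            errors[k] = abs(est - 4 * k) / (4 * k)
        assert errors[5] > errors[10] > errors[20] > errors[50]
        assert errors[20] < 0.08
        assert errors[50] < 0.05

    def test_estimator_variants_bracket_the_hybrid(self):
        frame = np.zeros((16, 16), dtype=bool)
        yy, xx = np.mgrid[0:16, 0:16]
        frame[(yy - 8) ** 2 + (xx - 8) ** 2 <= 9] = True
        lo = _perimeter_px(frame, "edge")
        hi = _perimeter_px(frame, "crofton")
        mid = _perimeter_px(frame, "hybrid")
        assert min(lo, hi) <= mid <= max(lo, hi)
        with pytest.raises(ValueError):
            _perimeter_px(frame, "nope")


class TestSummarize:
    def test_phantom_counts_and_totals(self, small_phantom):
        _, truth = small_phantom
        vol = label_components(truth.mask)
        table = summarize(vol)
        ts = truth_summary(truth)
        assert table.n_open == ts.n_open
        assert table.n_closed == ts.n_closed
        assert len(table.records) == len(truth.tube_table)
        assert table.records["n_voxels"].sum() == truth.mask.data.sum()

    def test_open_only_keeps_open_records(self, small_phantom):
        _, truth = small_phantom
        vol = label_components(truth.mask)
        table = summarize(vol, open_only=True)
        assert table.records["open"].all()
        assert table.n_closed == 0

    def test_empty_volume_yields_empty_table(self):
        vol = label_components(_mask(np.zeros((2, 4, 4))))
        table = summarize(vol)
        assert len(table.records) == 0
        assert table.totals == {
            "n_open": 0,
            "n_closed": 0,
            "total_open_surface_area_um2": 0.0,
            "mean_diameter_um": 0.0,
        }

    def test_single_tube_totals_equal_its_record(self):
        vol = _tube_volume(3, 6)
        table = summarize(vol)
        rec = table.records.iloc[0]
        assert table.totals["n_open"] == 1
        assert table.totals["total_open_surface_area_um2"] == pytest.approx(
            rec.lateral_surface_area_um2
        )
        assert table.totals["mean_diameter_um"] == pytest.approx(
            rec.mean_min_caliper_diameter_um
        )


class TestEffectivePermeability:
    def test_values(self):
        assert effective_permeability(0.0, 5.0) == 0.0
        assert effective_permeability(10.0, 2.0) == 5.0
        assert effective_permeability(3.7, 37699.0) == pytest.approx(
            9.814e-5, rel=1e-3
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            effective_permeability(1.0, 0.0)
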