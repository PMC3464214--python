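import math

import numpy as np
import pytest

from tubecount.synthgen import TubeNetworkSpec, generate_tube_network
from tubecount.tubes import (
    AnnotationError,
    TubePath,
    UntraceableTubeError,
    build_tube_graph,
    quantify_tubes,
    snap_endpoint,
    trace_tube,
    tube_statistics,
)
from conftest import capsule_mask, dijkstra_cost


class TestSnapEndpoint:
    def test_foreground_point_is_identity(self, bar_mask):
        assert snap_endpoint((4, 50), bar_mask, 10) == (4, 50)

    def test_snaps_to_unique_nearest(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 12] = True
        assert snap_endpoint((10, 10), mask, 5) == (10, 12)

    def test_empty_mask_raises(self):
        with pytest.raises(AnnotationError):
            snap_endpoint((5, 5), np.zeros((10, 10), dtype=bool), 5)

    def test_tie_broken_row_major(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[3, 4] = True  # above click
        mask[5, 4] = True  # below click, same distance
        assert snap_endpoint((4, 4), mask, 3) == (3, 4)

    def test_out_of_bounds_point(self):
        with pytest.raises(AnnotationError):
            snap_endpoint((50, 2), np.ones((10, 10), dtype=bool), 5)


class TestTraceTube:
    def test_straight_bar_length_and_width(self, bar_mask):
        path = trace_tube(bar_mask, (4, 2), (4, 101))
        assert path.length == pytest.approx(99, abs=1)
        assert path.mean_width == pytest.approx(5, rel=0.10)

    def test_l_shape_length_against_dijkstra_oracle(self):
        from scipy import ndimage

        mask = np.zeros((60, 70), dtype=bool)
        mask[5:10, 5:63] = True  # horizontal arm
        mask[5:50, 5:10] = True  # vertical arm
        start, end = (7, 57), (47, 7)  # 50 px and 40 px from the corner
        path = trace_tube(mask, start, end)
        # path stays inside the mask
        assert mask[path.polyline[:, 0], path.polyline[:, 1]].all()
        assert path.length == pytest.approx(90, rel=0.03)
        # the traced geodesic achieves the independently computed optimal cost
        dt = ndimage.distance_transform_edt(mask)
        oracle_cost = dijkstra_cost(mask, dt, start, end)
        costs = 1.0 + 1.0 / dt[path.polyline[:, 0], path.polyline[:, 1]]
        steps = np.hypot(*np.diff(path.polyline, axis=0).T)
        traced_cost = float((steps * (costs[1:] + costs[:-1]) / 2).sum())
        assert traced_cost == pytest.approx(oracle_cost, rel=1e-9)

    def test_disjoint_components_raise(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:10, 2:12] = True
        mask[5:10, 25:35] = True
        with pytest.raises(UntraceableTubeError):
            trace_tube(mask, (7, 5), (7, 30))

    def test_endpoint_off_mask_raises(self, bar_mask):
        with pytest.raises(AnnotationError):
            trace_tube(bar_mask, (0, 0), (4, 50))

    def test_length_at_least_endpoint_distance(self, rng):
        spec = TubeNetworkSpec(seed=21, noise_sigma=0.0, illumination_ramp=(1, 1))
        _, truth, ann = generate_tube_network(spec)
        for p0, p1 in ann:
            path = trace_tube(truth.mask, p0, p1)
            assert path.length >= math.hypot(p0[0] - p1[0], p0[1] - p1[1]) - 1


class TestBuildTubeGraph:
    def _toy_path(self, p0, p1):
        line = np.array([p0, p1])
        return TubePath(polyline=line, length=float(np.hypot(*(np.array(p1) - p0))),
                        mean_width=3.0, area_px=10, pixel_set=frozenset())

    def test_three_tubes_meeting_make_one_branch_point(self):
        paths = [self._toy_path((50, 50), (10, 50)),
                 self._toy_path((51, 49), (80, 20)),
                 self._toy_path((49, 51), (80, 80))]
        tg = build_tube_graph(paths, merge_eps=10)
        assert tg.n_tubes == 3
        assert tg.n_branching_points == 1
        degrees = sorted(d for _, d in tg.graph.degree())
        assert degrees == [1, 1, 1, 3]

    def test_two_tubes_sharing_endpoint_no_branch(self):
        paths = [self._toy_path((10, 10), (10, 60)),
                 self._toy_path((10, 60), (40, 60))]
        tg = build_tube_graph(paths, merge_eps=5)
        assert tg.n_branching_points == 0
        assert sorted(d for _, d in tg.graph.degree()) == [1, 1, 2]

    def test_disjoint_tubes(self):
        paths = [self._toy_path((10 + 30 * k, 5), (10 + 30 * k, 90)) for k in range(3)]
        tg = build_tube_graph(paths, merge_eps=5)
        assert tg.graph.number_of_nodes() == 6
        assert all(d == 1 for _, d in tg.graph.degree())
        assert tg.n_branching_points == 0

    def test_merge_is_transitive_single_linkage(self):
        # chain of endpoints each 8 px apart merges into one node at eps 10
        paths = [self._toy_path((0, 0), (50, 0)),
                 self._toy_path((50, 8), (100, 8)),
                 self._toy_path((50, 16), (0, 16))]
        tg = build_tube_graph(paths, merge_eps=10)
        assert tg.graph.number_of_nodes() == 4  # 3 free ends + 1 merged junction
        assert tg.n_branching_points == 1


class TestTubeStatistics:
    def test_empty_annotation_all_zero(self):
        tg = build_tube_graph([], 10)
        stats = tube_statistics(tg, np.zeros((10, 10), dtype=bool))
        assert stats.total_length == 0 and stats.n_tubes == 0
        assert stats.average_length == 0 and stats.total_tube_area == 0

    def test_y_network_stats(self):
        """Three 60 px arms from one center: 3 tubes, 1 branch point."""
        h = w = 160
        center = np.array([80.0, 80.0])
        ends = [center + 60 * np.array([math.cos(a), math.sin(a)])
                for a in (0.0, 2.2, 4.2)]
        mask = np.zeros((h, w), dtype=bool)
        for e in ends:
            mask |= capsule_mask((h, w), center, e, 5.0)
        ann = [(tuple(np.round(center).astype(int)), tuple(np.round(e).astype(int)))
               for e in ends]
        res = quantify_tubes(mask, ann)
        assert res.stats.n_tubes == 3
        assert res.stats.n_branching_points == 1
        assert res.stats.total_length == pytest.approx(180, rel=0.05)
        assert res.stats.total_tube_area <= mask.sum()
        assert res.stats.total_tube_area == pytest.approx(mask.sum(), rel=0.10)

    def test_pixel_size_scales_units(self, bar_mask):
        path = trace_tube(bar_mask, (4, 2), (4, 101))
        tg = build_tube_graph([path], 10)
        px = tube_statistics(tg, bar_mask, pixel_size=None)
        um = tube_statistics(tg, bar_mask, pixel_size=2.0)
        assert um.total_length == pytest.approx(2 * px.total_length)
        assert um.average_width == pytest.approx(2 * px.average_width)
        assert um.total_tube_area == pytest.approx(4 * px.total_tube_area)

    def test_rotation_robustness_of_length(self):
        """Recovered length of a straight tube changes <= 5% under rotation."""
        lengths = {}
        for ang in (0, 30, 45, 60):
            d = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
            p0, p1 = np.array([128.0, 128.0]) - 75 * d, np.array([128.0, 128.0]) + 75 * d
            mask = capsule_mask((256, 256), p0, p1, 5.0)
            path = trace_tube(mask, tuple(np.round(p0).astype(int)),
                              tuple(np.round(p1).astype(int)))
            lengths[ang] = path.length
        for ang, length in lengths.items():
            assert abs(length - 150.0) / 150.0 <= 0.05, (ang, length)

    def test_adding_tube_never_decreases_totals(self):
        spec = TubeNetworkSpec(seed=30, noise_sigma=0.0, illumination_ramp=(1, 1))
        _, truth, ann = generate_tube_network(spec)
        prev_len, prev_n = -1.0, -1
        for k in range(1, len(ann) + 1):
            res = quantify_tubes(truth.mask, ann[:k])
            assert res.stats.total_length >= prev_len
            assert res.stats.n_tubes >= prev_n
            prev_len, prev_n = res.stats.total_length, res.stats.n_tubes

    def test_untraceable_tube_skipped_and_logged(self):
        mask = np.zeros((30, 80), dtype=bool)
        mask[10:15, 2:30] = True
        mask[10:15, 50:78] = True
        ann = [((12, 3), (12, 28)), ((12, 52), (12, 3))]  # second spans the gap
        res = quantify_tubes(mask, ann)
        assert res.stats.n_tubes == 1
        assert len(res.skipped) == 1 and res.skipped[0][0] == 1
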