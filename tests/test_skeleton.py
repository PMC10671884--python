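"""Thinning, spur removal, branch detection and segment extraction."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk, line

from avlr import (detect_branch_points, extract_segments,
                  prune_junction_artifacts, remove_spurs, skeletonize)
from avlr.io import ARTERY, VEIN, VesselLabelMap
from avlr.skeleton import Skeleton, VesselSegment, segments_from_labels
from avlr.synthetic import CurveSpec, render_phantom

_S8 = np.ones((3, 3), dtype=bool)


def _skel_from_mask(mask, cls=ARTERY):
    return Skeleton(mask, np.where(mask, np.uint8(cls), np.uint8(0)))


def _draw_lines(shape, lines, cls=ARTERY):
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in lines:
        rr, cc = line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return _skel_from_mask(mask, cls)


class TestSkeletonize:
    def test_wide_horizontal_bar_thins_to_artery_centerline(self):
        arr = np.zeros((20, 60), dtype=np.uint8)
        arr[8:13, 10:50] = ARTERY
        skel = skeletonize(VesselLabelMap(arr))
        rows = np.unique(np.argwhere(skel.mask)[:, 0])
        assert len(rows) == 1  # a single-row centerline
        assert (skel.class_of[skel.mask] == ARTERY).all()

    def test_empty_map_gives_empty_skeleton(self):
        skel = skeletonize(VesselLabelMap(np.zeros((10, 10), dtype=np.uint8)))
        assert skel.n_pixels == 0

    def test_annulus_thins_to_closed_loop_of_degree_two(self):
        arr = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = disk((20, 20), 14)
        arr[rr, cc] = ARTERY
        rr, cc = disk((20, 20), 7)
        arr[rr, cc] = 0
        skel = skeletonize(VesselLabelMap(arr))
        nbr = skel.neighbor_counts()
        # exhaustive neighbor audit: every loop pixel has exactly 2 neighbors
        assert (nbr[skel.mask] == 2).all()


class TestRemoveSpurs:
    def test_short_twig_removed_line_intact(self):
        skel = _draw_lines((30, 60), [((15, 5), (15, 55)), ((15, 30), (12, 33))])
        out = remove_spurs(skel, min_spur=10)
        kept = np.argwhere(out.mask)
        assert (kept[:, 0] == 15).all()  # only the long line survives
        assert out.n_pixels == 51

    def test_min_spur_zero_is_identity(self):
        skel = _draw_lines((30, 60), [((15, 5), (15, 55)), ((15, 30), (12, 33))])
        out = remove_spurs(skel, min_spur=0)
        assert np.array_equal(out.mask, skel.mask)

    def test_free_standing_short_curve_not_deleted(self):
        skel = _draw_lines((10, 10), [((5, 2), (5, 6))])
        out = remove_spurs(skel, min_spur=50)
        assert out.n_pixels == 5

    def test_fixpoint_properties_on_random_trees(self, rng):
        """After pruning: no short junction-attached twig survives, the
        trunk is untouched, and pruning is idempotent (fixpoint)."""
        min_spur = 6
        for _ in range(5):
            # random tree: a trunk plus random short and long vertical twigs
            # (twig columns kept away from the trunk ends so the trunk tails
            # are longer than min_spur and never themselves count as spurs)
            trunk = [((25, 2), (25, 58))]
            cols = rng.choice(np.arange(10, 51, 3), size=6, replace=False)
            twigs = []
            for c in cols:
                # dr >= 2: a 1-px protrusion has 3 neighbors itself and is
                # junction debris, not an endpoint-terminated twig
                dr = int(rng.integers(2, 12)) * (1 if rng.random() < 0.5 else -1)
                twigs.append(((25, int(c)), (25 + dr, int(c))))
            skel = _draw_lines((60, 61), trunk + twigs)
            got = remove_spurs(skel, min_spur=min_spur)
            kept = {tuple(map(int, p)) for p in np.argwhere(got.mask)}
            # trunk preserved
            assert {(25, c) for c in range(2, 59)} <= kept
            # nothing invented
            assert kept <= {tuple(map(int, p)) for p in np.argwhere(skel.mask)}
            # a twig survives iff it is long enough (walk arc = |dr| - 1
            # after the junction-adjacent pixel joins the twig)
            for (r0, c0), (r1, c1) in twigs:
                dr = abs(r1 - r0)
                remnant = {(r, c0) for r in range(min(r0, r1), max(r0, r1) + 1)
                           if (r, c0) in kept and r != 25}
                if dr - 1 < min_spur:
                    assert not remnant
                else:
                    assert len(remnant) == dr
            # idempotent: pruning again changes nothing
            again = remove_spurs(got, min_spur=min_spur)
            assert np.array_equal(again.mask, got.mask)


class TestBranchPoints:
    def test_straight_line_has_none(self):
        skel = _draw_lines((10, 30), [((5, 2), (5, 27))])
        assert detect_branch_points(skel).n_raw == 0

    def test_cross_collapses_to_single_representative(self):
        skel = _draw_lines((21, 21), [((10, 0), (10, 20)), ((0, 10), (20, 10))])
        bp = detect_branch_points(skel)
        # exhaustive neighbor count: raw pixels are exactly those with >= 3
        nbr = skel.neighbor_counts()
        assert np.array_equal(bp.mask, skel.mask & (nbr >= 3))
        assert len(bp.representatives) == 1
        assert bp.representatives[0] == (10, 10)

    def test_y_junction_one_representative(self):
        skel = _draw_lines((40, 40), [((5, 20), (20, 20)), ((20, 20), (35, 10)),
                                      ((20, 20), (35, 30))])
        bp = detect_branch_points(skel)
        assert len(bp.representatives) == 1


class TestExtractSegments:
    def test_single_open_curve_is_one_segment(self):
        skel = _draw_lines((40, 40), [((5, 5), (30, 25))])
        segs = extract_segments(skel, detect_branch_points(skel))
        assert len(segs) == 1
        assert segs[0].n_pixels == skel.n_pixels
        assert segs[0].end_types == ("endpoint", "endpoint")

    @pytest.mark.parametrize("pattern,expected", [
        ("Y", 3),
        ("+", 4),
    ])
    def test_junction_segment_counts_match_component_oracle(self, pattern, expected):
        if pattern == "Y":
            skel = _draw_lines((40, 40), [((5, 20), (20, 20)), ((20, 20), (35, 10)),
                                          ((20, 20), (35, 30))])
        else:
            skel = _draw_lines((21, 21), [((10, 0), (10, 20)), ((0, 10), (20, 10))])
        bp = detect_branch_points(skel)
        segs = extract_segments(skel, bp)
        # brute-force oracle: count 8-connected components after deletion
        _, n_components = ndimage.label(skel.mask & ~bp.mask, structure=_S8)
        assert len(segs) == n_components == expected

    def test_pixel_conservation(self):
        skel = _draw_lines((40, 40), [((5, 20), (20, 20)), ((20, 20), (35, 10)),
                                      ((20, 20), (35, 30)), ((10, 2), (10, 12))])
        bp = detect_branch_points(skel)
        segs = extract_segments(skel, bp)
        n_isolated = 0  # no single-pixel remnants in this geometry
        assert skel.n_pixels == sum(s.n_pixels for s in segs) + bp.n_raw + n_isolated

    def test_paths_are_simple_and_eight_adjacent(self):
        skel = _draw_lines((50, 50), [((5, 5), (45, 25)), ((25, 15), (5, 45))])
        segs = extract_segments(skel, detect_branch_points(skel))
        for s in segs:
            steps = np.abs(np.diff(s.path, axis=0))
            assert steps.max() == 1  # consecutive pixels 8-adjacent
            assert len(np.unique(s.path, axis=0)) == len(s.path)  # no repeats

    def test_disjoint_curves_keep_their_classes(self):
        curves = [
            CurveSpec("line", {"p0": (50.0, 20.0), "p1": (50.0, 180.0)},
                      width=3, vessel_class=ARTERY),
            CurveSpec("sine", {"start": (120.0, 20.0), "angle": 0.0, "length": 160,
                               "amplitude": 8, "wavelength": 60},
                      width=3, vessel_class=VEIN),
            CurveSpec("line", {"p0": (170.0, 20.0), "p1": (170.0, 180.0)},
                      width=3, vessel_class=ARTERY),
        ]
        _, labels, _ = render_phantom(curves, canvas=(220, 220))
        segs = segments_from_labels(labels)
        assert sorted(s.vessel_class for s in segs) == [ARTERY, ARTERY, VEIN]


class TestPruneJunctionArtifacts:
    def _seg(self, n, end_types):
        path = np.column_stack([np.zeros(n, int), np.arange(n)])
        return VesselSegment("s", path, ARTERY, end_types)

    def test_short_branch_to_branch_connector_discarded(self):
        segs = [self._seg(4, ("branch", "branch"))]  # arc length 3
        assert prune_junction_artifacts(segs, max_junction_len=5) == []

    def test_long_connector_kept(self):
        segs = [self._seg(51, ("branch", "branch"))]
        assert len(prune_junction_artifacts(segs, max_junction_len=5)) == 1

    def test_threshold_zero_keeps_everything(self):
        segs = [self._seg(4, ("branch", "branch")),
                self._seg(9, ("endpoint", "branch"))]
        assert prune_junction_artifacts(segs, max_junction_len=0) == segs

    def test_endpoint_segments_never_pruned(self):
        segs = [self._seg(3, ("endpoint", "branch"))]
        assert prune_junction_artifacts(segs, max_junction_len=100) == segs
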