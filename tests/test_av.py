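"""Tests for ODR computation, segment extraction and A/V classification."""

import numpy as np
import pytest

import fundusqa as fq
from fundusqa.av import VesselSegment, segment_mean_odr
from fundusqa.errors import InvalidInputError


def bar_mask(h=40, w=60, width=7):
    m = np.zeros((h, w), dtype=bool)
    lo = h // 2 - width // 2
    m[lo : lo + width, 5:-5] = True
    return m


def plus_mask(size=81, width=7, arm=30):
    m = np.zeros((size, size), dtype=bool)
    c = size // 2
    m[c - width // 2 : c + width // 2 + 1, c - arm : c + arm + 1] = True
    m[c - arm : c + arm + 1, c - width // 2 : c + width // 2 + 1] = True
    return m


class TestODRMap:
    def test_basic_arithmetic(self):
        r = np.array([[100.0, 80.0]])
        g = np.array([[50.0, 80.0]])
        mask = np.ones((1, 2), dtype=bool)
        odr = fq.odr_map(r, g, mask)
        np.testing.assert_allclose(odr, [[1.0, 0.0]])

    def test_undefined_off_mask(self):
        r = g = np.full((3, 3), 10.0)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        odr = fq.odr_map(r, g, mask)
        assert np.isfinite(odr[1, 1])
        assert np.isnan(odr[mask == 0]).all()

    def test_g_floor_guards_small_denominators(self):
        r = np.array([[10.0]])
        g = np.array([[0.001]])
        odr = fq.odr_map(r, g, np.ones((1, 1), bool), g_floor=1.0)
        assert odr[0, 0] == pytest.approx((10.0 - 0.001) / 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            fq.odr_map(np.zeros((4, 4)), np.zeros((4, 5)), np.ones((4, 4), bool))

    def test_artery_below_vein_on_default_scene(self, default_scene):
        image, truth = default_scene
        odr = fq.odr_map(image.red, image.green, truth.mask)
        a = odr[truth.label_map == 1]
        v = odr[truth.label_map == 2]
        assert np.nanmean(a) < np.nanmean(v)


class TestExtractSegments:
    def test_straight_bar_gives_one_axial_segment(self):
        segs = fq.extract_segments(bar_mask(), min_length_px=10)
        assert len(segs) == 1
        rows = segs[0].centerline[:, 0]
        assert np.all(np.abs(rows - 20) <= 1)  # centerline on the bar axis

    def test_plus_sign_splits_into_four_arms(self):
        segs = fq.extract_segments(plus_mask(), min_length_px=10, spur_min_px=5)
        assert len(segs) == 4

    def test_empty_mask_gives_empty_list(self):
        assert fq.extract_segments(np.zeros((16, 16), bool)) == []

    def test_min_length_filters_short_paths(self):
        segs = fq.extract_segments(bar_mask(), min_length_px=1000)
        assert segs == []

    def test_scene_segment_count_near_primary_vessel_count(self, default_mask):
        n_true = fq.VesselTreeSpec().n_primary_vessels
        segs = fq.extract_segments(default_mask)
        assert abs(len(segs) - n_true) <= 0.2 * n_true + 1e-9

    def test_centerlines_are_connected_paths(self, default_mask):
        for seg in fq.extract_segments(default_mask):
            steps = np.abs(np.diff(seg.centerline, axis=0)).max(axis=1)
            assert np.all(steps == 1)  # consecutive pixels are 8-neighbours


def fake_segments_with_odr(values):
    """One-pixel-wide horizontal segments with prescribed mean ODR."""
    h = len(values) * 4
    odr = np.full((h, 20), np.nan)
    segs = []
    for i, v in enumerate(values):
        row = 2 + 4 * i
        odr[row, 2:18] = v
        centerline = np.array([[row, c] for c in range(2, 18)])
        segs.append(VesselSegment(segment_id=i, centerline=centerline))
    return segs, odr


class TestClassifyAV:
    def test_two_segments_split_by_ordering(self):
        segs, odr = fake_segments_with_odr([0.3, 1.2])
        labeled, t = fq.classify_av(segs, odr, refine=False)
        assert [s.label for s in labeled] == ["artery", "vein"]
        assert 0.3 < t <= 1.2

    def test_identical_odrs_yield_unknown_with_warning(self):
        segs, odr = fake_segments_with_odr([0.7, 0.7, 0.7])
        with pytest.warns(UserWarning):
            labeled, t = fq.classify_av(segs, odr, refine=False)
        assert t is None
        assert all(s.label == "unknown" for s in labeled)

    def test_single_segment_cannot_auto_threshold(self):
        segs, odr = fake_segments_with_odr([0.5])
        with pytest.warns(UserWarning):
            _, t = fq.classify_av(segs, odr, refine=False)
        assert t is None

    def test_fixed_threshold_used_verbatim(self):
        segs, odr = fake_segments_with_odr([0.3, 0.6, 1.2])
        labeled, t = fq.classify_av(segs, odr, threshold=0.5, refine=False)
        assert t == 0.5
        assert [s.label for s in labeled] == ["artery", "vein", "vein"]

    def test_raising_threshold_never_converts_artery_to_vein(self):
        values = [0.2, 0.5, 0.8, 1.1, 1.4]
        prev_arteries: set = set()
        for t in (0.1, 0.4, 0.7, 1.0, 1.3, 1.6):
            segs, odr = fake_segments_with_odr(values)
            labeled, _ = fq.classify_av(segs, odr, threshold=t, refine=False)
            arteries = {s.segment_id for s in labeled if s.label == "artery"}
            assert prev_arteries <= arteries  # arteries only accumulate
            prev_arteries = arteries

    def test_label_invariance_under_global_intensity_scaling(self, default_scene):
        image, _ = default_scene
        mask = fq.segment_vessels(image.green)

        def labels(r, g):
            segs = fq.extract_segments(mask)
            odr = fq.odr_map(r, g, mask)
            labeled, _ = fq.classify_av(segs, odr, refine=False)
            return [s.label for s in labeled]

        base = labels(image.red, image.green)
        scaled = labels(image.red * 1.7, image.green * 1.7)
        assert base == scaled

    def test_threshold_separates_class_means(self, default_report):
        rep = default_report
        arteries = [s.mean_odr for s in rep.segments if s.label == "artery"]
        veins = [s.mean_odr for s in rep.segments if s.label == "vein"]
        assert max(arteries) < rep.odr_threshold <= min(veins)

    def test_scene_labels_match_ground_truth(self, default_scene, default_report):
        _, truth = default_scene
        assert fq.label_accuracy(default_report.segments, truth) >= 0.95

    def test_width_refinement_fixes_near_threshold_pair(self):
        # two parallel adjacent segments, both just under the fixed
        # threshold (would both be arteries); widths disambiguate
        segs, odr = fake_segments_with_odr([0.58, 0.62])
        segs[0].mean_diameter_um = 200.0  # wider -> vein
        segs[1].mean_diameter_um = 120.0  # narrower -> artery
        labeled, _ = fq.classify_av(
            segs, odr, threshold=0.7, refine=True, pairing_radius_px=10.0,
            refine_margin=0.2,
        )
        assert labeled[0].label == "vein"
        assert labeled[1].label == "artery"

    def test_segment_without_defined_odr_is_an_error(self):
        odr = np.full((5, 5), np.nan)
        seg = VesselSegment(0, np.array([[2, 2], [2, 3]]))
        with pytest.raises(InvalidInputError):
            segment_mean_odr(seg, odr)
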