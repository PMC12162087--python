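"""Percentile thresholding, clustering, delineation and overlap metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fstloc import roi


class TestPercentileThreshold:
    def test_counts_by_hand(self):
        mask = roi.percentile_threshold(np.arange(100.0), 95)
        assert mask.sum() == 5  # values 95..99 exceed the 95th percentile

    def test_constant_map_passes_everywhere(self):
        assert roi.percentile_threshold(np.full(50, 3.0), 95).all()

    def test_monotone_in_q(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=500)
        m95 = roi.percentile_threshold(v, 95)
        m90 = roi.percentile_threshold(v, 90)
        assert np.all(m90[m95])  # raising q never adds vertices

    @pytest.mark.parametrize("q", [89.9, 95.1, 50])
    def test_out_of_band_rejected(self, q):
        with pytest.raises(ValueError):
            roi.percentile_threshold(np.arange(10.0), q)


class TestClusters:
    def test_empty_mask(self):
        assert roi.connected_clusters(np.zeros((4, 4), bool)) == []

    def test_diagonal_touch_is_two_clusters(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = m[1, 1] = True
        assert len(roi.connected_clusters(m)) == 2

    def test_sizes_sorted(self):
        m = np.zeros((8, 8), bool)
        m[1:4, 1:4] = True
        m[6, 6] = True
        sizes = [int(c.sum()) for c in roi.connected_clusters(m)]
        assert sizes == [9, 1]


class TestScenario:
    def test_three_constructed_cases(self):
        base = np.zeros((10, 10), bool)
        m2 = base.copy()
        m2[2:5, 2:5] = True
        m3 = base.copy()
        m3[6:9, 6:9] = True
        assert roi.classify_scenario(m2, m3) == "disjoint"
        m3_super = base.copy()
        m3_super[1:6, 1:6] = True  # strictly contains m2
        assert roi.classify_scenario(m2, m3_super) == "overlap_3d_superset"
        assert roi.classify_scenario(m3_super, m2) == "overlap_2d_superset"


class TestDelineate:
    SHAPE = (20, 20)
    A = (slice(8, 12), slice(4, 10))  # 24-vertex 2D-motion hotspot
    B = (slice(10, 14), slice(10, 14))  # 16-vertex anterior/inferior 3D hotspot

    def _maps(self, b_level=2.0, seed=0):
        """2D hotspot (A) plus an anterior-adjacent 3D hotspot (B), on a
        weak-noise background so percentiles interpolate cleanly."""
        rng = np.random.default_rng(seed)
        v2 = rng.normal(0.0, 0.01, self.SHAPE)
        v3 = rng.normal(0.0, 0.01, self.SHAPE)
        v2[self.A] = 2.0
        v3[self.A] = 0.5
        v3[self.B] = b_level
        return v2, v3

    def test_selects_anterior_inferior_candidate(self):
        v2, v3 = self._maps()
        v3[2:6, 0:4] = 2.0  # a posterior/superior competitor
        out = roi.delineate(v2, v3, self.SHAPE, q_start=94.0)
        rows, cols = np.nonzero(out.mask("pFST"))
        assert cols.mean() > 9  # the anterior one won
        assert out.mask("hMTMST").sum() == 24
        assert not (out.mask("hMTMST") & out.mask("pFST")).any()

    def test_shift_invariance(self):
        v2, v3 = self._maps()
        a = roi.delineate(v2, v3, self.SHAPE, q_start=94.0)
        b = roi.delineate(v2 + 7.0, v3 + 7.0, self.SHAPE, q_start=94.0)
        assert np.array_equal(a.labels, b.labels)

    def test_threshold_lowering_recorded(self):
        # the 3D hotspot is weaker than A's 3D response: it only enters the
        # mask once both thresholds have been lowered
        v2, v3 = self._maps(b_level=0.4)
        out = roi.delineate(v2, v3, self.SHAPE, q_start=94.0)
        assert out.pfst_found
        assert out.threshold_used_2d < 94.0
        assert out.mask("pFST").sum() == 16

    def test_pfst_empty_and_flagged_when_no_candidate(self):
        v2, v3 = self._maps()
        window = np.zeros(self.SHAPE, bool)
        window[self.A] = True  # search window excludes the 3D hotspot
        out = roi.delineate(v2, v3, self.SHAPE, q_start=94.0, window_mask=window)
        assert not out.pfst_found
        assert out.mask("pFST").sum() == 0
        assert any("no qualifying" in n for n in out.notes)

    def test_empty_window_fails_loudly(self):
        v2, v3 = self._maps()
        with pytest.raises(RuntimeError, match="hMT/MST"):
            roi.delineate(
                v2, v3, self.SHAPE, q_start=94.0,
                window_mask=np.zeros(self.SHAPE, bool),
            )


class TestMetrics:
    def test_dice_known_values(self):
        a = np.zeros(30, bool)
        b = np.zeros(30, bool)
        a[:10] = True
        b[6:16] = True
        assert roi.dice(a, b) == pytest.approx(0.4)
        assert roi.dice(a, a) == 1.0
        assert roi.dice(a, ~a) == 0.0
        assert roi.dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0

    @given(seed=st.integers(0, 100))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_dice_properties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=40) < 0.3
        b = rng.uniform(size=40) < 0.3
        d = roi.dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == roi.dice(b, a)
        if a.any() and d == 1.0:
            assert np.array_equal(a, b)

    def test_centroid_distance_three_four_five(self):
        m1 = np.zeros((6, 6), bool)
        m2 = np.zeros((6, 6), bool)
        m1[0, 0] = True
        m2[3, 4] = True
        assert roi.centroid_distance(m1, m2) == pytest.approx(5.0)
        assert roi.centroid_distance(m1, m1) == 0.0

    def test_centroid_distance_blocks(self):
        m1 = np.zeros((20, 20), bool)
        m2 = np.zeros((20, 20), bool)
        m1[0:2, 0:2] = True
        m2[10:12, 0:2] = True
        assert roi.centroid_distance(m1, m2) == pytest.approx(10.0)

    def test_centroid_distance_empty_rejected(self):
        with pytest.raises(ValueError):
            roi.centroid_distance(np.zeros((3, 3), bool), np.ones((3, 3), bool))

    def test_surface_area(self):
        m = np.ones((10, 10), bool)
        assert roi.surface_area(m, 1.0) == 100.0
        assert roi.surface_area(np.zeros((3, 3), bool), 2.0) == 0.0
        assert roi.surface_area(np.ones(96, bool), 3.14) == pytest.approx(301.44)
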