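"""Facial geometric catalog, per-series summaries and entropy statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdscreen import facial
from pdscreen.facial import (FeatureCatalogEntry, LandmarkSeries, approx_entropy,
                             default_catalog, eval_catalog_feature, extract_series,
                             face_length, shannon_entropy, summarize)
from pdscreen.synthetic import neutral_template


def frame_with(fl: float = 1.0, overrides: dict | None = None) -> np.ndarray:
    """A (68,2) frame with face length ``fl``; override keys are 1-based."""
    pts = np.zeros((68, 2))
    pts[27] = (0.0, 0.0)      # landmark 28
    pts[8] = (0.0, fl)        # landmark 9
    for idx, xy in (overrides or {}).items():
        pts[idx - 1] = xy
    return pts


class TestFaceLength:
    def test_vertical_distance(self):
        assert face_length(frame_with(100.0)) == pytest.approx(100.0)

    def test_homogeneity_under_scaling(self):
        f = neutral_template()
        assert face_length(2.0 * f) == pytest.approx(2.0 * face_length(f))

    def test_coincident_points_error(self):
        with pytest.raises(facial.DegenerateFrameError):
            face_length(frame_with(0.0))


class TestCatalogEval:
    def test_distance_normalized_by_face_length(self):
        f = frame_with(2.0, {1: (0.0, 0.0), 17: (1.0, 0.0)})
        entry = FeatureCatalogEntry("D10", "distance", (1, 17), "face_length")
        assert eval_catalog_feature(f, entry) == pytest.approx(0.5)

    def test_right_angle(self):
        f = frame_with(1.0, {22: (0, 0), 19: (1, 0), 40: (0, 0), 43: (0, 1)})
        entry = FeatureCatalogEntry("EYEBROW1", "angle", ((22, 19), (40, 43)))
        assert eval_catalog_feature(f, entry) == pytest.approx(90.0)

    def test_unit_square_shoelace_area(self):
        f = frame_with(1.0, {61: (0, 0), 62: (1, 0), 63: (1, 1), 64: (0, 1)})
        entry = FeatureCatalogEntry("SQ", "area", (61, 62, 63, 64),
                                    "face_length_squared")
        assert eval_catalog_feature(f, entry) == pytest.approx(1.0)

    def test_ratio_zero_denominator_is_nan(self):
        f = frame_with(1.0, {49: (0, 0), 55: (3, 0), 52: (1, 1), 58: (1, 1)})
        cat = default_catalog()
        entry = next(e for e in cat if e.name == "RATIO_MOUTH")
        assert math.isnan(eval_catalog_feature(f, entry, cat))


class TestCatalog:
    def test_55_entries_unique_names(self):
        cat = default_catalog()
        assert len(cat) == 55
        assert len({e.name for e in cat}) == 55

    def test_eyebrow3_aliases_eyebrow2(self):
        cat = {e.name: e for e in default_catalog()}
        assert cat["EYEBROW2"].point_spec == cat["EYEBROW3"].point_spec

    def test_indices_in_range(self):
        for e in default_catalog():
            if e.kind in ("distance", "vertical", "area"):
                assert all(1 <= i <= 68 for i in e.point_spec)


class TestExtractSeries:
    def test_identical_frames_give_constant_series(self):
        pts = np.repeat(neutral_template()[None], 10, axis=0)
        feats = extract_series(LandmarkSeries("s", "TSK3", 25.0, pts))
        assert feats.shape == (10, 55)
        assert np.allclose(feats.to_numpy(), feats.to_numpy()[0], equal_nan=True)

    def test_short_gap_interpolated_linearly(self):
        base = neutral_template()
        pts = np.stack([base + i for i in range(5)])  # linear motion
        gap = np.array([False, False, True, False, False])
        corrupted = pts.copy()
        corrupted[2] = 0.0
        series = LandmarkSeries("s", "TSK3", 25.0, corrupted, gap)
        feats = extract_series(series)
        oracle = extract_series(LandmarkSeries("s", "TSK3", 25.0, pts))
        assert len(feats) == 5
        pd.testing.assert_frame_equal(feats, oracle)

    def test_long_gap_dropped_consistently(self):
        base = neutral_template()
        n = 50
        pts = np.repeat(base[None], n, axis=0)
        gap = np.zeros(n, dtype=bool)
        gap[10:30] = True          # 0.8 s at 25 FPS: too long to interpolate
        feats = extract_series(LandmarkSeries("s", "TSK3", 25.0, pts, gap))
        assert len(feats) == n - 20

    def test_too_few_frames_error(self):
        pts = np.repeat(neutral_template()[None], 3, axis=0)
        gap = np.array([False, True, True])
        with pytest.raises(facial.InsufficientDataError):
            extract_series(LandmarkSeries("s", "TSK3", 25.0, pts, gap))


class TestSummarize:
    def test_linear_trend(self):
        t = np.arange(0, 101) / 25.0            # 0..4 s at 25 FPS
        s = summarize(2.0 + 0.5 * t, fps=25.0)
        assert s.slope == pytest.approx(0.5)
        assert s.mean == pytest.approx(3.0)
        assert s.range == pytest.approx(2.0)

    def test_constant_series(self):
        s = summarize(np.full(50, 3.3), fps=25.0)
        for v in (s.std, s.rsd, s.se, s.ae):
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_var_equals_std_squared_and_range(self, rng):
        x = rng.normal(size=200)
        s = summarize(x, fps=25.0)
        assert s.var == pytest.approx(s.std**2, abs=0)
        assert s.range == pytest.approx(s.max - s.min, abs=0)

    def test_rsd_scale_invariance(self, rng):
        x = rng.uniform(1.0, 2.0, 100)
        for c in (0.5, 3.0, 100.0):
            assert summarize(c * x, 25.0).rsd == pytest.approx(
                summarize(x, 25.0).rsd, rel=1e-9)

    def test_slope_is_fps_independent_in_time_units(self):
        x = np.linspace(0.0, 1.0, 100)
        s25 = summarize(x, fps=25.0)
        s50 = summarize(np.linspace(0.0, 1.0, 200), fps=50.0)
        # both series traverse one unit over ~4 s
        assert s25.slope == pytest.approx(s50.slope, rel=0.02)

    def test_entropy_nan_below_min_length(self):
        s = summarize(np.array([1.0, 2.0, 3.0]), fps=25.0)
        assert math.isnan(s.se) and math.isnan(s.ae)


def brute_apen(x: np.ndarray, m: int, r: float) -> float:
    """Direct regularity-statistic definition, nested loops."""
    n = len(x)

    def phi(mm):
        nvec = n - mm + 1
        total = 0.0
        for i in range(nvec):
            c = 0
            for j in range(nvec):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / nvec)
        return total / nvec

    return phi(m) - phi(m + 1)


def brute_shannon(x: np.ndarray, bins: int) -> float:
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    width = (hi - lo) / bins
    counts = [0] * bins
    for v in x:
        counts[min(int((v - lo) / width), bins - 1)] += 1
    return -sum(c / len(x) * math.log2(c / len(x)) for c in counts if c)


class TestEntropies:
    def test_apen_constant_zero(self):
        assert approx_entropy(np.ones(30), 2, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_apen_periodic_below_shuffled(self, rng):
        x = np.tile([0.0, 1.0], 50)
        sh = rng.permutation(x)
        r = 0.2 * x.std()
        assert approx_entropy(x, 2, r) < approx_entropy(sh, 2, r)

    def test_apen_too_short_error(self):
        with pytest.raises(facial.InsufficientDataError):
            approx_entropy([1.0, 2.0, 3.0], m=2)

    def test_shannon_one_value_per_bin(self):
        assert shannon_entropy(np.arange(16) + 0.5, bins=16) == pytest.approx(4.0)

    def test_shannon_two_equal_bins(self):
        x = np.array([0.0] * 8 + [1.0] * 8)
        assert shannon_entropy(x, bins=2) == pytest.approx(1.0)

    def test_shannon_bounded_by_log2_bins(self, rng):
        x = rng.normal(size=500)
        assert 0.0 <= shannon_entropy(x, 16) <= 4.0

    @pytest.mark.parametrize("seed", range(10))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=60)
        r = 0.2 * x.std()
        assert approx_entropy(x, 2, r) == pytest.approx(
            brute_apen(x, 2, r), abs=1e-9)
        assert shannon_entropy(x, 16) == pytest.approx(
            brute_shannon(x, 16), abs=1e-9)


class TestSimilarityInvariance:
    @given(tx=st.floats(-50, 50), ty=st.floats(-50, 50), s=st.floats(0.3, 3.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_translation_and_scaling(self, tx, ty, s):
        rng = np.random.default_rng(7)
        pts = np.repeat(neutral_template()[None], 6, axis=0)
        pts += rng.normal(0, 0.5, pts.shape)
        moved = pts * s + np.array([tx, ty])
        a = extract_series(LandmarkSeries("s", "TSK3", 25.0, pts)).to_numpy()
        b = extract_series(LandmarkSeries("s", "TSK3", 25.0, moved)).to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9, rtol=1e-9)


def test_full_extraction_yields_550_scalars(tiny_bundle):
    series = next(iter(tiny_bundle.landmarks.values()))
    feats = extract_series(series)
    scalars = facial.summarize_all(feats, series.fps)
    assert len(scalars) == 550
    assert f"slopeM7" in {k[: len("slopeM7")] for k in scalars}
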