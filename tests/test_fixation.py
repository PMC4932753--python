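"""I-DT fixation detection, viewport geometry and ROI hit-testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilpath import gaze_io
from pupilpath.fixation import (
    assign_roi,
    detect_fixations,
    first_droi_fixation,
    screen_to_slide,
)
from pupilpath.preprocess import CleanRecording
from pupilpath.synthetic import slide_to_screen


def make_clean_xy(x, y, rate=60.0):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    return CleanRecording(
        "P", "C",
        t=np.arange(n) * 1000.0 / rate,
        x=x, y=y,
        d=np.full(n, 13.0), d_raw=np.full(n, 13.0),
        interpolated_mask=np.zeros(n, bool),
        null_fraction=0.0,
        nominal_rate=rate,
    )


def oracle_idt(x, y, n_min, disp):
    """Independent brute-force I-DT: recompute window dispersion from
    scratch with slice max/min at every step."""
    n = len(x)
    segs = []
    i = 0
    while i + n_min <= n:
        def dispersion(a, b):
            return (max(x[a:b]) - min(x[a:b])) + (max(y[a:b]) - min(y[a:b]))
        if dispersion(i, i + n_min) > disp:
            i += 1
            continue
        j = i + n_min
        while j < n and dispersion(i, j + 1) <= disp:
            j += 1
        segs.append((i, j))
        i = j
    return segs


class TestIdt:
    def test_stationary_gaze_is_one_fixation(self):
        clean = make_clean_xy([500.0] * 30, [400.0] * 30)
        fixs = detect_fixations(clean, 41.0, 100.0)
        assert len(fixs) == 1
        assert fixs[0].duration_ms == pytest.approx(29 * 1000.0 / 60.0)
        assert fixs[0].centroid_screen == pytest.approx((500.0, 400.0))
        assert (fixs[0].onset_index, fixs[0].offset_index) == (0, 30)

    def test_always_over_threshold_yields_none(self):
        x = [100.0 if i % 2 else 300.0 for i in range(40)]
        clean = make_clean_xy(x, [500.0] * 40)
        assert detect_fixations(clean, 50.0, 100.0) == []

    def test_three_cluster_scanpath_matches_oracle(self):
        rng = np.random.default_rng(11)
        centers = [(300.0, 300.0), (900.0, 700.0), (1500.0, 300.0)]
        xs, ys = [], []
        for k, (cx, cy) in enumerate(centers):
            xs += list(cx + rng.uniform(-2, 2, 20))
            ys += list(cy + rng.uniform(-2, 2, 20))
            if k < 2:
                nx, ny = centers[k + 1]
                frac = np.linspace(0.2, 0.8, 5)
                xs += list(cx + frac * (nx - cx))
                ys += list(cy + frac * (ny - cy))
        clean = make_clean_xy(xs, ys)
        fixs = detect_fixations(clean, 41.0, 100.0)
        segs = oracle_idt(xs, ys, 7, 41.0)
        assert [(f.onset_index, f.offset_index) for f in fixs] == segs
        assert len(fixs) == 3
        for f, (cx, cy) in zip(fixs, centers):
            assert abs(f.centroid_screen[0] - cx) < 1.0
            assert abs(f.centroid_screen[1] - cy) < 1.0

    @given(st.integers(0, 2 ** 31 - 1), st.floats(-500, 500),
           st.floats(-500, 500))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, seed, dx, dy):
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 15, size=(80, 2))
        pos = 600 + np.cumsum(steps, axis=0)
        clean_a = make_clean_xy(pos[:, 0], pos[:, 1])
        clean_b = make_clean_xy(pos[:, 0] + dx, pos[:, 1] + dy)
        fa = detect_fixations(clean_a, 41.0, 100.0)
        fb = detect_fixations(clean_b, 41.0, 100.0)
        assert [(f.onset_index, f.offset_index) for f in fa] == \
            [(f.onset_index, f.offset_index) for f in fb]

    def test_fixations_are_ordered_and_disjoint(self):
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 20, size=(300, 2))
        pos = 600 + np.cumsum(steps, axis=0)
        fixs = detect_fixations(make_clean_xy(pos[:, 0], pos[:, 1]),
                                41.0, 100.0)
        for a, b in zip(fixs, fixs[1:]):
            assert a.offset_index <= b.onset_index
        for f in fixs:
            assert f.offset_index > f.onset_index


class TestViewportGeometry:
    def test_screen_origin_maps_to_viewport_origin(self):
        s = gaze_io.ViewportState(0.0, 7.0, 123.0, 456.0)
        assert screen_to_slide((0.0, 0.0), s) == (123.0, 456.0)

    def test_identity_zoom(self):
        s = gaze_io.ViewportState(0.0, 1.0, 0.0, 0.0)
        assert screen_to_slide((400.0, 300.0), s) == (400.0, 300.0)

    def test_zoomed_pan_arithmetic(self):
        s = gaze_io.ViewportState(0.0, 10.0, 5000.0, 7000.0)
        assert screen_to_slide((400.0, 300.0), s) == (5040.0, 7030.0)

    def test_slide_to_screen_inverse_example(self):
        s = gaze_io.ViewportState(0.0, 10.0, 5000.0, 7000.0)
        (sx, sy), visible = slide_to_screen((5040.0, 7030.0), s)
        assert (sx, sy) == pytest.approx((400.0, 300.0))
        assert visible

    @given(st.floats(1.0, 60.0), st.floats(0, 30000), st.floats(0, 30000),
           st.floats(0, 1920), st.floats(0, 1080))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, zoom, ox, oy, sx, sy):
        s = gaze_io.ViewportState(0.0, zoom, ox, oy)
        (bx, by), visible = slide_to_screen(screen_to_slide((sx, sy), s), s)
        assert abs(bx - sx) < 1e-9
        assert abs(by - sy) < 1e-9
        assert visible

    def test_offscreen_flag(self):
        s = gaze_io.ViewportState(0.0, 10.0, 5000.0, 7000.0)
        _, visible = slide_to_screen((4000.0, 7000.0), s)
        assert not visible


@pytest.fixture
def square_roi():
    return gaze_io.ROISet("C1", [gaze_io.make_roi(
        "droi-1", [(1000, 1000), (1200, 1000), (1200, 1200), (1000, 1200)])])


@pytest.fixture
def unit_viewport():
    return gaze_io.ViewportTrace([gaze_io.ViewportState(0.0, 1.0, 0.0, 0.0)])


def fix_at(x, y, onset=0):
    from pupilpath.fixation import Fixation
    return Fixation(onset_index=onset, offset_index=onset + 10,
                    onset_t=onset * 1000.0 / 60.0,
                    centroid_screen=(x, y), duration_ms=150.0)


class TestRoiAssignment:
    def test_interior_hit(self, square_roi, unit_viewport):
        assert assign_roi(fix_at(1100, 1100), square_roi,
                          unit_viewport) == "droi-1"

    def test_one_px_outside_misses(self, square_roi, unit_viewport):
        assert assign_roi(fix_at(999.0, 1100), square_roi,
                          unit_viewport) is None

    def test_boundary_counts_as_inside(self, square_roi, unit_viewport):
        assert assign_roi(fix_at(1000.0, 1100.0), square_roi,
                          unit_viewport) == "droi-1"

    def test_first_hit_wins(self, square_roi, unit_viewport):
        fixs = [fix_at(0, 0, 0), fix_at(0, 0, 10), fix_at(0, 0, 20),
                fix_at(0, 0, 30), fix_at(1100, 1100, 40),
                fix_at(0, 0, 50), fix_at(1100, 1100, 60)]
        ev = first_droi_fixation(fixs, square_roi, unit_viewport, "P", "C1")
        assert ev is not None
        assert ev.fixation_number == 4
        assert ev.event_index == 40

    def test_no_hits_gives_none(self, square_roi, unit_viewport):
        fixs = [fix_at(0, 0, i * 10) for i in range(5)]
        assert first_droi_fixation(fixs, square_roi, unit_viewport) is None
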