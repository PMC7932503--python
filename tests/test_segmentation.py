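import numpy as np
import pytest

from bari.cine_io import CineLoop, RoiRect
from bari.phantom import inject_lumen_artefact, simulate_cine, _default_roi
from bari.segmentation import (ContourSet, FrameContour, LevelSetConfig,
                               QcThresholds, WallTraces, extract_wall_traces,
                               qc_recording, segment_lumen)

from conftest import small_spec, wall_errors_px


class TestSegmentLumen:
    def test_phantom_walls_found_within_one_pixel(self, small_loop,
                                                  segmented_small_loop):
        _, _, truth = small_loop
        _, traces = segmented_small_loop
        assert traces.valid_fraction > 0.9
        err = wall_errors_px(traces, truth)
        assert err.mean() < 1.0

    def test_uniform_frames_flag_all_failed(self):
        frames = np.full((4, 80, 40), 3000, dtype=np.uint16)
        loop = CineLoop(frames=frames, pixel_spacing=(0.021, 0.021),
                        frame_interval=0.04)
        roi = RoiRect(30, 50, 10, 30)
        contours = segment_lumen(loop, roi)
        assert all(f.failed for f in contours.frames)

    def test_contour_encloses_seed_rectangle(self, small_loop, small_roi,
                                             segmented_small_loop):
        contours, _ = segmented_small_loop
        roi = small_roi
        for fc in contours.frames:
            if fc.failed:
                continue
            assert np.any(fc.points[:, 0] < roi.row_min)
            assert np.any(fc.points[:, 0] >= roi.row_max)

    def test_segmentation_is_deterministic(self, small_loop, small_roi):
        _, loop, _ = small_loop
        config = LevelSetConfig()
        a = segment_lumen(loop, small_roi, config)
        b = segment_lumen(loop, small_roi, config)
        for fa, fb in zip(a.frames, b.frames):
            assert fa.failed == fb.failed
            assert np.array_equal(fa.points, fb.points)

    def test_error_grows_as_wall_contrast_degrades(self):
        # speckle ladder: stronger multiplicative speckle blurs the wall
        # edge, so localization error must not decrease (one-sided trend
        # with a small sampling allowance)
        means = []
        for contrast in (0.2, 0.8):
            errs = []
            for seed in range(5):
                spec = small_spec(speckle_contrast=contrast)
                loop, truth = simulate_cine(spec, seed=seed)
                roi = _default_roi(spec, truth)
                traces = extract_wall_traces(segment_lumen(loop, roi), roi,
                                             loop)
                errs.append(wall_errors_px(traces, truth).mean())
            means.append(np.mean(errs))
        assert means[1] >= means[0] - 0.02


class TestExtractWallTraces:
    def _contour_set(self, points):
        return ContourSet(frames=[FrameContour(points=np.asarray(points,
                                                                 dtype=float),
                                               iterations=10, residual=0.0)],
                          col_offset=0, col_stop=40)

    def _loop(self):
        frames = np.zeros((2, 100, 40), dtype=np.uint16)
        return CineLoop(frames=frames, pixel_spacing=(0.021, 0.021),
                        frame_interval=0.02)

    def test_multi_valued_contour_columns_are_averaged(self):
        # an "S"-shaped contour giving rows {12, 14} at column 10 reduces
        # to their mean 13
        roi = RoiRect(30, 70, 5, 20)
        pts = [[12.0, 10.0], [14.0, 10.0], [80.0, 10.0]]
        cs = self._contour_set(pts)
        config = LevelSetConfig(subpixel_refine=False)
        tr = extract_wall_traces(cs, roi, self._loop(), config)
        i = int(np.flatnonzero(tr.x_px == 10)[0])
        assert tr.y_t[i, 0] == pytest.approx(13.0)
        assert tr.y_b[i, 0] == pytest.approx(80.0)

    def test_single_valued_contour_passes_through_exactly(self):
        roi = RoiRect(30, 70, 5, 20)
        pts = [[25.5, 8.0], [81.25, 8.0]]
        cs = self._contour_set(pts)
        config = LevelSetConfig(subpixel_refine=False)
        tr = extract_wall_traces(cs, roi, self._loop(), config)
        i = int(np.flatnonzero(tr.x_px == 8)[0])
        assert tr.y_t[i, 0] == 25.5
        assert tr.y_b[i, 0] == 81.25

    def test_inverted_walls_masked_others_kept(self):
        # a cell whose top row does not lie above its bottom row is
        # QC-masked without affecting neighbours (the midline split makes
        # this impossible for raw averages; the guard protects the
        # refinement step)
        from bari.segmentation import _valid_wall_mask

        y_t = np.array([[50.0, 25.0], [26.0, np.nan]])
        y_b = np.array([[45.0, 80.0], [79.0, 81.0]])
        mask = _valid_wall_mask(y_t, y_b)
        assert not mask[0, 0]      # inverted -> masked
        assert mask[0, 1] and mask[1, 0]
        assert not mask[1, 1]      # missing top -> masked

    def test_missing_group_column_is_masked(self):
        roi = RoiRect(30, 70, 5, 20)
        pts = [[25.0, 11.0],                 # top only at column 11
               [25.0, 13.0], [80.0, 13.0]]   # both at column 13
        cs = self._contour_set(pts)
        config = LevelSetConfig(subpixel_refine=False)
        tr = extract_wall_traces(cs, roi, self._loop(), config)
        i11 = int(np.flatnonzero(tr.x_px == 11)[0])
        i13 = int(np.flatnonzero(tr.x_px == 13)[0])
        assert not tr.qc_mask[i11, 0]
        assert tr.qc_mask[i13, 0]

    def test_failed_frames_fully_masked(self):
        roi = RoiRect(30, 70, 5, 20)
        cs = ContourSet(frames=[FrameContour(points=np.empty((0, 2)),
                                             iterations=400, residual=50.0,
                                             failed=True, reason="x")],
                        col_offset=0, col_stop=40)
        tr = extract_wall_traces(cs, roi, self._loop(), LevelSetConfig())
        assert not tr.qc_mask.any()


class TestQcRecording:
    def test_clean_phantom_is_usable(self, small_loop, segmented_small_loop):
        _, loop, _ = small_loop
        _, traces = segmented_small_loop
        verdict = qc_recording(traces, QcThresholds(), cine=loop)
        assert verdict.usable
        assert verdict.reasons == ()

    def test_intraluminal_artefact_is_excluded(self):
        spec = small_spec()
        loop, truth = simulate_cine(spec, seed=11)
        bright = inject_lumen_artefact(loop, truth, intensity=0.8,
                                       thickness_px=10)
        roi = _default_roi(spec, truth)
        contours = segment_lumen(bright, roi)
        traces = extract_wall_traces(contours, roi, bright)
        verdict = qc_recording(traces, QcThresholds(), cine=bright)
        assert not verdict.usable
        assert "intraluminal artefact" in verdict.reasons or \
            "insufficient valid wall samples" in verdict.reasons

    def test_mask_fraction_threshold(self):
        nx, nt = 10, 10
        qc = np.zeros((nx, nt), dtype=bool)
        qc[:, :4] = True  # 60% masked
        y_t = np.where(qc, 30.0, np.nan)
        y_b = np.where(qc, 70.0, np.nan)
        tr = WallTraces(x_px=np.arange(nx, dtype=float),
                        x_mm=np.arange(nx) * 0.021, y_t=y_t, y_b=y_b,
                        qc_mask=qc, pixel_spacing=(0.021, 0.021),
                        frame_interval=0.02)
        verdict = qc_recording(tr, QcThresholds(mask_fraction=0.5))
        assert not verdict.usable
        assert "insufficient valid wall samples" in verdict.reasons

    def test_discontinuous_trace_excluded(self):
        nx, nt = 10, 10
        qc = np.ones((nx, nt), dtype=bool)
        y_t = np.full((nx, nt), 30.0)
        y_t[:, 5:] = 50.0  # 20 px jump between frames 4 and 5
        y_b = np.full((nx, nt), 80.0)
        tr = WallTraces(x_px=np.arange(nx, dtype=float),
                        x_mm=np.arange(nx) * 0.021, y_t=y_t, y_b=y_b,
                        qc_mask=qc, pixel_spacing=(0.021, 0.021),
                        frame_interval=0.02)
        verdict = qc_recording(tr, QcThresholds(jump_px=5.0))
        assert not verdict.usable
        assert "discontinuous wall trace" in verdict.reasons
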