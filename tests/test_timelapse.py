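"""Registration, region detection, smoothing, PIV, divergence, tracking."""

import math

import numpy as np
import pytest

from plumaquant import (
    FlowSpec,
    ImageFrame,
    SceneSpec,
    VelocityField,
    aggregate_aligned,
    compute_piv,
    detect_regions,
    field_divergence,
    generate_texture,
    generate_timelapse,
    region_motility,
    register_drift,
    smooth_and_align,
    track_primordia,
)
from plumaquant.errors import (
    FieldTooSmallError,
    FrameMismatchError,
    GridTooSmallError,
    InvalidTrefError,
    RegionOutOfBoundsError,
)
from plumaquant.timelapse import aggregate_aligned as _agg  # noqa: F401


def uniform_field(nr=5, nc=5, u=0.0, v=0.0, stride_um=16.0):
    return VelocityField(
        u=np.full((nr, nc), float(u)),
        v=np.full((nr, nc), float(v)),
        valid=np.ones((nr, nc), dtype=bool),
        box_stride_um=stride_um,
    )


class TestRegisterDrift:
    def test_identical_frames_zero_shift(self):
        fr = generate_texture(SceneSpec(128, 128, 1.0, seed=1))
        aligned, shifts, low = register_drift([fr, fr, fr])
        np.testing.assert_array_equal(shifts, 0)
        assert not low.any()

    def test_planted_translation_recovered(self):
        fr = generate_texture(SceneSpec(128, 128, 1.0, seed=2))
        moved = fr.with_pixels(np.roll(fr.pixels, (5, -3), axis=(0, 1)))
        aligned, shifts, low = register_drift([fr, moved])
        assert tuple(shifts[1]) == (5, -3)
        # edges are replication-filled; compare away from the border
        np.testing.assert_array_equal(
            aligned[1].pixels[8:-8, 8:-8], fr.pixels[8:-8, 8:-8]
        )

    def test_pure_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(0)
        a = ImageFrame(rng.uniform(0, 100, (128, 128)), 1.0)
        b = ImageFrame(rng.uniform(0, 100, (128, 128)), 1.0)
        _, _, low = register_drift([a, b])
        assert low[1]

    def test_geometry_mismatch_rejected(self):
        a = ImageFrame(np.zeros((64, 64)), 1.0)
        b = ImageFrame(np.zeros((64, 48)), 1.0)
        with pytest.raises(FrameMismatchError):
            register_drift([a, b])


class TestDetectRegions:
    def test_planted_hot_stripe(self):
        amp = np.full((6, 12), 0.05)
        amp[:, 4:7] = 0.4
        reg = detect_regions(amp)
        assert reg.segment_cols == (4, 5, 6)

    def test_uniform_map_leftmost_tie_break(self):
        reg = detect_regions(np.full((4, 9), 0.2))
        assert reg.segment_cols == (0, 1, 2)

    def test_planted_extrema_in_4box_sets(self):
        amp = np.full((6, 9), 0.2)
        amp[:, 3:6] = 0.3
        hot = [(0, 3), (2, 4), (4, 5), (5, 3)]
        cold = [(1, 4), (3, 5), (5, 4), (0, 5)]
        for r, c in hot:
            amp[r, c] = 0.6
        for r, c in cold:
            amp[r, c] = 0.05
        reg = detect_regions(amp)
        assert reg.segment_cols == (3, 4, 5)
        assert set(reg.ip_boxes_4) == set(hot)
        assert set(reg.p_boxes_4) == set(cold)
        assert set(reg.ip_boxes_4).isdisjoint(reg.p_boxes_4)

    def test_nine_box_blocks_are_3x3_on_middle_column(self):
        amp = np.full((8, 9), 0.2)
        amp[:, 3:6] = 0.3
        for r, c in [(1, 3), (1, 4), (2, 3), (2, 4)]:
            amp[r, c] = 0.6
        for r, c in [(6, 4), (6, 5), (7, 4), (7, 5)]:
            amp[r, c] = 0.05
        reg = detect_regions(amp)
        for block in (reg.ip_boxes_9, reg.p_boxes_9):
            assert len(block) == 9
            rows = sorted({r for r, _ in block})
            cols = sorted({c for _, c in block})
            assert len(rows) == 3 and rows[2] - rows[0] == 2
            assert cols == [3, 4, 5]  # centred on segment middle column
            assert all(0 <= r < 8 for r, _ in block)

    def test_too_few_columns_rejected(self):
        with pytest.raises(GridTooSmallError):
            detect_regions(np.ones((5, 2)))

    @pytest.mark.parametrize("seed", range(20))
    def test_synthetic_stripe_recovery(self, seed):
        from plumaquant.synthetic import generate_striped_texture
        from plumaquant import anisotropy_map, make_grid

        spec = SceneSpec(480, 480, 0.5, 1.0, 0.0, 0.75, 0.5, seed=seed)
        frame = generate_striped_texture(spec, (200, 300), 2.0)
        amap = anisotropy_map(frame, make_grid(frame, 25.0, 0.5))
        reg = detect_regions(np.where(amap.degenerate, 0.0, amap.amplitude))
        assert reg.segment_cols == (8, 9, 10)


class TestSmoothAndAlign:
    def test_constant_series_unchanged(self):
        s = smooth_and_align(np.full(50, 3.5), t_ref_frame=10)
        np.testing.assert_allclose(s.values, 3.5)

    def test_linear_ramp_preserved(self):
        ramp = np.arange(60, dtype=float)
        s = smooth_and_align(ramp, t_ref_frame=0, window_frames=30)
        np.testing.assert_allclose(s.values, ramp, atol=1e-9)

    def test_time_axis_zeroed_at_tref(self):
        s = smooth_and_align(np.arange(20.0), t_ref_frame=8, frame_interval_min=5.0)
        assert s.time_min[8] == 0.0
        assert s.time_min[0] == -40.0

    def test_tref_outside_rejected(self):
        with pytest.raises(InvalidTrefError):
            smooth_and_align(np.arange(10.0), t_ref_frame=10)

    def test_nan_interpolated_on_even_grid(self):
        vals = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        s = smooth_and_align(vals, t_ref_frame=0, window_frames=1)
        np.testing.assert_allclose(s.values, [0, 1, 2, 3, 4])

    def test_t_ref_heuristic_finds_amplitude_drop(self):
        from plumaquant.timelapse import suggest_t_ref

        rng = np.random.default_rng(0)
        series = 0.3 + 0.01 * rng.standard_normal(80)
        series[50:] -= 0.15  # condensation: P-region amplitude drops
        assert suggest_t_ref(series, baseline_frames=30) == 50
        flat = 0.3 + 0.01 * rng.standard_normal(80)
        assert suggest_t_ref(flat, baseline_frames=30) is None

    def test_aggregate_two_movies_on_shared_support(self):
        a = smooth_and_align(np.arange(10.0), t_ref_frame=4, window_frames=1)
        b = smooth_and_align(np.arange(10.0, 20.0), t_ref_frame=6, window_frames=1)
        agg = aggregate_aligned([a, b])
        # shared aligned frames: [-4..5] & [-6..3] -> [-4..3]
        np.testing.assert_array_equal(agg.aligned_frames, np.arange(-4, 4))
        # mean of (frame+4) and (frame+16) at aligned frame f
        np.testing.assert_allclose(
            agg.values, (np.arange(0, 8) + np.arange(12, 20)) / 2.0
        )


class TestPIV:
    def test_identical_frames_zero_field(self):
        fr = generate_texture(SceneSpec(160, 160, 0.5, seed=3))
        f = compute_piv(fr, fr, frame_interval_min=5.0)
        np.testing.assert_allclose(f.speed, 0.0, atol=1e-9)

    @pytest.mark.parametrize("shift", [(3, 0), (0, 5), (-4, 2), (8, -8)])
    def test_integer_shift_exact(self, shift):
        fr = generate_texture(SceneSpec(192, 192, 0.5, 1.0, 0.0, 1.0, 0.0, seed=4))
        moved = fr.with_pixels(np.roll(fr.pixels, shift, axis=(0, 1)))
        f = compute_piv(fr, moved, frame_interval_min=5.0, subpixel=False)
        to_px = 1.0 / (0.5 * 12.0)
        np.testing.assert_allclose(f.v * to_px, shift[0], atol=1e-9)
        np.testing.assert_allclose(f.u * to_px, shift[1], atol=1e-9)

    def test_unit_conversion_3px_per_frame(self):
        fr = generate_texture(SceneSpec(192, 192, 0.5, 1.0, 0.0, 1.0, 0.0, seed=4))
        moved = fr.with_pixels(np.roll(fr.pixels, (3, 0), axis=(0, 1)))
        f = compute_piv(fr, moved, frame_interval_min=5.0, subpixel=False)
        np.testing.assert_allclose(f.speed, 18.0, atol=1e-9)

    def test_subpixel_half_pixel_shift(self):
        from scipy import ndimage

        fr = generate_texture(SceneSpec(256, 256, 0.5, 1.0, 0.0, 1.0, 0.0, seed=4))
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        moved = fr.with_pixels(
            np.maximum(
                ndimage.map_coordinates(fr.pixels, [yy - 0.5, xx], order=3, mode="reflect"),
                0.0,
            )
        )
        f = compute_piv(fr, moved, frame_interval_min=5.0)
        dy_px = f.v / (0.5 * 12.0)
        assert abs(dy_px.mean() - 0.5) <= 0.2

    def test_galilean_consistency(self):
        fr = generate_texture(SceneSpec(224, 224, 0.5, 1.0, 0.0, 1.0, 0.0, seed=6))
        m1 = fr.with_pixels(np.roll(fr.pixels, (2, 0), axis=(0, 1)))
        m2 = fr.with_pixels(np.roll(fr.pixels, (6, 0), axis=(0, 1)))
        f1 = compute_piv(fr, m1, frame_interval_min=5.0, subpixel=False)
        f2 = compute_piv(fr, m2, frame_interval_min=5.0, subpixel=False)
        dv_px = (f2.v - f1.v) / (0.5 * 12.0)
        assert np.abs(dv_px - 4.0).max() <= 0.2
        fs1 = compute_piv(fr, m1, frame_interval_min=5.0)
        fs2 = compute_piv(fr, m2, frame_interval_min=5.0)
        assert abs((fs2.v - fs1.v).mean() / (0.5 * 12.0) - 4.0) <= 0.2

    def test_flat_windows_invalid(self):
        a = ImageFrame(np.zeros((64, 64)), 1.0)
        f = compute_piv(a, a, frame_interval_min=5.0)
        assert not f.valid.any()

    def test_planted_uniform_flow_recovered(self):
        scene = SceneSpec(256, 256, 0.5, 1.0, 0.0, 1.0, 1.0, seed=5)
        flow = FlowSpec(
            model="uniform", uniform_velocity_um_per_h=(9.0, 0.0), n_frames=3
        )
        res = generate_timelapse(scene, flow)
        f = compute_piv(res.frames[0], res.frames[1], frame_interval_min=5.0)
        assert np.mean(f.speed) == pytest.approx(9.0, rel=0.10)

    def test_motility_recovery_random_walk(self):
        # step sd calibrated so the mean 2D step norm matches the target speed
        for target in (4.5, 10.0):
            sd_um = target * (5.0 / 60.0) / math.sqrt(math.pi / 2.0)
            flow = FlowSpec(
                model="random_walk", random_step_sd_um=sd_um, n_frames=8, seed=3
            )
            res = generate_timelapse(
                SceneSpec(256, 256, 0.5, 1.0, 0.0, 1.0, 1.0, seed=8), flow
            )
            speeds = [
                np.mean(
                    compute_piv(
                        res.frames[k], res.frames[k + 1], frame_interval_min=5.0
                    ).speed
                )
                for k in range(len(res.frames) - 1)
            ]
            truth = np.mean(
                np.hypot(res.true_velocity_um_h[..., 0], res.true_velocity_um_h[..., 1])
            )
            assert np.mean(speeds) == pytest.approx(truth, rel=0.20)


class TestRegionMotility:
    def test_uniform_speed_pass_through(self):
        f = uniform_field(u=10.0)
        speed, n_bad = region_motility(f, [(r, c) for r in range(3) for c in range(3)])
        assert speed == 10.0 and n_bad == 0

    def test_arithmetic_mean_of_norms(self):
        f = uniform_field()
        f.u = np.arange(25, dtype=float).reshape(5, 5) + 1.0  # norms 1..25
        region = [(r, c) for r in range(3) for c in range(3)]
        speed, _ = region_motility(f, region)
        expected = np.mean([f.u[r, c] for r, c in region])
        assert speed == pytest.approx(expected)

    def test_region_out_of_bounds(self):
        with pytest.raises(RegionOutOfBoundsError):
            region_motility(uniform_field(), [(4, 4), (4, 5), (5, 4)])


class TestDivergence:
    def test_uniform_field_zero_divergence(self):
        div = field_divergence(uniform_field(u=7.0, v=-2.0))
        np.testing.assert_allclose(div, 0.0, atol=1e-12)

    def test_linear_field_exact_2c(self):
        c = 0.03
        nr = nc = 7
        stride = 16.0
        x = np.arange(nc) * stride
        y = np.arange(nr) * stride
        xx, yy = np.meshgrid(x, y)
        f = VelocityField(
            u=c * xx, v=c * yy, valid=np.ones((nr, nc), bool), box_stride_um=stride
        )
        div = field_divergence(f)
        np.testing.assert_allclose(div, 2 * c, atol=1e-12)

    def test_divergence_linearity(self):
        rng = np.random.default_rng(1)
        stride = 10.0
        fa = VelocityField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)),
                           np.ones((6, 6), bool), stride)
        fb = VelocityField(rng.normal(size=(6, 6)), rng.normal(size=(6, 6)),
                           np.ones((6, 6), bool), stride)
        fsum = VelocityField(fa.u + fb.u, fa.v + fb.v, np.ones((6, 6), bool), stride)
        np.testing.assert_allclose(
            field_divergence(fsum), field_divergence(fa) + field_divergence(fb),
            atol=1e-12,
        )

    def test_planted_sink_negative_region_divergence(self):
        scene = SceneSpec(256, 256, 0.5, 1.0, 0.0, 1.0, 1.0, seed=6)
        flow = FlowSpec(
            model="sink", sink_centers=((64.0, 64.0),), sink_strength_per_h=0.5,
            n_frames=2,
        )
        res = generate_timelapse(scene, flow)
        f = compute_piv(res.frames[0], res.frames[1], frame_interval_min=5.0)
        r, c = np.unravel_index(
            np.argmin(np.hypot(res.box_centers_x_um - 64, res.box_centers_y_um - 64)),
            f.shape,
        )
        region = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        _, region_div = field_divergence(f, region)
        assert region_div < 0.0

    def test_small_field_rejected(self):
        with pytest.raises(FieldTooSmallError):
            field_divergence(uniform_field(nr=2, nc=5))


class TestTracking:
    def test_static_blob_single_constant_track(self, disc_frame_factory):
        frames = [disc_frame_factory([(100, 100)]) for _ in range(8)]
        tracks = track_primordia(frames, 0.30, 0, 300, gate_px=10)
        assert len(tracks) == 1
        assert tracks[0].start_frame == 0 and tracks[0].end_frame == 7
        assert np.ptp(tracks[0].positions_px) <= 0.5

    def test_advected_blob_slope(self, disc_frame_factory):
        frames = [disc_frame_factory([(60 + 2 * k, 100)]) for k in range(12)]
        tracks = track_primordia(frames, 0.30, 0, 300, gate_px=10)
        assert len(tracks) == 1
        slope = np.polyfit(np.arange(12), tracks[0].positions_px, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_merge_produces_single_fusion_event(self, disc_frame_factory):
        frames = [
            disc_frame_factory([(60 + 5 * k, 100), (140 - 4 * k, 100)])
            for k in range(10)
        ]
        tracks = track_primordia(frames, 0.30, 0, 300, gate_px=20)
        assert len(tracks) == 2
        fusions = [(f, tid) for t in tracks for f, tid in t.fusion_events]
        assert len(fusions) == 1
        merge_frame = fusions[0][0]
        open_before = sum(
            1 for t in tracks if t.start_frame <= merge_frame - 1 <= t.end_frame
        )
        open_after = sum(
            1 for t in tracks if t.start_frame <= merge_frame <= t.end_frame
        )
        assert (open_before, open_after) == (2, 1)
        assert sum(t.ended_by_fusion for t in tracks) == 1

    def test_track_count_drops_only_at_fusion(self, disc_frame_factory):
        frames = [
            disc_frame_factory([(50 + 5 * k, 60), (150 - 4 * k, 60), (100, 160)])
            for k in range(12)
        ]
        tracks = track_primordia(frames, 0.30, 0, 300, gate_px=20)
        n_open = [
            sum(1 for t in tracks if t.start_frame <= k <= t.end_frame)
            for k in range(12)
        ]
        drops = [n_open[i] - n_open[i + 1] for i in range(11)]
        fusion_frames = {f for t in tracks for f, _ in t.fusion_events}
        assert all(d in (0, 1) for d in drops)
        assert sum(drops) == len(fusion_frames) == 1

    def test_empty_movie_no_tracks(self):
        frames = [ImageFrame(np.zeros((64, 64)), 1.0)] * 3
        assert track_primordia(frames, 0.3, 0, 100, gate_px=5) == []
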