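import numpy as np
import pytest
from scipy import ndimage

from vckulm import (Detection, FrameStack, MotionConfig,
                    compensate_detections, dp_search_vs_exhaustive,
                    estimate_displacement_field, ncc, ncc_fast,
                    parabolic_subpixel_offset)
from vckulm.motion import prefix_sum_table, window_sum


class TestNCC:
    def test_identical_block_is_one(self, textured_frame):
        block = textured_frame[10:26, 10:26]
        assert ncc(block, block) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        a = np.zeros((4, 4))
        a[:2] = 1.0
        b = np.zeros((4, 4))
        b[2:] = 1.0
        assert ncc(a, b) == 0.0

    def test_proportional_blocks_correlate_perfectly_and_scale_invariant(self):
        s_r = np.array([[1.0, 2.0], [3.0, 4.0]])
        s_d = np.array([[2.0, 4.0], [6.0, 8.0]])
        assert ncc(s_r, s_d) == pytest.approx(1.0)
        # oracle: direct double-sum evaluation
        direct = (s_r * s_d).sum() / np.sqrt((s_r**2).sum() * (s_d**2).sum())
        assert ncc(s_r, s_d) == pytest.approx(direct)
        for c in (0.1, 3.0, 1e4):
            assert ncc(s_r * c, s_d) == pytest.approx(ncc(s_r, s_d))

    def test_zero_energy_returns_zero(self):
        assert ncc(np.zeros((3, 3)), np.ones((3, 3))) == 0.0


class TestPrefixSums:
    def test_rectangle_sums_match_direct_summation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(40, 50))
        table = prefix_sum_table(a)
        for _ in range(100):
            r0 = rng.integers(0, 35)
            c0 = rng.integers(0, 45)
            h = rng.integers(1, 40 - r0)
            w = rng.integers(1, 50 - c0)
            assert window_sum(table, r0, c0, h, w) == \
                pytest.approx(a[r0:r0 + h, c0:c0 + w].sum(), abs=1e-9)


class TestNCCFast:
    def test_matches_bruteforce_on_random_frames(self):
        rng = np.random.default_rng(1)
        shifts = [(dx, dy) for dx in range(-3, 4) for dy in range(-3, 4)]
        for _ in range(10):
            ref = rng.random((64, 64))
            tgt = rng.random((64, 64))
            block = (20, 20, 16, 16)
            fast = ncc_fast(ref, tgt, block, shifts)
            r0, c0, h, w = block
            ref_block = ref[r0:r0 + h, c0:c0 + w]
            for (dx, dy) in shifts:
                direct = ncc(ref_block,
                             tgt[r0 + dy:r0 + dy + h, c0 + dx:c0 + dx + w])
                assert abs(fast[(dx, dy)] - direct) < 1e-10

    def test_all_ones_frames_give_unit_correlation(self):
        ones = np.ones((32, 32))
        out = ncc_fast(ones, ones, (8, 8, 16, 16),
                       [(0, 0), (1, -1), (-2, 2)])
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_zero_mean_variant_matches_direct(self):
        rng = np.random.default_rng(2)
        ref = rng.random((40, 40))
        tgt = rng.random((40, 40))
        block = (10, 10, 16, 16)
        fast = ncc_fast(ref, tgt, block, [(1, 1), (-2, 0)], zero_mean=True)
        r0, c0, h, w = block
        for (dx, dy) in fast:
            direct = ncc(ref[r0:r0 + h, c0:c0 + w],
                         tgt[r0 + dy:r0 + dy + h, c0 + dx:c0 + dx + w],
                         zero_mean=True)
            assert abs(fast[(dx, dy)] - direct) < 1e-10


class TestParabolicFit:
    def test_symmetric_samples_give_zero(self):
        xi, flag = parabolic_subpixel_offset(0.5, 1.0, 0.5)
        assert xi == 0.0 and not flag

    def test_known_parabola_vertex_recovered_exactly(self):
        # R(u) = 1 - (u - 0.2)^2 sampled at u in {-1, 0, 1}
        xi, flag = parabolic_subpixel_offset(-0.44, 0.96, 0.36)
        assert xi == pytest.approx(0.2, abs=1e-15) and not flag

    def test_vertex_sweep_exact(self):
        for v in np.linspace(-0.4, 0.4, 81):
            r = lambda u: 1 - (u - v) ** 2
            xi, flag = parabolic_subpixel_offset(r(-1), r(0), r(1))
            assert not flag
            assert abs(xi - v) < 1e-12

    def test_flat_samples_flagged(self):
        xi, flag = parabolic_subpixel_offset(1.0, 1.0, 1.0)
        assert xi == 0.0 and flag


def _shifted_stack(base, shifts, order=1):
    frames = [ndimage.shift(base, (dy, dx), order=order, mode="nearest")
              for (dx, dy) in shifts]
    return FrameStack(frames=np.stack(frames), frame_rate=100.0)


SMALL = MotionConfig(block_size=16, block_stride=16, search_range=4)


class TestDisplacementField:
    def test_static_stack_zero_field_unit_corr(self, textured_frame):
        stack = FrameStack(frames=np.tile(textured_frame, (5, 1, 1)),
                           frame_rate=100.0)
        fields = estimate_displacement_field(stack, SMALL)
        for fld in fields:
            assert np.all(fld.dx_grid == 0) and np.all(fld.dy_grid == 0)
            assert np.all(fld.peak_corr == pytest.approx(1.0))

    def test_reference_frame_field_identically_zero(self, textured_frame):
        stack = _shifted_stack(textured_frame, [(1, 0), (0, 0), (-1, 0)])
        fields = estimate_displacement_field(stack, SMALL)
        ref = fields[1]
        assert np.all(ref.dx_grid == 0) and np.all(ref.dy_grid == 0)

    def test_integer_self_shift_recovered_exactly(self, textured_frame):
        # target = reference translated by integer (+3, -2)
        base = textured_frame
        shifted = np.zeros_like(base)
        shifted[:-0 or None, :] = ndimage.shift(base, (-2, 3), order=0,
                                                mode="nearest")
        stack = FrameStack(frames=np.stack([base, base, shifted]),
                           frame_rate=100.0)
        fields = estimate_displacement_field(stack, SMALL)
        fld = fields[2]
        interior = fld.peak_corr > 0.999
        assert interior.sum() >= 4
        assert np.all(fld.dx_grid[interior] == 3.0)
        assert np.all(fld.dy_grid[interior] == -2.0)

    def test_subpixel_shifts_recovered_within_tenth_pixel(self, textured_frame):
        rng = np.random.default_rng(3)
        shifts = [(0.0, 0.0)] + [tuple(rng.uniform(-0.4, 0.4, 2))
                                 for _ in range(6)]
        stack = _shifted_stack(textured_frame, shifts)
        cfg = MotionConfig(block_size=32, block_stride=16, search_range=2)
        fields = estimate_displacement_field(stack, cfg)
        ref_idx = len(shifts) // 2
        ref_dx, ref_dy = shifts[ref_idx]
        errors = []
        for fld, (dx, dy) in zip(fields, shifts):
            errors.append(np.abs(fld.dx_grid - (dx - ref_dx)).mean())
            errors.append(np.abs(fld.dy_grid - (dy - ref_dy)).mean())
        assert np.mean(errors) < 0.1

    def test_scale_invariance_of_estimates(self, textured_frame):
        stack = _shifted_stack(textured_frame, [(0.3, -0.2), (0, 0), (-0.3, 0.2)])
        f1 = estimate_displacement_field(stack, SMALL)
        scaled = FrameStack(frames=stack.frames * 7.3, frame_rate=100.0)
        f2 = estimate_displacement_field(scaled, SMALL)
        for a, b in zip(f1, f2):
            assert np.allclose(a.dx_grid, b.dx_grid, atol=1e-9)
            assert np.allclose(a.dy_grid, b.dy_grid, atol=1e-9)

    def test_compensation_then_reestimation_near_zero(self, textured_frame):
        """Rigidly shifted stack: estimating, resampling each frame back,
        then re-estimating leaves a residual field < 0.05 px RMS."""
        shifts = [(2.0, -1.0), (1.0, -0.5), (0.0, 0.0), (-1.0, 0.5),
                  (-2.0, 1.0)]
        stack = _shifted_stack(textured_frame, shifts)
        fields = estimate_displacement_field(stack, SMALL)
        corrected = []
        for k, fld in enumerate(fields):
            dx = float(np.mean(fld.dx_grid))
            dy = float(np.mean(fld.dy_grid))
            corrected.append(ndimage.shift(stack.frames[k], (-dy, -dx),
                                           order=1, mode="nearest"))
        stack2 = FrameStack(frames=np.stack(corrected), frame_rate=100.0)
        fields2 = estimate_displacement_field(stack2, SMALL)
        residual = np.sqrt(np.mean([
            (fld.dx_grid**2 + fld.dy_grid**2).mean() for fld in fields2]))
        assert residual < 0.05


class TestDPSearch:
    def test_smooth_sinusoidal_motion_full_agreement(self, textured_frame):
        t = np.arange(9)
        shifts = [(2.0 * np.sin(2 * np.pi * k / 9), 0.0) for k in t]
        stack = _shifted_stack(textured_frame, shifts)
        report = dp_search_vs_exhaustive(stack, SMALL)
        assert report["agreement_fraction"] == 1.0

    def test_zero_motion_trivially_identical(self, textured_frame):
        stack = FrameStack(frames=np.tile(textured_frame, (4, 1, 1)),
                           frame_rate=100.0)
        report = dp_search_vs_exhaustive(stack, SMALL)
        assert report["agreement_fraction"] == 1.0

    def test_discontinuous_motion_disagreement_reported(self):
        # adversarial: periodic texture + jump beyond the local basin can
        # defeat the seeded search; any disagreement must be reported
        yy, xx = np.mgrid[0:64, 0:64]
        base = np.sin(2 * np.pi * xx / 8.0) + 2.0
        shifts = [(0, 0), (0, 0), (4, 0)]
        stack = _shifted_stack(base, shifts, order=0)
        report = dp_search_vs_exhaustive(stack, SMALL)
        assert report["n_informative_blocks"] == \
            report["n_agree"] + len(report["disagreements"])


class TestCompensateDetections:
    def _uniform_fields(self, n_frames, dx, dy, grid=(3, 3)):
        cx = np.tile(np.arange(grid[1]) * 16.0 + 8, (grid[0], 1))
        cy = np.tile((np.arange(grid[0]) * 16.0 + 8)[:, None], (1, grid[1]))
        from vckulm import DisplacementField
        return [DisplacementField(frame=f, center_x=cx, center_y=cy,
                                  dx_grid=np.full(grid, dx),
                                  dy_grid=np.full(grid, dy),
                                  peak_corr=np.ones(grid))
                for f in range(n_frames)]

    def test_zero_field_is_identity(self):
        dets = [Detection(0, 10.3, 20.7, 5.0)]
        out = compensate_detections(dets, self._uniform_fields(1, 0.0, 0.0))
        assert out[0].x == 10.3 and out[0].y == 20.7

    def test_uniform_field_shifts_all_detections(self):
        dets = [Detection(0, 10.0, 20.0, 5.0), Detection(0, 30.0, 15.0, 2.0)]
        out = compensate_detections(dets, self._uniform_fields(1, 3.0, -2.0))
        for before, after in zip(dets, out):
            assert after.x == pytest.approx(before.x - 3.0)
            assert after.y == pytest.approx(before.y + 2.0)
            assert after.brightness == before.brightness

    def test_static_landmarks_return_to_rest_after_compensation(self,
                                                                 textured_frame):
        """Sinusoidal tissue motion applied to a textured scene with bright
        static point landmarks: after estimating the displacement fields and
        compensating the per-frame landmark detections, the landmarks sit at
        their reference-frame positions within 0.15 px RMS."""
        from vckulm import LocalizationConfig, localize_frame
        from conftest import gaussian_blob
        rng = np.random.default_rng(7)
        landmarks = [(rng.uniform(20, 60), rng.uniform(20, 60))
                     for _ in range(6)]
        base = textured_frame.copy()
        for (x, y) in landmarks:
            base += gaussian_blob(base.shape, x, y, sigma=1.2, amplitude=30.0)
        n = 15
        t = np.arange(n)
        shifts = list(zip(1.5 * np.sin(2 * np.pi * t / 12),
                          0.8 * np.sin(2 * np.pi * t / 12 + 0.7)))
        stack = _shifted_stack(base, shifts)
        fields = estimate_displacement_field(
            stack, MotionConfig(block_size=32, block_stride=16, search_range=3))
        cfg = LocalizationConfig(min_peak_intensity=10.0)
        dets = []
        for k in range(n):
            dets.extend(localize_frame(stack.frames[k], cfg, frame_index=k))
        comp = compensate_detections(dets, fields)
        ref_dx, ref_dy = shifts[n // 2]
        errs = []
        for d in comp:
            e = min(np.hypot(d.x - (x + ref_dx), d.y - (y + ref_dy))
                    for (x, y) in landmarks)
            errs.append(e)
        assert len(errs) >= 5 * len(landmarks)
        assert np.sqrt(np.mean(np.square(errs))) < 0.15

    def test_missing_frame_field_raises(self):
        with pytest.raises(KeyError):
            compensate_detections([Detection(5, 1, 1, 1)],
                                  self._uniform_fields(1, 0, 0))
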