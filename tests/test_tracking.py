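import itertools

import numpy as np
import pytest

from vckulm import (Detection, Track, TrackState, TrackerConfig,
                    kalman_predict, kalman_update, match_cost, match_frame,
                    statistical_velocity, track_identity_f1, track_stack,
                    track_stack_nn)


def _state(S, P=None, **kw):
    return TrackState(S=np.asarray(S, float),
                      P=np.eye(5) if P is None else P, **kw)


CFG = TrackerConfig()


class TestKalmanPredict:
    def test_constant_velocity_arithmetic(self):
        out = kalman_predict(_state([0, 0, 5, 1, 2]), CFG)
        assert np.allclose(out.S, [1, 2, 5, 1, 2])

    def test_zero_velocity_leaves_position_and_grows_covariance(self):
        s = _state([3, 4, 2, 0, 0])
        out = kalman_predict(s, CFG)
        assert np.allclose(out.S[:2], [3, 4])
        assert np.all(np.linalg.eigvalsh(out.P - s.P @ np.zeros((5, 5))) >= -1e-9)
        assert out.P[2, 2] > s.P[2, 2]

    def test_ten_chained_predictions_advance_exactly(self):
        s = _state([0, 0, 1, 1, 0])
        for _ in range(10):
            s = kalman_predict(s, CFG)
        assert s.S[0] == 10.0


class TestKalmanUpdate:
    def test_huge_measurement_noise_keeps_prediction(self):
        # K -> 0: the estimate is solely the predicted state
        cfg = TrackerConfig(r_pos=1e12, r_i=1e12)
        s = _state([1, 2, 3, 0.5, 0.5], P=np.eye(5) * 1e-6)
        out = kalman_update(s, (10, 20, 30), cfg)
        assert np.allclose(out.S, s.S, atol=1e-4)

    def test_huge_prior_uncertainty_adopts_measurement(self):
        # K -> identity on observed components: estimate = measurement
        cfg = TrackerConfig(r_pos=1e-9, r_i=1e-9)
        s = _state([1, 2, 3, 0, 0], P=np.eye(5) * 1e6)
        out = kalman_update(s, (10, 20, 30), cfg)
        assert np.allclose(out.S[:3], [10, 20, 30], atol=1e-3)

    def test_equal_uncertainty_gives_midpoint(self):
        # 1D hand algebra: P = R on an observed axis => K = 0.5 and the
        # estimate is the midpoint of prediction and measurement
        cfg = TrackerConfig(r_pos=2.0, r_i=2.0)
        P = np.diag([2.0, 2.0, 2.0, 1.0, 1.0])
        s = _state([0, 0, 0, 0, 0], P=P)
        out = kalman_update(s, (4, 6, 8), cfg)
        assert np.allclose(out.S[:3], [2, 3, 4], atol=1e-12)

    def test_covariance_stays_symmetric_psd_through_1000_cycles(self):
        rng = np.random.default_rng(0)
        s = _state([0, 0, 5, 1, 0],
                   P=np.diag([0.1, 0.1, 1.0, 25.0, 25.0]))
        for k in range(1000):
            s = kalman_predict(s, CFG)
            z = s.S[:3] + rng.normal(0, 0.1, 3)
            s = kalman_update(s, z, CFG)
            assert np.allclose(s.P, s.P.T)
            assert np.linalg.eigvalsh(s.P).min() >= -1e-9


class TestStatisticalVelocity:
    def test_constant_displacements(self):
        tr = Track(0, points=[(0, 0, 0, 1), (1, 1, 0, 1), (2, 2, 0, 1),
                              (3, 3, 0, 1)])
        assert statistical_velocity(tr) == (1.0, 0.0)

    def test_mean_of_two_displacements(self):
        tr = Track(0, points=[(0, 0, 0, 1), (1, 0, 1, 1), (2, 0, 4, 1)])
        assert statistical_velocity(tr) == (0.0, 2.0)

    def test_only_last_three_displacements_used(self):
        # oracle: direct mean of the stated 3-step window
        pts = [(0, 0, 0, 1), (1, 100, 0, 1), (2, 101, 0, 1), (3, 102, 0, 1),
               (4, 103, 0, 1)]
        tr = Track(0, points=pts)
        assert statistical_velocity(tr) == (1.0, 0.0)

    def test_single_point_returns_zero(self):
        assert statistical_velocity(Track(0, points=[(0, 5, 5, 1)])) == (0.0, 0.0)


class TestMatchCost:
    def test_perfect_match_costs_zero(self):
        s = _state([10, 10, 5, 0, 0])
        det = Detection(0, 10.0, 10.0, 5.0)
        assert match_cost(s, det, CFG, brightness_scale=5.0) == 0.0

    def test_gate_boundary_costs_one(self):
        s = _state([0, 0, 5, 0, 0])
        det = Detection(0, CFG.gate_radius, 0.0, 5.0)
        assert match_cost(s, det, CFG, brightness_scale=5.0) == pytest.approx(1.0)

    def test_outside_gate_infeasible(self):
        s = _state([0, 0, 5, 0, 0])
        det = Detection(0, CFG.gate_radius + 0.01, 0.0, 5.0)
        assert match_cost(s, det, CFG, brightness_scale=5.0) == np.inf

    def test_brightness_disambiguates_positional_tie(self):
        """Two tracks, two detections with tied positions: the assignment
        flips when brightness weighting is enabled (oracle: enumerate both
        permutations' total costs)."""
        bright, dim = 10.0, 2.0
        t_bright = Track(0, points=[(0, 0, 0, bright)],
                         state=_state([5, 0, bright, 0, 0]))
        t_dim = Track(1, points=[(0, 10, 0, dim)],
                      state=_state([5, 0.2, dim, 0, 0]))
        # both detections equidistant-ish from both tracks, brightness swapped
        d_dim = Detection(1, 5.0, 0.0, dim)
        d_bright = Detection(1, 5.0, 0.2, bright)
        for lam in (0.0, 1.0):
            cfg = TrackerConfig(brightness_weight=lam)
            matched, _, _ = match_frame([t_bright, t_dim], [d_dim, d_bright],
                                        cfg, brightness_scale=5.0)
            got = {tr.track_id: det.brightness for tr, det in matched}
            # oracle over the 2 permutations
            def total(perm):
                return sum(match_cost(tr.state, det, cfg, 5.0)
                           for tr, det in perm)
            p1 = [(t_bright, d_dim), (t_dim, d_bright)]
            p2 = [(t_bright, d_bright), (t_dim, d_dim)]
            best = p1 if total(p1) <= total(p2) else p2
            expect = {tr.track_id: det.brightness for tr, det in best}
            assert got == expect
        # and the two weightings must actually disagree
        cfg0 = TrackerConfig(brightness_weight=0.0)
        cfg1 = TrackerConfig(brightness_weight=1.0)
        m0, _, _ = match_frame([t_bright, t_dim], [d_dim, d_bright], cfg0, 5.0)
        m1, _, _ = match_frame([t_bright, t_dim], [d_dim, d_bright], cfg1, 5.0)
        assert {t.track_id: d.brightness for t, d in m0} != \
               {t.track_id: d.brightness for t, d in m1}


class TestMatchFrame:
    def test_single_in_gate_pair_matches(self):
        tr = Track(0, points=[(0, 0, 0, 5)], state=_state([1, 0, 5, 0, 0]))
        det = Detection(1, 1.5, 0.0, 5.0)
        matched, ut, ud = match_frame([tr], [det], CFG, 5.0)
        assert len(matched) == 1 and not ut and not ud

    def test_out_of_gate_detection_stays_unmatched(self):
        tr = Track(0, points=[(0, 0, 0, 5)], state=_state([0, 0, 5, 0, 0]))
        det = Detection(1, 50.0, 0.0, 5.0)
        matched, ut, ud = match_frame([tr], [det], CFG, 5.0)
        assert not matched and len(ut) == 1 and len(ud) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_assignment_equals_bruteforce_permutation_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 5)
        tracks = [Track(i, points=[(0, 0, 0, 1)],
                        state=_state([*rng.uniform(0, 20, 2),
                                      rng.uniform(1, 10), 0, 0]))
                  for i in range(n)]
        dets = [Detection(1, *rng.uniform(0, 20, 2), rng.uniform(1, 10))
                for _ in range(n)]
        cfg = TrackerConfig(gate_radius=30.0)
        matched, _, _ = match_frame(tracks, dets, cfg, 5.0)
        got = sum(match_cost(tr.state, det, cfg, 5.0) for tr, det in matched)
        best = min(sum(match_cost(tr.state, det, cfg, 5.0)
                       for tr, det in zip(tracks, perm))
                   for perm in itertools.permutations(dets))
        assert got == pytest.approx(best, abs=1e-12)


def _detections_for_line(n_frames, x0=10.0, y0=5.0, vx=0.0, vy=1.0,
                         brightness=8.0, skip=()):
    return [Detection(f, x0 + vx * f, y0 + vy * f, brightness)
            for f in range(n_frames) if f not in skip]


class TestTrackStack:
    def test_single_bubble_single_track_exact_positions(self):
        dets = _detections_for_line(20)
        tracks = track_stack(dets, TrackerConfig(min_track_length=5))
        assert len(tracks) == 1
        for (f, x, y, b), det in zip(tracks[0].points, dets):
            assert abs(x - det.x) < 1e-6 and abs(y - det.y) < 1e-6

    def test_dropout_bridged_into_one_track(self):
        dets = _detections_for_line(20, skip={10})
        tracks = track_stack(dets, TrackerConfig(max_coast=1))
        assert len(tracks) == 1
        frames = [p[0] for p in tracks[0].points]
        assert 9 in frames and 11 in frames and 10 not in frames

    def test_no_coast_splits_at_dropout(self):
        dets = _detections_for_line(20, skip={10})
        tracks = track_stack(dets, TrackerConfig(max_coast=0,
                                                 min_track_length=3))
        assert len(tracks) == 2

    def test_detections_disjoint_across_tracks(self, tracking_phantom):
        from vckulm import LocalizationConfig
        from vckulm.localize import localize_stack
        stack, _ = tracking_phantom
        dets = localize_stack(stack, LocalizationConfig(min_peak_intensity=2.0))
        tracks = track_stack(dets)
        seen = set()
        for tr in tracks:
            for p in tr.points:
                key = (p[0], round(p[1], 9), round(p[2], 9))
                assert key not in seen
                seen.add(key)

    def test_noiseless_constant_velocity_converges(self):
        dets = _detections_for_line(20, vx=0.7, vy=0.3)
        tracks = track_stack(dets)
        assert len(tracks) == 1
        # after convergence the filtered state tracks truth to <1e-6
        st = tracks[0].state
        assert abs(st.S[3] - 0.7) < 1e-3 and abs(st.S[4] - 0.3) < 1e-3

    def test_kalman_beats_nearest_neighbour_on_phantom(self, tracking_phantom):
        from vckulm import LocalizationConfig
        from vckulm.localize import localize_stack
        stack, gt = tracking_phantom
        dets = localize_stack(stack, LocalizationConfig(min_peak_intensity=2.0))
        cfg = TrackerConfig()
        vck = track_stack(dets, cfg)
        nn = track_stack_nn(dets, gate_radius=cfg.gate_radius,
                            min_track_length=cfg.min_track_length)
        f1_vck = track_identity_f1(vck, gt.true_tracks)["f1"]
        f1_nn = track_identity_f1(nn, gt.true_tracks)["f1"]
        assert f1_vck > f1_nn

    def test_crossing_bubbles_brightness_prevents_swaps(self):
        """Two crossing equidistant bubbles with distinct brightness are
        never swapped when the brightness channel is on; with it off,
        swaps occur (100 seeded trials)."""
        def crossing_dets(rng):
            dets = []
            for f in range(12):
                # bubbles cross at frame 6 on mirrored diagonals
                dets.append(Detection(f, 10.0 + f, 10.0 + f
                                      + rng.normal(0, 0.01), 10.0))
                dets.append(Detection(f, 22.0 - f, 10.0 + f
                                      + rng.normal(0, 0.01), 3.0))
            return dets

        def swapped(tracks):
            for tr in tracks:
                bs = {round(p[3]) for p in tr.points}
                if len(bs) > 1:
                    return True
            return False

        any_swap_off = False
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dets = crossing_dets(rng)
            cfg_on = TrackerConfig(brightness_weight=2.0, brightness_scale=10.0)
            assert not swapped(track_stack(dets, cfg_on))
            rng = np.random.default_rng(seed)
            dets = crossing_dets(rng)
            cfg_off = TrackerConfig(brightness_weight=0.0)
            any_swap_off |= swapped(track_stack(dets, cfg_off))
        assert any_swap_off
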