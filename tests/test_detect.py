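import numpy as np
import pytest

from microsaccades.detect import (DegenerateTrialError, DetectionParams,
                                  MicrosaccadeEvent, compute_velocity,
                                  detect_monocular, detect_trial,
                                  estimate_thresholds, event_properties,
                                  pair_binocular)
from microsaccades.io import GazeTrial
from microsaccades.simulate import (SimulationConfig, inject_microsaccade,
                                    simulate_study)


def brute_force_velocity(p, fs, window):
    """Independent per-sample evaluation of the moving-average differentiator."""
    m = window // 2
    n = len(p)
    dt = 1.0 / fs
    v = np.zeros(n)
    for j in range(n):
        mm = min(m, j, n - 1 - j)
        if mm == 0:
            continue
        v[j] = sum(p[j + k] - p[j - k] for k in range(1, mm + 1)) / (mm * (mm + 1) * dt)
    return v


def brute_force_runs(mask):
    runs, start = [], None
    for i, val in enumerate(mask):
        if val and start is None:
            start = i
        elif not val and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


class TestComputeVelocity:
    def test_constant_position_gives_zero(self):
        x = np.full(50, 3.7)
        vx, vy = compute_velocity(x, x, 500.0, 5)
        assert np.all(vx == 0) and np.all(vy == 0)

    def test_linear_ramp_exact_on_interior(self):
        c = 0.013
        x = c * np.arange(100)
        vx, _ = compute_velocity(x, np.zeros(100), 500.0, 5)
        np.testing.assert_allclose(vx[2:-2], c * 500.0, rtol=1e-12)
        # penultimate samples use the central difference, also exact here
        assert vx[1] == pytest.approx(c * 500.0, rel=1e-12)
        assert vx[0] == 0 and vx[-1] == 0

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_brute_force_oracle(self, window):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=rng.integers(window, 60))
            y = rng.normal(size=x.size)
            vx, vy = compute_velocity(x, y, 500.0, window)
            np.testing.assert_allclose(vx, brute_force_velocity(x, 500.0, window),
                                       atol=1e-12)
            np.testing.assert_allclose(vy, brute_force_velocity(y, 500.0, window),
                                       atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_velocity(np.zeros(3), np.zeros(3), 500.0, 5)


class TestEstimateThresholds:
    def test_alternating_signs_give_eta_equal_vfac(self):
        v = np.tile([1.0, -1.0], 10)
        eta_x, eta_y = estimate_thresholds(v, v, vfac=5.0)
        assert eta_x == pytest.approx(5.0) and eta_y == pytest.approx(5.0)

    def test_constant_velocity_is_degenerate(self):
        v = np.full(20, 2.0)
        with pytest.raises(DegenerateTrialError):
            estimate_thresholds(v, v, vfac=5.0)

    def test_matches_sort_based_median_oracle(self):
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(50):
            v = rng.normal(size=11)
            w = rng.normal(size=11)
            sigmas = []
            for comp in (v, w):
                s = np.sort(comp)
                med_sq = np.sort(comp ** 2)[5]
                sigmas.append(np.sqrt(max(med_sq - s[5] ** 2, 0.0)))
            if min(sigmas) < 1e-10:    # one-sign vector: degenerate by design
                with pytest.raises(DegenerateTrialError):
                    estimate_thresholds(v, w, vfac=3.0)
                continue
            eta_x, eta_y = estimate_thresholds(v, w, vfac=3.0)
            assert eta_x == pytest.approx(3.0 * sigmas[0], abs=1e-12)
            assert eta_y == pytest.approx(3.0 * sigmas[1], abs=1e-12)
            checked += 1
        assert checked >= 30

    def test_invalid_samples_excluded_from_estimate(self):
        v = np.tile([1.0, -1.0], 10)
        spiky = v.copy()
        spiky[:4] = 100.0
        mask = np.zeros(20, bool)
        mask[:4] = True
        eta_x, _ = estimate_thresholds(spiky, v, vfac=5.0, invalid_mask=mask)
        assert eta_x == pytest.approx(5.0)


class TestDetectMonocular:
    @staticmethod
    def velocities_from_mask(mask, eta=1.0):
        vx = np.where(mask, 10.0 * eta, 0.1 * eta)
        return vx, np.zeros_like(vx)

    def test_all_subthreshold_gives_no_events(self):
        vx, vy = self.velocities_from_mask(np.zeros(30, bool))
        assert detect_monocular(vx, vy, 1.0, 1.0, mindur=6) == []

    @pytest.mark.parametrize("length,expected", [(5, 0), (6, 1)])
    def test_duration_boundary(self, length, expected):
        mask = np.zeros(40, bool)
        mask[10:10 + length] = True
        vx, vy = self.velocities_from_mask(mask)
        events = detect_monocular(vx, vy, 1.0, 1.0, mindur=6)
        assert len(events) == expected
        if expected:
            assert events[0] == (10, 10 + length - 1)

    def test_matches_run_length_oracle_on_random_masks(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            mask = rng.uniform(size=rng.integers(10, 80)) < 0.4
            vx, vy = self.velocities_from_mask(mask)
            for mindur in (1, 2, 4):
                got = detect_monocular(vx, vy, 1.0, 1.0, mindur=mindur)
                expected = [r for r in brute_force_runs(mask)
                            if r[1] - r[0] + 1 >= mindur]
                assert got == expected

    def test_merge_gap_joins_nearby_runs_before_duration_test(self):
        mask = np.zeros(40, bool)
        mask[10:14] = True       # 4 samples
        mask[16:20] = True       # 4 samples, gap of 2
        vx, vy = self.velocities_from_mask(mask)
        assert detect_monocular(vx, vy, 1.0, 1.0, mindur=6, merge_gap=0) == []
        assert detect_monocular(vx, vy, 1.0, 1.0, mindur=6, merge_gap=2) == [(10, 19)]

    def test_events_overlapping_invalid_samples_discarded(self):
        mask = np.zeros(40, bool)
        mask[10:20] = True
        vx, vy = self.velocities_from_mask(mask)
        invalid = np.zeros(40, bool)
        invalid[19] = True
        assert detect_monocular(vx, vy, 1.0, 1.0, 6, invalid_mask=invalid) == []


def make_event(eye, onset, offset, peak=50.0, fs=500.0):
    return MicrosaccadeEvent(eye=eye, onset_index=onset, offset_index=offset,
                             duration_ms=(offset - onset + 1) * 1000.0 / fs,
                             peak_velocity=peak, dx=0.4, dy=0.0, amplitude=0.4)


class TestPairBinocular:
    def test_identical_lists_all_paired(self):
        left = [make_event("L", 10, 17), make_event("L", 40, 48)]
        right = [make_event("R", 10, 17), make_event("R", 40, 48)]
        pairs = pair_binocular(left, right)
        assert len(pairs) == 2
        assert all(p.eye == "BIN" for p in pairs)

    def test_disjoint_lists_give_no_pairs(self):
        left = [make_event("L", 10, 17)]
        right = [make_event("R", 30, 37)]
        assert pair_binocular(left, right) == []

    def test_chain_pairs_greedily_in_onset_order(self):
        # L1 overlaps both R1 and R2: greedy pairing takes (L1, R1), R2 stays
        left = [make_event("L", 10, 30)]
        right = [make_event("R", 12, 16), make_event("R", 22, 26)]
        pairs = pair_binocular(left, right)
        assert len(pairs) == 1
        assert pairs[0].onset_index == 10 and pairs[0].offset_index == 30

    def test_union_span_and_winner_properties(self):
        left = [make_event("L", 10, 20, peak=80.0)]
        right = [make_event("R", 14, 25, peak=50.0)]
        (pair,) = pair_binocular(left, right)
        assert (pair.onset_index, pair.offset_index) == (10, 25)
        assert pair.peak_velocity == 80.0
        assert pair.duration_ms == pytest.approx(16 * 2.0)

    def test_min_overlap_respected(self):
        left = [make_event("L", 10, 17)]
        right = [make_event("R", 17, 24)]   # exactly 1 shared sample
        assert len(pair_binocular(left, right, min_overlap=1)) == 1
        assert pair_binocular(left, right, min_overlap=2) == []

    def test_unsorted_input_rejected(self):
        left = [make_event("L", 40, 48), make_event("L", 10, 17)]
        with pytest.raises(ValueError, match="sorted"):
            pair_binocular(left, [])


class TestEventProperties:
    def test_monotone_single_axis_displacement(self):
        n = 30
        x = np.zeros(n)
        y = np.zeros(n)
        inject_microsaccade(x, y, 10, 0.5, 0.0, 8)
        vx, vy = compute_velocity(x, y, 500.0, 5)
        ev = event_properties(x, y, vx, vy, 10, 18, 500.0)
        assert ev.dx == pytest.approx(0.5, abs=1e-12)
        assert ev.dy == pytest.approx(0.0, abs=1e-12)
        assert ev.amplitude == pytest.approx(0.5, abs=1e-12)

    def test_overshoot_makes_amplitude_exceed_net_displacement(self):
        x = np.zeros(30)
        x[12:] = 0.6    # overshoot to 0.6 ...
        x[15:] = 0.5    # ... settles at 0.5
        vx, vy = compute_velocity(x, np.zeros(30), 500.0, 5)
        ev = event_properties(x, np.zeros(30), vx, vy, 10, 20, 500.0)
        assert ev.amplitude == pytest.approx(0.6)
        assert ev.dx == pytest.approx(0.5)
        assert ev.amplitude >= np.hypot(ev.dx, ev.dy)


def quiet_trial_arrays(n=2750, fs=500.0, noise=1e-4, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, n)
    y = rng.normal(0, noise, n)
    return x, y


def trial_from_arrays(xl, yl, xr, yr, fs=500.0, **kw):
    n = len(xl)
    defaults = dict(participant_id="P1", session="pre", trial_index=1,
                    sampling_rate=fs, time=np.arange(n) / fs,
                    left_x=xl, left_y=yl, right_x=xr, right_y=yr,
                    valid_left=np.ones(n, bool), valid_right=np.ones(n, bool))
    defaults.update(kw)
    return GazeTrial(**defaults)


class TestDetectTrial:
    def test_single_injected_event_detected_binocularly(self):
        xl, yl = quiet_trial_arrays(seed=1)
        xr, yr = quiet_trial_arrays(seed=2)
        for x, y in ((xl, yl), (xr, yr)):
            inject_microsaccade(x, y, 1000, 0.4, 0.3, 8)
        det = detect_trial(trial_from_arrays(xl, yl, xr, yr))
        assert len(det.binocular_events) == 1
        assert abs(det.binocular_events[0].onset_index - 1000) <= 10
        assert det.binocular_events[0].amplitude == pytest.approx(0.4, rel=0.15)

    def test_quiet_trial_has_no_events(self):
        xl, yl = quiet_trial_arrays(seed=3)
        xr, yr = quiet_trial_arrays(seed=4)
        det = detect_trial(trial_from_arrays(xl, yl, xr, yr))
        assert det.binocular_events == [] and not det.excluded

    def test_detection_is_deterministic(self):
        xl, yl = quiet_trial_arrays(seed=5)
        xr, yr = quiet_trial_arrays(seed=6)
        inject_microsaccade(xl, yl, 500, 0.5, 1.0, 8)
        inject_microsaccade(xr, yr, 500, 0.5, 1.0, 8)
        tr = trial_from_arrays(xl, yl, xr, yr)
        a = detect_trial(tr)
        b = detect_trial(tr)
        assert [e for e in a.events] == [e for e in b.events]

    def test_frozen_signal_flagged_excluded_not_zero(self):
        n = 100
        z = np.zeros(n)
        det = detect_trial(trial_from_arrays(z, z, z, z))
        assert det.excluded
        assert det.exclusion_reason

    def test_translation_invariance(self):
        xl, yl = quiet_trial_arrays(seed=7)
        xr, yr = quiet_trial_arrays(seed=8)
        inject_microsaccade(xl, yl, 700, 0.5, 0.7, 8)
        inject_microsaccade(xr, yr, 700, 0.5, 0.7, 8)
        base = detect_trial(trial_from_arrays(xl, yl, xr, yr))
        shifted = detect_trial(trial_from_arrays(xl + 3.0, yl - 2.0,
                                                 xr + 3.0, yr - 2.0))
        assert [(e.eye, e.onset_index, e.offset_index) for e in base.events] == \
               [(e.eye, e.onset_index, e.offset_index) for e in shifted.events]

    def test_mirror_symmetry_flips_direction_only(self):
        xl, yl = quiet_trial_arrays(seed=9)
        xr, yr = quiet_trial_arrays(seed=10)
        inject_microsaccade(xl, yl, 700, 0.5, 0.0, 8)
        inject_microsaccade(xr, yr, 700, 0.5, 0.0, 8)
        base = detect_trial(trial_from_arrays(xl, yl, xr, yr))
        mirrored = detect_trial(trial_from_arrays(-xl, yl, -xr, yr))
        assert [(e.onset_index, e.offset_index) for e in base.events] == \
               [(e.onset_index, e.offset_index) for e in mirrored.events]
        for e0, e1 in zip(base.binocular_events, mirrored.binocular_events):
            assert e1.dx == pytest.approx(-e0.dx, abs=1e-12)
            assert e1.dy == pytest.approx(e0.dy, abs=1e-12)


class TestOnSimulatedData:
    def test_counts_track_ground_truth_across_trials(self):
        cfg = SimulationConfig(n_participants=2, n_trials_per_session=25,
                               blink_probability_per_trial=0.0, seed=21)
        dataset, gt = simulate_study(cfg)
        detected = []
        truth = []
        for tr in dataset.trials:
            det = detect_trial(tr)
            detected.append(len(det.binocular_events))
            truth.append(len(gt.events[tr.key()]))
        r = np.corrcoef(detected, truth)[0, 1]
        assert len(detected) == 100
        assert r >= 0.9

    def test_counts_monotone_in_vfac_and_mindur(self, toy_study):
        dataset, _ = toy_study
        trials = dataset.trials[:12]
        for tr in trials:
            counts_vfac = [len(detect_trial(tr, DetectionParams(vfac=v)).binocular_events)
                           for v in (3.0, 4.0, 5.0, 6.5, 8.0)]
            assert all(a >= b for a, b in zip(counts_vfac, counts_vfac[1:]))
            counts_mindur = [len(detect_trial(tr, DetectionParams(mindur=m)).binocular_events)
                             for m in (2, 4, 6, 9, 11)]
            assert all(a >= b for a, b in zip(counts_mindur, counts_mindur[1:]))
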