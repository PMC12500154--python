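import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_detect

from saccatt.gaze_io import GazeEpoch
from saccatt.saccade_detect import (
    DetectParams,
    compute_velocity,
    detect_all,
    detect_saccades,
    gaussian_kernel,
    smooth_velocity,
    threshold_sweep,
)

T = np.arange(-1000.0, 1500.0)


def make_epoch(x, y=None, trial_id=0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return GazeEpoch(time_ms=T[: x.size], x_deg=x, y_deg=y, trial_id=trial_id)


def raised_cosine_trace(onset_ms, magnitude, duration_ms=20.0, n=2500, base=0.0):
    t = T[:n]
    phase = np.clip((t - onset_ms) / duration_ms, 0.0, 1.0)
    return base + magnitude * 0.5 * (1 - np.cos(np.pi * phase))


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        v = compute_velocity(make_epoch(np.full(100, 2.0)))
        assert v.shape == (99,)
        np.testing.assert_array_equal(v, 0.0)

    def test_single_sample_step_is_100_deg_per_s(self):
        x = np.zeros(100)
        x[50:] = 0.1
        v = compute_velocity(make_epoch(x))
        assert v[49] == pytest.approx(100.0)
        assert np.count_nonzero(v) == 1

    def test_vertical_step_invisible_in_1d_visible_in_2d(self):
        y = np.zeros(100)
        y[50:] = 0.2
        ep = make_epoch(np.zeros(100), y)
        assert np.all(compute_velocity(ep, "1d") == 0.0)
        assert compute_velocity(ep, "2d").max() > 0.0

    def test_missing_in_missing_out(self):
        x = np.ones(50)
        x[20] = np.nan
        v = compute_velocity(make_epoch(x))
        assert np.isnan(v[19]) and np.isnan(v[20])
        assert np.isfinite(np.delete(v, [19, 20])).all()


class TestSmoothing:
    def test_constant_preserved(self):
        v = np.full(200, 3.3)
        np.testing.assert_allclose(smooth_velocity(v), v)

    def test_impulse_response_is_unit_mass_kernel(self):
        v = np.zeros(101)
        v[50] = 1.0
        sm = smooth_velocity(v)
        np.testing.assert_allclose(sm.sum(), 1.0)
        np.testing.assert_allclose(sm[47:54], gaussian_kernel(7))

    def test_white_noise_variance_reduced_as_weighted_average(self, rng):
        # oracle: Var(Σ w_i x_i) = Σ w_i² Var(x) for iid noise
        v = rng.normal(0, 1, 50_000)
        sm = smooth_velocity(v)
        w2 = np.sum(gaussian_kernel(7) ** 2)
        ratio = sm[10:-10].var() / v.var()
        assert ratio < 1.0
        assert ratio == pytest.approx(w2, rel=0.1)

    def test_nan_renormalization_keeps_constant(self):
        v = np.full(100, 2.0)
        v[40:45] = np.nan
        sm = smooth_velocity(v)
        np.testing.assert_allclose(sm[np.isfinite(sm)], 2.0)


class TestDetect:
    def test_single_planted_saccade_recovered(self):
        x = raised_cosine_trace(250.0, 0.5)
        det = detect_saccades(make_epoch(x))
        assert len(det.events) == 1
        ev = det.events[0]
        assert abs(ev.onset_ms - 250.0) <= 3.0
        assert ev.direction == 1
        assert ev.magnitude_deg == pytest.approx(0.5, abs=0.02)

    def test_refractory_merges_saccades_60ms_apart(self):
        x = raised_cosine_trace(200.0, 0.3) + raised_cosine_trace(260.0, 0.3)
        det = detect_saccades(make_epoch(x))
        assert len(det.events) == 1
        assert [r for _, r in det.discarded] == ["refractory"]

    def test_sub_minimum_shift_recorded_not_evented(self):
        x = raised_cosine_trace(250.0, 0.03)
        det = detect_saccades(make_epoch(x))
        assert det.events == []
        assert len(det.sub_min_onsets_ms) == 1
        assert abs(det.sub_min_onsets_ms[0] - 250.0) < 5.0

    def test_leftward_direction_sign(self):
        det = detect_saccades(make_epoch(raised_cosine_trace(300.0, -0.4)))
        assert det.events[0].direction == -1

    def test_2d_mode_reports_angle_and_norm(self):
        x = raised_cosine_trace(250.0, 0.3)
        y = raised_cosine_trace(250.0, 0.4)
        det = detect_saccades(make_epoch(x, y), DetectParams(mode="2d"))
        ev = det.events[0]
        assert ev.magnitude_deg == pytest.approx(0.5, abs=0.02)
        assert ev.angle_rad == pytest.approx(np.arctan2(0.4, 0.3), abs=0.05)

    @given(st.floats(-30, 30))
    @settings(max_examples=20, deadline=None)
    def test_translation_equivariance(self, offset):
        x = raised_cosine_trace(100.0, 0.4, base=0.0)
        a = detect_saccades(make_epoch(x))
        b = detect_saccades(make_epoch(x + offset))
        assert [(e.onset_ms, e.direction) for e in a.events] == [
            (e.onset_ms, e.direction) for e in b.events
        ]
        for ea, eb in zip(a.events, b.events):
            assert ea.magnitude_deg == pytest.approx(eb.magnitude_deg, abs=1e-9)


def slow_wobble(n=2500, amp=0.001, freq_hz=5.0):
    """Deterministic sub-threshold background so the median velocity is
    nonzero but never crosses even a 2× median threshold (velocity of a
    sinusoid stays below 2× its own median = 1.41× its peak)."""
    return amp * np.sin(2 * np.pi * freq_hz * T[:n] / 1000.0)


class TestThresholdSweep:
    def test_unreachable_threshold_yields_no_events(self):
        x = raised_cosine_trace(250.0, 0.5) + slow_wobble()
        res = threshold_sweep([make_epoch(x)], k_values=(1e9,))
        assert len(res[1e9]["events"]) == 0

    def test_strong_saccades_identical_across_k(self):
        eps = []
        for i in range(10):
            x = raised_cosine_trace(150.0 + 30 * i, 0.8) + slow_wobble()
            eps.append(make_epoch(x, trial_id=i))
        res = threshold_sweep(eps)
        counts = {k: len(v["events"]) for k, v in res.items()}
        assert len(set(counts.values())) == 1 and counts[2.0] == 10

    def test_subset_monotonicity_on_clean_data(self):
        x = raised_cosine_trace(250.0, 0.5) + slow_wobble(amp=0.004)
        res = threshold_sweep([make_epoch(x)])
        sets = {k: [e.onset_ms for e in res[k]["per_trial"][0].events]
                for k in (2.0, 3.0, 4.0, 5.0)}
        # every event surviving a stricter threshold has a counterpart at the
        # looser one (onsets may shift by a sample or two at the crossing)
        for small, large in ((2.0, 3.0), (3.0, 4.0), (4.0, 5.0)):
            for onset in sets[large]:
                assert any(abs(onset - o) <= 5.0 for o in sets[small])

    def test_noise_event_count_non_increasing_in_k(self, rng):
        eps = [make_epoch(rng.normal(0, 0.05, 2500), trial_id=i) for i in range(12)]
        res = threshold_sweep(eps)
        counts = [len(res[k]["events"]) + sum(len(d.sub_min_onsets_ms)
                                              for d in res[k]["per_trial"].values())
                  for k in (2.0, 3.0, 4.0, 5.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))



class TestNaiveOracleEquivalence:
    def test_matches_naive_rule_replay_on_random_traces(self, rng):
        params = DetectParams()
        for trial in range(100):
            x = rng.normal(0, 0.02, 600)
            # sprinkle occasional larger shifts
            if trial % 3 == 0:
                x += raised_cosine_trace(rng.uniform(-800, 300), rng.uniform(0.1, 0.6),
                                         n=600)
            ep = make_epoch(x, trial_id=trial)
            det = detect_saccades(ep, params)
            expect_events, expect_sub = naive_detect(ep, params)
            got = [(e.onset_ms, e.direction, e.magnitude_deg) for e in det.events]
            assert len(got) == len(expect_events), f"trial {trial}"
            for g, e in zip(got, expect_events):
                assert g[0] == e[0] and g[1] == e[1]
                assert g[2] == pytest.approx(e[2], abs=1e-9)
            assert det.sub_min_onsets_ms == pytest.approx(expect_sub)


def test_detect_all_returns_tidy_table(tiny_experiment):
    cfg, datasets, truth = tiny_experiment
    table, per_trial = detect_all(datasets[0].gaze_epochs[:20])
    assert set(table.columns) >= {"trial_id", "onset_ms", "direction", "magnitude_deg"}
    assert len(per_trial) == 20
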