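import numpy as np
import pandas as pd
import pytest

from saccatt.erp_core import EegEpochs
from saccatt.synthgen import (
    EEG_CHANNELS,
    GroundTruth,
    SimConfig,
    generate_experiment,
    load_participant,
    simulate_participant,
    synth_eeg_trial,
    synth_gaze_trial,
    trial_rng,
)


def small_cfg(**kw):
    base = dict(n_participants=2, trials_per_task=20, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_bad_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(p_toward=0.5, p_away=0.5, p_none=0.5)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="epoch_window"):
            SimConfig(saccade_bias_window=(150, 2000))


class TestDeterminism:
    def test_fixed_seed_run_twice_identical(self):
        cfg = small_cfg()
        d1, t1 = generate_experiment(cfg)
        d2, t2 = generate_experiment(cfg)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.eeg.data, b.eeg.data)
            for ea, eb in zip(a.gaze_epochs, b.gaze_epochs):
                np.testing.assert_array_equal(ea.x_deg, eb.x_deg)
        pd.testing.assert_frame_equal(t1.trials, t2.trials)

    def test_on_disk_files_byte_identical(self, tmp_path):
        cfg = small_cfg(n_participants=1, trials_per_task=6)
        generate_experiment(cfg, tmp_path / "a")
        generate_experiment(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == twin.read_bytes(), f.name


class TestGazeTrial:
    def test_toward_left_cue_is_leftward_negative(self):
        cfg = small_cfg()
        for k in range(20):
            rng = trial_rng(cfg, 0, 0, k)
            _, _, planted = synth_gaze_trial("toward", "left", cfg, rng)
            main = next(p for p in planted if not p.is_return and not p.is_background)
            assert main.direction == -1
            assert 0.1 <= main.magnitude_deg <= 1.0

    def test_noise_free_none_trial_is_constant(self):
        cfg = small_cfg(drift_speed=0, tracker_noise_sd=0, blink_prob=0,
                        background_rate=0)
        x, y, planted = synth_gaze_trial("none", "left", cfg, trial_rng(cfg, 0, 0, 0))
        assert planted == []
        np.testing.assert_array_equal(x, 0.0)
        np.testing.assert_array_equal(y, 0.0)

    def test_planted_magnitude_readable_from_trace(self):
        cfg = small_cfg(blink_prob=0, background_rate=0, return_prob=0,
                        saccade_mag_range=(0.5, 0.5))
        t = cfg.gaze_times()
        devs = []
        for k in range(20):
            x, _, planted = synth_gaze_trial("toward", "right", cfg,
                                             trial_rng(cfg, 0, 0, k))
            main = planted[0]
            pre = x[(t >= main.onset_ms - 50) & (t < main.onset_ms)].mean()
            post = x[(t >= main.onset_ms + 50) & (t < main.onset_ms + 100)].mean()
            devs.append(post - pre - 0.5)
        devs = np.asarray(devs)
        # single readouts wander with fixational drift; the mean does not
        assert np.abs(devs).max() < 0.15
        assert abs(devs.mean()) < 0.03

    def test_none_class_has_no_saccade_in_attention_window(self):
        cfg = small_cfg(blink_prob=0)
        lo, hi = cfg.saccade_bias_window
        for k in range(100):
            _, _, planted = synth_gaze_trial("none", "left", cfg, trial_rng(cfg, 0, 1, k))
            assert all(not (lo <= p.onset_ms < hi) for p in planted)

    def test_p_none_one_no_planted_saccades_in_window(self):
        cfg = small_cfg(p_toward=0, p_away=0, p_none=1.0, n_participants=1,
                        trials_per_task=30)
        _, _, sacc = simulate_participant(cfg, 0)
        lo, hi = cfg.saccade_bias_window
        in_win = sacc[(sacc["onset_ms"] >= lo) & (sacc["onset_ms"] < hi)]
        assert len(in_win) == 0


class TestEegTrial:
    def test_noise_free_diff_is_exactly_the_planted_bump(self):
        cfg = small_cfg(noise_sd=0, alpha_amp=0, alpha_lat_amp=0)
        t = cfg.eeg_times()
        eeg = synth_eeg_trial("toward", "left", [], cfg, trial_rng(cfg, 0, 0, 0))
        po7, po8 = eeg[0], eeg[1]
        diff = po8 - po7  # contra − ipsi for a left cue
        win = (t >= 200) & (t < 300)
        assert diff[win].mean() == pytest.approx(-1.5, abs=1e-9)
        assert diff[t < 100].max() == pytest.approx(0.0, abs=1e-6)

    def test_oz_lambda_peak_follows_saccade_onset(self):
        from saccatt.synthgen import PlantedSaccade

        cfg = small_cfg(noise_sd=0, alpha_amp=0)
        t = cfg.eeg_times()
        planted = [PlantedSaccade(onset_ms=250.0, direction=1, magnitude_deg=0.5)]
        eeg = synth_eeg_trial("none", "left", planted, cfg, trial_rng(cfg, 0, 0, 0))
        oz = eeg[EEG_CHANNELS.index("Oz")]
        assert t[np.argmax(oz)] == pytest.approx(250.0 + cfg.lambda_delay_ms, abs=2.0)

    def test_heog_step_sign_follows_saccade_direction(self):
        from saccatt.synthgen import PlantedSaccade

        cfg = small_cfg(noise_sd=0, alpha_amp=0)
        t = cfg.eeg_times()
        planted = [PlantedSaccade(onset_ms=200.0, direction=-1, magnitude_deg=0.5)]
        eeg = synth_eeg_trial("none", "left", planted, cfg, trial_rng(cfg, 0, 0, 0))
        heog = eeg[EEG_CHANNELS.index("HEOG")]
        assert heog[t > 250].mean() == pytest.approx(-0.5 * cfg.eog_gain, abs=1e-6)

    def test_cued_side_swap_mirrors_lateralized_components(self):
        cfg = small_cfg(noise_sd=0)
        seed_state = trial_rng(cfg, 0, 0, 5)
        left = synth_eeg_trial("toward", "left", [], cfg, trial_rng(cfg, 0, 0, 5))
        right = synth_eeg_trial("toward", "right", [], cfg, trial_rng(cfg, 0, 0, 5))
        np.testing.assert_allclose(left[0], right[1])  # PO7 ↔ PO8
        np.testing.assert_allclose(left[1], right[0])

    def test_mean_amplitude_recovered_from_200_trials(self):
        # CLT check on the configured noise level
        cfg = small_cfg(alpha_amp=0)
        t = cfg.eeg_times()
        win = (t >= 200) & (t < 300)
        vals = []
        for k in range(200):
            eeg = synth_eeg_trial("toward", "left", [], cfg, trial_rng(cfg, 0, 0, k))
            vals.append((eeg[1] - eeg[0])[win].mean())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - (-1.5)) <= 2 * se


class TestExperimentStructure:
    def test_sides_balanced_within_one(self):
        cfg = small_cfg(trials_per_task=21, n_participants=1)
        data, tt, _ = simulate_participant(cfg, 0)
        for task, grp in data.meta.groupby("task"):
            counts = grp["cued_side"].value_counts()
            assert abs(counts.get("left", 0) - counts.get("right", 0)) <= 1

    def test_both_tasks_present(self, tiny_experiment):
        _, datasets, _ = tiny_experiment
        assert set(datasets[0].meta["task"]) == {"perception", "wm"}

    def test_class_proportions_within_3_binomial_se(self, tiny_experiment):
        cfg, _, truth = tiny_experiment
        labels = truth.trials["class_label"]
        n = len(labels)
        for cls, p in (("toward", cfg.p_toward), ("away", cfg.p_away),
                       ("none", cfg.p_none)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs((labels == cls).mean() - p) <= 3 * se

    def test_background_saccade_rate_independent_of_class(self, tiny_experiment):
        # planted background (out-of-window) saccade counts per trial should
        # not differ between classes
        _, _, truth = tiny_experiment
        bg = truth.saccades[truth.saccades["is_background"] & ~truth.saccades["is_return"]]
        per_trial = bg.groupby(["participant", "trial"]).size()
        merged = truth.trials.set_index(["participant", "trial"]).join(
            per_trial.rename("n_bg")).fillna({"n_bg": 0})
        by_class = merged.groupby("class_label")["n_bg"].mean()
        assert by_class.max() - by_class.min() < 0.2

    def test_round_trip_through_readers_lossless(self, tmp_path):
        cfg = small_cfg(n_participants=1, trials_per_task=5)
        datasets, truth = generate_experiment(cfg, tmp_path)
        back = load_participant(tmp_path / "p00")
        np.testing.assert_array_equal(back.eeg.data, datasets[0].eeg.data)
        assert back.eeg.ch_names == list(EEG_CHANNELS)
        for a, b in zip(back.gaze_epochs, datasets[0].gaze_epochs):
            np.testing.assert_allclose(a.x_deg, b.x_deg, atol=1e-12)
            assert a.task == b.task and a.cued_side == b.cued_side
        truth2 = GroundTruth.load(tmp_path / "truth.json")
        assert truth2.n2pc_amp_by_class == truth.n2pc_amp_by_class
        assert len(truth2.trials) == len(truth.trials)
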