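"""Synthetic gaze + EEG experiment generator with planted ground truth.

Emulates a two-task (perceptual vs working-memory selection) covert
spatial-attention experiment: on each trial two objects sit 5° left and
right of fixation, a central cue (t = 0) indicates one side, and the
participant keeps fixating.  The generator plants, per trial,

* a microsaccade class (``toward`` / ``away`` / ``none``) realized as a
  small square-wave gaze shift (outgoing saccade plus a return saccade
  100–250 ms later) whose outgoing onset falls in the 150–400 ms
  attention window for ``toward``/``away`` trials and nowhere near it
  for ``none`` trials;
* fixational drift, tracker noise, zero-run blinks, and task-unrelated
  background saccades far outside the attention window;
* EEG (PO7, PO8, Oz, HEOG) containing a cue-locked N2pc bump on the
  channel contralateral to the cued side (amplitude per class), a
  saccade-locked HEOG deflection mirroring the planted eye position, a
  saccade-locked lambda bump on Oz, a 10 Hz alpha rhythm with reduced
  contralateral amplitude from ~400 ms, and 1/f + white noise;
* behavioral responses (lognormal RT, Bernoulli accuracy).

All randomness derives from one seed through counter-based
``SeedSequence`` spawning, so any participant/trial can be regenerated
independently and in any order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import defaults
from .erp_core import EegEpochs
from .gaze_io import GazeEpoch, write_gaze_table

EEG_CHANNELS = ["PO7", "PO8", "Oz", "HEOG"]
TASKS = ("perception", "wm")
CLASSES = ("toward", "away", "none")


@dataclass
class SimConfig:
    """Study-design and signal parameters of the simulated experiment."""

    n_participants: int = 23
    trials_per_task: int = 600
    gaze_rate: float = defaults.GAZE_RATE_HZ
    eeg_rate: float = defaults.EEG_RATE_HZ
    epoch_window: tuple[float, float] = defaults.EPOCH_WINDOW_MS
    object_eccentricity: float = 5.0
    saccade_bias_window: tuple[float, float] = defaults.CLASS_WINDOW_MS
    # trial-class probabilities (match the reported toward/away/none mix)
    p_toward: float = 0.375
    p_away: float = 0.24
    p_none: float = 0.385
    # planted lateralized ERP
    n2pc_amp_by_class: dict = field(
        default_factory=lambda: {"toward": -1.5, "none": -0.5, "away": 0.0}
    )
    n2pc_window: tuple[float, float] = defaults.N2PC_WINDOW_MS
    subject_gain_sd: float = 0.25  # between-participant N2pc gain spread
    # saccade-locked EEG
    lambda_delay_ms: float = 125.0
    lambda_amp: float = 6.0  # µV, Oz bump per outgoing saccade
    eog_gain: float = 16.0  # µV per degree of horizontal eye rotation
    # alpha rhythm
    alpha_amp: float = 5.0  # µV base amplitude on PO7/PO8
    alpha_lat_amp: float = 0.2  # fractional contra decrease / ipsi increase
    alpha_onset_ms: float = 400.0
    # noise
    noise_sd: float = 10.0  # µV per EEG channel (white + 1/f in equal parts)
    drift_speed: float = 0.5  # deg/s RMS fixational drift velocity
    tracker_noise_sd: float = 0.001  # deg, white gaze measurement noise
    blink_prob: float = 0.05  # per-trial probability of one blink
    # planted saccade geometry
    saccade_mag_range: tuple[float, float] = (0.1, 1.0)
    saccade_duration_ms: float = 20.0
    main_onset_range: tuple[float, float] = (160.0, 390.0)
    return_delay_range: tuple[float, float] = (100.0, 250.0)
    return_prob: float = 1.0
    background_rate: float = 0.3  # Hz within the allowed background spans
    # behavior
    rt_mean_by_class: dict = field(
        default_factory=lambda: {"toward": 780.0, "none": 820.0, "away": 860.0}
    )
    rt_log_sd: float = 0.3
    accuracy_by_class: dict = field(
        default_factory=lambda: {"toward": 0.90, "none": 0.88, "away": 0.85}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.p_toward + self.p_away + self.p_none
        if not np.isclose(p, 1.0):
            raise ValueError(f"class probabilities must sum to 1 (got {p})")
        if min(self.p_toward, self.p_away, self.p_none) < 0:
            raise ValueError("class probabilities must be non-negative")
        if self.gaze_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        lo, hi = self.epoch_window
        for name in ("saccade_bias_window", "n2pc_window"):
            w = getattr(self, name)
            if not (lo <= w[0] < w[1] <= hi):
                raise ValueError(f"{name} {w} must lie inside epoch_window {self.epoch_window}")
        missing = set(CLASSES) - set(self.n2pc_amp_by_class)
        if missing:
            raise ValueError(f"n2pc_amp_by_class missing classes: {missing}")

    @property
    def class_probs(self) -> np.ndarray:
        return np.array([self.p_toward, self.p_away, self.p_none])

    @property
    def n_gaze_samples(self) -> int:
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.gaze_rate / 1000.0))

    @property
    def n_eeg_samples(self) -> int:
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.eeg_rate / 1000.0))

    def gaze_times(self) -> np.ndarray:
        return self.epoch_window[0] + 1000.0 / self.gaze_rate * np.arange(self.n_gaze_samples)

    def eeg_times(self) -> np.ndarray:
        return self.epoch_window[0] + 1000.0 / self.eeg_rate * np.arange(self.n_eeg_samples)


@dataclass
class PlantedSaccade:
    onset_ms: float
    direction: int  # −1 left, +1 right
    magnitude_deg: float
    is_return: bool = False
    is_background: bool = False


@dataclass
class ParticipantData:
    participant: int
    gaze_epochs: list[GazeEpoch]
    eeg: EegEpochs
    meta: pd.DataFrame  # trial, task, cued_side, rt_ms, correct


@dataclass
class GroundTruth:
    """Planted per-trial truth for the whole experiment."""

    trials: pd.DataFrame  # participant, trial, task, cued_side, class_label, ...
    saccades: pd.DataFrame  # participant, trial, onset_ms, direction, magnitude_deg, flags
    n2pc_amp_by_class: dict
    rt_mean_by_class: dict
    accuracy_by_class: dict
    subject_gains: dict

    def save(self, path: Path | str) -> None:
        payload = {
            "trials": self.trials.to_dict(orient="list"),
            "saccades": self.saccades.to_dict(orient="list"),
            "n2pc_amp_by_class": self.n2pc_amp_by_class,
            "rt_mean_by_class": self.rt_mean_by_class,
            "accuracy_by_class": self.accuracy_by_class,
            "subject_gains": {str(k): v for k, v in self.subject_gains.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Path | str) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            trials=pd.DataFrame(d["trials"]),
            saccades=pd.DataFrame(d["saccades"]),
            n2pc_amp_by_class=d["n2pc_amp_by_class"],
            rt_mean_by_class=d["rt_mean_by_class"],
            accuracy_by_class=d["accuracy_by_class"],
            subject_gains={int(k): v for k, v in d["subject_gains"].items()},
        )


# ---------------------------------------------------------------------------
# RNG plumbing: counter-based splitting so regeneration is order-independent.

def trial_rng(cfg: SimConfig, participant: int, task_idx: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(participant, task_idx, trial))
    )


def participant_rng(cfg: SimConfig, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(participant,)))


def task_rng(cfg: SimConfig, participant: int, task_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(participant, task_idx))
    )


# ---------------------------------------------------------------------------
# Gaze synthesis


def _raised_cosine_step(t_ms: np.ndarray, onset_ms: float, duration_ms: float) -> np.ndarray:
    """Unit displacement profile: 0 before onset, 1 after onset+duration."""
    phase = np.clip((t_ms - onset_ms) / duration_ms, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * phase))


def _background_spans(cfg: SimConfig) -> list[tuple[float, float]]:
    """Onset spans for task-unrelated saccades, chosen so that neither the
    saccade nor its return can enter the attention window."""
    lo, hi = cfg.epoch_window
    win_lo, win_hi = cfg.saccade_bias_window
    guard = cfg.return_delay_range[1] + 2 * cfg.saccade_duration_ms
    pre = (lo + 100.0, win_lo - guard)
    post = (win_hi + 150.0, hi - guard - 50.0)
    return [s for s in (pre, post) if s[1] > s[0]]


def _plant_saccades(
    class_label: str, cued_side: str, cfg: SimConfig, rng: np.random.Generator
) -> list[PlantedSaccade]:
    toward_sign = -1 if cued_side == "left" else +1
    planted: list[PlantedSaccade] = []

    def add_pair(onset: float, direction: int, is_background: bool) -> None:
        mag = float(rng.uniform(*cfg.saccade_mag_range))
        planted.append(
            PlantedSaccade(onset, direction, mag, is_return=False, is_background=is_background)
        )
        if rng.random() < cfg.return_prob:
            delay = float(rng.uniform(*cfg.return_delay_range))
            planted.append(
                PlantedSaccade(onset + delay, -direction, mag, is_return=True,
                               is_background=is_background)
            )

    if class_label in ("toward", "away"):
        onset = float(rng.uniform(*cfg.main_onset_range))
        sign = toward_sign if class_label == "toward" else -toward_sign
        add_pair(onset, sign, is_background=False)

    spans = _background_spans(cfg)
    if spans and cfg.background_rate > 0:
        total_s = sum(b - a for a, b in spans) / 1000.0
        n_bg = rng.poisson(cfg.background_rate * total_s)
        weights = np.array([b - a for a, b in spans])
        for _ in range(n_bg):
            span = spans[rng.choice(len(spans), p=weights / weights.sum())]
            onset = float(rng.uniform(*span))
            # keep saccades well separated so each remains individually
            # resolvable by an onset-to-onset refractory rule
            if any(abs(onset - p.onset_ms) < 300.0 for p in planted):
                continue
            add_pair(onset, int(rng.choice([-1, 1])), is_background=True)
    return planted


def synth_gaze_trial(
    class_label: str,
    cued_side: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    planted: list[PlantedSaccade] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[PlantedSaccade]]:
    """Generate one gaze trial: (x_deg, y_deg, planted saccades).

    Blinks are encoded as exact-zero runs on both axes (tracker loss
    semantics); everything else is drift + tracker noise + the planted
    square-wave saccades.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if planted is None:
        planted = _plant_saccades(class_label, cued_side, cfg, rng)
    t = cfg.gaze_times()
    n = t.size

    def drift_trace() -> np.ndarray:
        if cfg.drift_speed <= 0:
            return np.zeros(n)
        raw = rng.standard_normal(n)
        vel = gaussian_filter1d(raw, sigma=20.0, mode="reflect")
        sd = vel.std()
        if sd > 0:
            vel *= (cfg.drift_speed / cfg.gaze_rate) / sd
        pos = np.cumsum(vel)
        return pos - pos.mean()

    x = drift_trace()
    y = drift_trace()
    if cfg.tracker_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.tracker_noise_sd, n)
        y = y + rng.normal(0.0, cfg.tracker_noise_sd, n)
    for p in planted:
        x = x + p.direction * p.magnitude_deg * _raised_cosine_step(
            t, p.onset_ms, cfg.saccade_duration_ms
        )
    if cfg.blink_prob > 0 and rng.random() < cfg.blink_prob:
        dur = rng.uniform(100.0, 200.0)
        start = rng.uniform(t[0], t[-1] - dur)
        blink = (t >= start) & (t < start + dur)
        x[blink] = 0.0
        y[blink] = 0.0
    return x, y, planted


# ---------------------------------------------------------------------------
# EEG synthesis

_PINK_FILTER_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _pink_filter(n: int, fs: float) -> np.ndarray:
    key = (n, fs)
    if key not in _PINK_FILTER_CACHE:
        f = np.fft.fftfreq(n, d=1.0 / fs)
        g = np.zeros(n)
        nz = f != 0
        g[nz] = 1.0 / np.sqrt(np.abs(f[nz]))
        g /= np.sqrt(np.mean(g**2))
        _PINK_FILTER_CACHE[key] = g
    return _PINK_FILTER_CACHE[key]


def _noise(cfg: SimConfig, rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """White + 1/f noise in equal variance shares, total SD = noise_sd."""
    if cfg.noise_sd == 0:
        return np.zeros((n_ch, n))
    sd_part = cfg.noise_sd / np.sqrt(2.0)
    white = rng.normal(0.0, sd_part, (n_ch, n))
    g = _pink_filter(n, cfg.eeg_rate)
    w = rng.standard_normal((n_ch, n))
    pink = np.real(np.fft.ifft(np.fft.fft(w, axis=1) * g, axis=1)) * sd_part
    return white + pink


def synth_eeg_trial(
    class_label: str,
    cued_side: str,
    planted: list[PlantedSaccade],
    cfg: SimConfig,
    rng: np.random.Generator,
    n2pc_gain: float = 1.0,
) -> np.ndarray:
    """One EEG epoch (channels × time, µV) for channels PO7, PO8, Oz, HEOG."""
    t = cfg.eeg_times()
    n = t.size
    i_po7, i_po8, i_oz, i_heog = range(4)
    contra_i, ipsi_i = (i_po8, i_po7) if cued_side == "left" else (i_po7, i_po8)

    # channel-wise noise drawn first so that the deterministic components
    # below are exchangeable across cued sides at fixed rng state
    eeg = _noise(cfg, rng, len(EEG_CHANNELS), n)

    # (i) cue-locked N2pc: Gaussian negativity on the contralateral channel.
    # The configured amplitude is the bump's *mean over the N2pc window*
    # (the quantity the downstream analysis measures), so the peak is
    # scaled up by the window-mean factor of the Gaussian shape.
    amp = cfg.n2pc_amp_by_class[class_label] * n2pc_gain
    if amp != 0.0:
        c = 0.5 * (cfg.n2pc_window[0] + cfg.n2pc_window[1])
        sd = (cfg.n2pc_window[1] - cfg.n2pc_window[0]) / 4.0
        shape = np.exp(-0.5 * ((t - c) / sd) ** 2)
        win = (t >= cfg.n2pc_window[0]) & (t < cfg.n2pc_window[1])
        eeg[contra_i] += (amp / shape[win].mean()) * shape

    # (ii) saccade-locked HEOG: corneo-retinal dipole follows planted eye position
    if planted and cfg.eog_gain != 0.0:
        pos = np.zeros(n)
        for p in planted:
            pos += p.direction * p.magnitude_deg * _raised_cosine_step(
                t, p.onset_ms, cfg.saccade_duration_ms
            )
        eeg[i_heog] += cfg.eog_gain * pos

    # (iii) saccade-locked lambda response on Oz (outgoing saccades only)
    if cfg.lambda_amp != 0.0:
        for p in planted:
            if p.is_return:
                continue
            center = p.onset_ms + cfg.lambda_delay_ms
            eeg[i_oz] += cfg.lambda_amp * np.exp(-0.5 * ((t - center) / 15.0) ** 2)

    # (iv) alpha rhythm with contra < ipsi amplitude from ~alpha_onset_ms
    if cfg.alpha_amp != 0.0:
        ramp = np.clip((t - cfg.alpha_onset_ms) / 100.0, 0.0, 1.0)
        env = 0.5 * (1.0 - np.cos(np.pi * ramp))
        env[t < cfg.alpha_onset_ms] = 0.0
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sin(2.0 * np.pi * 10.0 * t / 1000.0 + phase) * env * cfg.alpha_amp
        eeg[contra_i] += (1.0 - cfg.alpha_lat_amp) * osc
        eeg[ipsi_i] += (1.0 + cfg.alpha_lat_amp) * osc
    return eeg


# ---------------------------------------------------------------------------
# Trial / participant / experiment assembly


def _cued_sides(cfg: SimConfig, participant: int, task_idx: int) -> np.ndarray:
    """Exactly balanced left/right cue sequence, shuffled per task block."""
    n = cfg.trials_per_task
    sides = np.array(["left", "right"] * (n // 2) + ["left"] * (n % 2), dtype=object)
    task_rng(cfg, participant, task_idx).shuffle(sides)
    return sides


def simulate_participant(cfg: SimConfig, participant: int) -> tuple[ParticipantData, pd.DataFrame, pd.DataFrame]:
    """Generate one participant; returns (data, truth_trials, truth_saccades)."""
    p_rng = participant_rng(cfg, participant)
    gain = float(np.clip(p_rng.normal(1.0, cfg.subject_gain_sd), 0.2, None))

    gaze_epochs: list[GazeEpoch] = []
    eeg_data = np.empty((2 * cfg.trials_per_task, len(EEG_CHANNELS), cfg.n_eeg_samples),
                        dtype=np.float32)
    meta_rows, truth_rows, sacc_rows = [], [], []
    t_gaze = cfg.gaze_times()
    trial_id = 0
    for task_idx, task in enumerate(TASKS):
        sides = _cued_sides(cfg, participant, task_idx)
        for k in range(cfg.trials_per_task):
            rng = trial_rng(cfg, participant, task_idx, k)
            cued = str(sides[k])
            label = str(rng.choice(CLASSES, p=cfg.class_probs))
            x, y, planted = synth_gaze_trial(label, cued, cfg, rng)
            eeg_data[trial_id] = synth_eeg_trial(label, cued, planted, cfg, rng, gain)
            rt = float(np.exp(rng.normal(
                np.log(cfg.rt_mean_by_class[label]) - 0.5 * cfg.rt_log_sd**2, cfg.rt_log_sd)))
            correct = int(rng.random() < cfg.accuracy_by_class[label])
            gaze_epochs.append(GazeEpoch(time_ms=t_gaze, x_deg=x, y_deg=y,
                                         trial_id=trial_id, task=task, cued_side=cued))
            meta_rows.append({"trial": trial_id, "task": task, "cued_side": cued,
                              "rt_ms": rt, "correct": correct})
            main = next((p for p in planted if not p.is_return and not p.is_background), None)
            truth_rows.append({
                "participant": participant, "trial": trial_id, "task": task,
                "cued_side": cued, "class_label": label,
                "main_onset_ms": main.onset_ms if main else np.nan,
                "main_direction": main.direction if main else 0,
                "main_magnitude_deg": main.magnitude_deg if main else np.nan,
                "rt_ms": rt, "correct": correct,
            })
            for p in planted:
                sacc_rows.append({
                    "participant": participant, "trial": trial_id,
                    "onset_ms": p.onset_ms, "direction": p.direction,
                    "magnitude_deg": p.magnitude_deg,
                    "is_return": p.is_return, "is_background": p.is_background,
                })
            trial_id += 1

    meta = pd.DataFrame(meta_rows)
    eeg = EegEpochs(data=eeg_data, ch_names=list(EEG_CHANNELS), sfreq=cfg.eeg_rate,
                    times_ms=cfg.eeg_times(), metadata=meta)
    data = ParticipantData(participant=participant, gaze_epochs=gaze_epochs, eeg=eeg, meta=meta)
    return data, pd.DataFrame(truth_rows), pd.DataFrame(sacc_rows)


def generate_experiment(
    cfg: SimConfig, out_dir: Path | str | None = None
) -> tuple[list[ParticipantData], GroundTruth]:
    """Generate the full experiment; optionally write it to ``out_dir``.

    Output layout (per participant ``pNN/``): ``gaze.csv`` (long table),
    ``eeg.npy`` + ``eeg.json`` sidecar + ``eeg_metadata.csv``, and
    ``metadata.csv``; ground truth as ``truth.json`` at the root.
    """
    datasets, truth_t, truth_s, gains = [], [], [], {}
    for p in range(cfg.n_participants):
        data, tt, ts = simulate_participant(cfg, p)
        gains[p] = float(np.clip(participant_rng(cfg, p).normal(1.0, cfg.subject_gain_sd), 0.2, None))
        datasets.append(data)
        truth_t.append(tt)
        truth_s.append(ts)
    truth = GroundTruth(
        trials=pd.concat(truth_t, ignore_index=True),
        saccades=pd.concat(truth_s, ignore_index=True),
        n2pc_amp_by_class=dict(cfg.n2pc_amp_by_class),
        rt_mean_by_class=dict(cfg.rt_mean_by_class),
        accuracy_by_class=dict(cfg.accuracy_by_class),
        subject_gains=gains,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for data in datasets:
            pdir = out_dir / f"p{data.participant:02d}"
            pdir.mkdir(exist_ok=True)
            write_gaze_table(pdir / "gaze.csv", data.gaze_epochs)
            data.eeg.save(pdir / "eeg")
            data.meta.to_csv(pdir / "metadata.csv", index=False)
        truth.save(out_dir / "truth.json")
    return datasets, truth


def load_participant(pdir: Path | str) -> ParticipantData:
    """Round-trip reader for the on-disk participant layout."""
    from .gaze_io import epochs_from_table, read_gaze_table

    pdir = Path(pdir)
    meta = pd.read_csv(pdir / "metadata.csv")
    gaze = epochs_from_table(read_gaze_table(pdir / "gaze.csv"), meta)
    eeg = EegEpochs.load(pdir / "eeg")
    return ParticipantData(participant=int(pdir.name.lstrip("p")), gaze_epochs=gaze,
                           eeg=eeg, meta=meta)
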