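"""Epoched-EEG container, baseline correction, and lateralized (N2pc) ERPs.

The N2pc is quantified as the difference between the posterior channel
contralateral versus ipsilateral to the cued (or memorized) object
location, i.e. ``diff = contra − ipsi`` over the PO7/PO8 pair, averaged
over a predefined 200–300 ms window after cue onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import defaults


@dataclass
class EegEpochs:
    """Trials × channels × time voltage array (µV), cue at t = 0 ms."""

    data: np.ndarray
    ch_names: list[str]
    sfreq: float
    times_ms: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × time")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("channel-name count does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if self.times_ms.size != self.data.shape[2]:
            raise ValueError("time axis does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def ch_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present (have {self.ch_names})") from None

    def time_slice(self, window_ms: tuple[float, float]) -> slice:
        """Index slice for the half-open window [lo, hi) ms."""
        lo, hi = window_ms
        if lo < self.times_ms[0] or hi > self.times_ms[-1] + 1000.0 / self.sfreq:
            raise ValueError(f"window {window_ms} outside epoch "
                             f"({self.times_ms[0]:.0f}..{self.times_ms[-1]:.0f} ms)")
        a = int(np.searchsorted(self.times_ms, lo, side="left"))
        b = int(np.searchsorted(self.times_ms, hi, side="left"))
        return slice(a, b)

    def save(self, prefix: Path | str) -> None:
        """Write ``<prefix>.npy`` plus a JSON sidecar (and metadata CSV)."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.data)
        sidecar = {
            "ch_names": self.ch_names,
            "sfreq": self.sfreq,
            "tmin_ms": float(self.times_ms[0]),
            "n_times": int(self.times_ms.size),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        if self.metadata is not None:
            self.metadata.to_csv(prefix.parent / (prefix.name + "_metadata.csv"), index=False)

    @classmethod
    def load(cls, prefix: Path | str) -> "EegEpochs":
        prefix = Path(prefix)
        data = np.load(prefix.with_suffix(".npy"))
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        times = sidecar["tmin_ms"] + 1000.0 / sidecar["sfreq"] * np.arange(sidecar["n_times"])
        meta_path = prefix.parent / (prefix.name + "_metadata.csv")
        meta = pd.read_csv(meta_path) if meta_path.exists() else None
        return cls(data=data, ch_names=list(sidecar["ch_names"]), sfreq=sidecar["sfreq"],
                   times_ms=times, metadata=meta)


@dataclass
class LateralizedWave:
    """Contra/ipsi/difference time courses for one channel pair."""

    times_ms: np.ndarray
    contra: np.ndarray
    ipsi: np.ndarray
    diff: np.ndarray
    n_left: int
    n_right: int
    smoothing_sd_samples: float | None = defaults.ERP_SMOOTH_SD_SAMPLES
    label: str = "PO7/PO8"


def baseline_correct(
    epochs: EegEpochs, window_ms: tuple[float, float] = defaults.BASELINE_WINDOW_MS
) -> EegEpochs:
    """Subtract the per-trial, per-channel mean over ``window_ms``.

    Idempotent: re-application changes nothing beyond float rounding.
    """
    sl = epochs.time_slice(window_ms)
    if sl.stop <= sl.start:
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EegEpochs(
        data=epochs.data - base,
        ch_names=list(epochs.ch_names),
        sfreq=epochs.sfreq,
        times_ms=epochs.times_ms,
        metadata=epochs.metadata,
    )


def smooth_wave(wave: np.ndarray, sd_samples: float) -> np.ndarray:
    """Gaussian smoothing with reflective edge padding."""
    return gaussian_filter1d(np.asarray(wave, dtype=float), sd_samples, mode="reflect")


def contra_ipsi(
    epochs: EegEpochs,
    metadata: pd.DataFrame | None = None,
    pair: tuple[str, str] = ("PO7", "PO8"),
    smoothing_sd_samples: float | None = defaults.ERP_SMOOTH_SD_SAMPLES,
) -> LateralizedWave:
    """Trial-averaged contra/ipsi waves relative to the cued side.

    PO7 sits over the left hemisphere and PO8 over the right, so the
    contralateral channel is PO8 on left-cued trials and PO7 on
    right-cued trials.  Smoothing (Gaussian, SD in samples) is applied
    to the trial-averaged waves; pass ``None`` to disable.
    """
    meta = metadata if metadata is not None else epochs.metadata
    if meta is None:
        raise ValueError("trial metadata with cued_side required")
    sides = meta["cued_side"].to_numpy()
    left = sides == "left"
    right = sides == "right"
    for name, m in (("left", left), ("right", right)):
        if not m.any():
            raise ValueError(f"no trials with cued_side == {name!r}")
    i_left_ch = epochs.ch_index(pair[0])   # left-hemisphere channel
    i_right_ch = epochs.ch_index(pair[1])  # right-hemisphere channel
    data = epochs.data.astype(float)
    # contra: right-hemisphere channel on left-cued trials and vice versa
    contra_sum = data[left, i_right_ch].sum(axis=0) + data[right, i_left_ch].sum(axis=0)
    ipsi_sum = data[left, i_left_ch].sum(axis=0) + data[right, i_right_ch].sum(axis=0)
    n = int(left.sum() + right.sum())
    contra = contra_sum / n
    ipsi = ipsi_sum / n
    if smoothing_sd_samples:
        contra = smooth_wave(contra, smoothing_sd_samples)
        ipsi = smooth_wave(ipsi, smoothing_sd_samples)
    return LateralizedWave(
        times_ms=epochs.times_ms,
        contra=contra,
        ipsi=ipsi,
        diff=contra - ipsi,
        n_left=int(left.sum()),
        n_right=int(right.sum()),
        smoothing_sd_samples=smoothing_sd_samples,
        label=f"{pair[0]}/{pair[1]}",
    )


def n2pc_amplitude(
    wave: LateralizedWave, window_ms: tuple[float, float] = defaults.N2PC_WINDOW_MS
) -> float:
    """Mean of the contra−ipsi difference over the half-open window (µV)."""
    lo, hi = window_ms
    sel = (wave.times_ms >= lo) & (wave.times_ms < hi)
    if not sel.any():
        raise ValueError(f"window {window_ms} contains no samples")
    return float(wave.diff[sel].mean())


def grand_average(waves: list[LateralizedWave]) -> LateralizedWave:
    """Unweighted mean across participants' lateralized waves."""
    if not waves:
        raise ValueError("no waves to average")
    t = waves[0].times_ms
    return LateralizedWave(
        times_ms=t,
        contra=np.mean([w.contra for w in waves], axis=0),
        ipsi=np.mean([w.ipsi for w in waves], axis=0),
        diff=np.mean([w.diff for w in waves], axis=0),
        n_left=sum(w.n_left for w in waves),
        n_right=sum(w.n_right for w in waves),
        smoothing_sd_samples=waves[0].smoothing_sd_samples,
        label=waves[0].label,
    )
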