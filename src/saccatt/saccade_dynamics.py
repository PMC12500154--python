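"""Saccade-rate time courses and the toward−away directional bias.

Rates are computed with a centered sliding window (default 50 ms,
advanced in 1 ms steps): the rate at time t is the number of saccade
onsets across trials inside ``[t − w/2, t + w/2)`` divided by
``n_trials × window`` (in seconds), giving Hz per trial.  Windows
truncated by the epoch edge are normalized by their realized length.
The time × size decomposition restricts the toward−away bias to
overlapping magnitude bins (0.2° wide, advanced by 0.04°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults


@dataclass
class RateTimeCourse:
    time_ms: np.ndarray
    rate_toward: np.ndarray  # Hz
    rate_away: np.ndarray  # Hz
    window_ms: float
    step_ms: float

    @property
    def bias(self) -> np.ndarray:
        """toward − away rate, Hz."""
        return self.rate_toward - self.rate_away

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, rate in (("toward", self.rate_toward), ("away", self.rate_away),
                            ("bias", self.bias)):
            frames.append(pd.DataFrame({"time_ms": self.time_ms, "rate_hz": rate,
                                        "label": label}))
        return pd.concat(frames, ignore_index=True)


def _label_events(events: pd.DataFrame, cued_side: pd.Series | dict | None) -> np.ndarray:
    """Map events to 'toward'/'away' given per-trial cued side."""
    if "label" in events.columns:
        return events["label"].to_numpy()
    if cued_side is None:
        raise ValueError("need either a 'label' column or per-trial cued sides")
    side_map = dict(cued_side) if not isinstance(cued_side, dict) else cued_side
    sides = events["trial_id"].map(side_map)
    toward = (events["direction"].to_numpy() < 0) == (sides.to_numpy() == "left")
    return np.where(toward, "toward", "away")


def _windowed_rate(
    onsets: np.ndarray,
    n_trials: int,
    time_ms: np.ndarray,
    window_ms: float,
    epoch_window: tuple[float, float],
) -> np.ndarray:
    half = window_ms / 2.0
    lo = np.maximum(time_ms - half, epoch_window[0])
    hi = np.minimum(time_ms + half, epoch_window[1])
    counts = (np.searchsorted(onsets, hi, side="left")
              - np.searchsorted(onsets, lo, side="left"))
    realized_s = (hi - lo) / 1000.0
    return counts / (n_trials * realized_s)


def saccade_rate(
    events: pd.DataFrame,
    n_trials: int,
    cued_side: dict | pd.Series | None = None,
    window_ms: float = defaults.RATE_WINDOW_MS,
    step_ms: float = defaults.RATE_STEP_MS,
    epoch_window: tuple[float, float] = defaults.EPOCH_WINDOW_MS,
) -> RateTimeCourse:
    """Toward/away saccade-rate time courses in Hz.

    ``events`` needs ``onset_ms`` plus either a precomputed
    ``label`` column ('toward'/'away') or ``trial_id`` + ``direction``
    with ``cued_side`` supplied per trial.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    time_ms = np.arange(epoch_window[0], epoch_window[1], step_ms, dtype=float)
    if len(events) == 0:
        zero = np.zeros(time_ms.size)
        return RateTimeCourse(time_ms, zero, zero.copy(), window_ms, step_ms)
    labels = _label_events(events, cued_side)
    rates = {}
    for lab in ("toward", "away"):
        onsets = np.sort(events.loc[labels == lab, "onset_ms"].to_numpy(dtype=float))
        rates[lab] = _windowed_rate(onsets, n_trials, time_ms, window_ms, epoch_window)
    return RateTimeCourse(time_ms, rates["toward"], rates["away"], window_ms, step_ms)


def rate_by_size(
    events: pd.DataFrame,
    n_trials: int,
    cued_side: dict | pd.Series | None = None,
    size_bin_deg: float = defaults.SIZE_BIN_DEG,
    size_step_deg: float = defaults.SIZE_STEP_DEG,
    max_size_deg: float = 2.0,
    window_ms: float = defaults.RATE_WINDOW_MS,
    step_ms: float = defaults.RATE_STEP_MS,
    epoch_window: tuple[float, float] = defaults.EPOCH_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time × size matrix of the toward−away bias rate.

    Rows are window-centered times, columns are overlapping magnitude
    bins ``[s, s + size_bin_deg)`` advanced by ``size_step_deg``.
    Returns ``(time_ms, size_lo_deg, bias_matrix)``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    time_ms = np.arange(epoch_window[0], epoch_window[1], step_ms, dtype=float)
    size_lo = np.arange(0.0, max_size_deg - size_bin_deg + 1e-9, size_step_deg)
    bias = np.zeros((time_ms.size, size_lo.size))
    if len(events):
        labels = _label_events(events, cued_side)
        mags = events["magnitude_deg"].to_numpy(dtype=float)
        for j, s in enumerate(size_lo):
            in_bin = (mags >= s) & (mags < s + size_bin_deg)
            if not in_bin.any():
                continue
            for lab, sgn in (("toward", 1.0), ("away", -1.0)):
                sel = in_bin & (labels == lab)
                if sel.any():
                    onsets = np.sort(events.loc[sel, "onset_ms"].to_numpy(dtype=float))
                    bias[:, j] += sgn * _windowed_rate(onsets, n_trials, time_ms,
                                                       window_ms, epoch_window)
    return time_ms, size_lo, bias


def rate_to_long(time_ms: np.ndarray, size_lo: np.ndarray, bias: np.ndarray) -> pd.DataFrame:
    t, s = np.meshgrid(time_ms, size_lo, indexing="ij")
    return pd.DataFrame({"time_ms": t.ravel(), "size_deg": s.ravel(),
                         "rate_hz": bias.ravel(), "label": "bias"})
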