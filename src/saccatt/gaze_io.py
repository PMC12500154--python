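"""Gaze-table I/O, blink masking, and cue-locked epoching.

Gaze recordings arrive as uniformly sampled (time, x, y) traces in
visual degrees.  Signal loss (blinks) is encoded by the tracker as
exact zeros on both axes simultaneously; :func:`mask_blinks` replaces
those runs — padded by ±100 ms to cover lid-closure artifacts — with
NaN.  Missing samples are never interpolated: downstream stages decide
whether a trial with missing data in their window of interest is usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults

log = logging.getLogger(__name__)

GAZE_COLUMNS = ["trial", "task", "time_ms", "x_deg", "y_deg"]


@dataclass
class GazeEpoch:
    """One trial of cue-locked gaze samples.

    ``time_ms`` is uniform with cue onset at 0; ``x_deg``/``y_deg`` may
    contain NaN where the signal was lost.
    """

    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    trial_id: int
    task: str = ""
    cued_side: str = ""

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if self.x_deg.shape != self.time_ms.shape or self.y_deg.shape != self.time_ms.shape:
            raise ValueError("time/x/y must have identical lengths")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            if not (np.all(dt > 0) and np.allclose(dt, dt[0])):
                raise ValueError("time axis must be strictly increasing and uniform")

    @property
    def rate_hz(self) -> float:
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])

    @property
    def n_missing(self) -> int:
        return int(np.sum(np.isnan(self.x_deg) | np.isnan(self.y_deg)))


def _zero_runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs in a boolean array."""
    idx = np.flatnonzero(flag)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def mask_blinks(
    x: np.ndarray,
    y: np.ndarray,
    rate_hz: float = defaults.GAZE_RATE_HZ,
    pad_ms: float = defaults.BLINK_PAD_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace zero-clusters (signal loss) ±pad_ms with NaN.

    A zero-cluster is a run of samples where x and y are *both* exactly
    zero.  Each cluster is extended by ``pad_ms`` on both sides; padded
    intervals that overlap merge naturally (interval union).  Non-missing
    samples outside the padded clusters are returned unchanged.  A fully
    zero trial becomes fully missing (flagged in the log, not an error).
    """
    x = np.array(x, dtype=float, copy=True)
    y = np.array(y, dtype=float, copy=True)
    lost = (x == 0.0) & (y == 0.0)
    if not lost.any():
        return x, y
    pad = int(round(pad_ms * rate_hz / 1000.0))
    n = x.size
    mask = np.zeros(n, dtype=bool)
    for start, stop in _zero_runs(lost):
        mask[max(0, start - pad) : min(n, stop + pad + 1)] = True
    if mask.all():
        log.warning("mask_blinks: trial fully missing after blink padding")
    x[mask] = np.nan
    y[mask] = np.nan
    return x, y


def epoch_gaze(
    samples: pd.DataFrame,
    cue_onsets_ms: np.ndarray,
    window_ms: tuple[float, float] = defaults.EPOCH_WINDOW_MS,
    rate_hz: float = defaults.GAZE_RATE_HZ,
) -> tuple[list[GazeEpoch], int]:
    """Cut a continuous recording into cue-locked epochs.

    ``samples`` needs columns ``time_ms, x_deg, y_deg``.  Epochs span the
    half-open window ``[lo, hi)`` around each cue; cues whose window is
    not fully contained in the recording are skipped and counted (second
    return value), each with a logged reason.
    """
    t = samples["time_ms"].to_numpy(dtype=float)
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    dt = 1000.0 / rate_hz
    lo, hi = window_ms
    n_samp = int(round((hi - lo) / dt))
    epochs: list[GazeEpoch] = []
    n_skipped = 0
    for k, cue in enumerate(np.atleast_1d(cue_onsets_ms)):
        start = int(round((cue + lo - t[0]) / dt))
        stop = start + n_samp
        if start < 0 or stop > t.size:
            log.info("epoch_gaze: cue %d at %.0f ms skipped (window outside recording)", k, cue)
            n_skipped += 1
            continue
        epochs.append(
            GazeEpoch(
                time_ms=lo + dt * np.arange(n_samp),
                x_deg=x[start:stop],
                y_deg=y[start:stop],
                trial_id=k,
            )
        )
    return epochs, n_skipped


def read_gaze_table(path) -> pd.DataFrame:
    """Read a delimited gaze table and validate its layout."""
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze table missing columns: {missing}")
    for trial, grp in df.groupby("trial"):
        dt = np.diff(grp["time_ms"].to_numpy())
        if dt.size and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError(f"non-uniform time axis in trial {trial}")
    return df


def write_gaze_table(path, epochs: list[GazeEpoch], task: str | None = None) -> None:
    frames = []
    for ep in epochs:
        frames.append(
            pd.DataFrame(
                {
                    "trial": ep.trial_id,
                    "task": task if task is not None else ep.task,
                    "time_ms": ep.time_ms,
                    "x_deg": ep.x_deg,
                    "y_deg": ep.y_deg,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def epochs_from_table(df: pd.DataFrame, meta: pd.DataFrame | None = None) -> list[GazeEpoch]:
    """Build :class:`GazeEpoch` objects from a long gaze table.

    ``meta`` (optional) supplies ``cued_side`` per trial via a ``trial``
    column.
    """
    side = {}
    if meta is not None:
        side = dict(zip(meta["trial"], meta["cued_side"]))
    out = []
    for (trial, task), grp in df.groupby(["trial", "task"], sort=True):
        out.append(
            GazeEpoch(
                time_ms=grp["time_ms"].to_numpy(dtype=float),
                x_deg=grp["x_deg"].to_numpy(dtype=float),
                y_deg=grp["y_deg"].to_numpy(dtype=float),
                trial_id=int(trial),
                task=str(task),
                cued_side=side.get(trial, ""),
            )
        )
    return out
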