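"""Velocity-threshold microsaccade detection.

The detector follows the classic median-velocity scheme: sample-to-sample
gaze velocity (1D horizontal or 2D Euclidean), Gaussian smoothing over a
7 ms window, a trial-specific threshold of ``k`` times the median smoothed
velocity, onset at the first supra-threshold sample of each crossing, a
100 ms onset-to-onset refractory period, and direction/magnitude read out
from mean gaze position in fixed pre (−50..0 ms) and post (50..100 ms)
windows around the onset.  Shifts smaller than 0.05° are too small for a
reliable direction estimate; they are not returned as events but recorded
per trial so that trial classification can exclude those trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .gaze_io import GazeEpoch

log = logging.getLogger(__name__)


@dataclass
class DetectParams:
    """Parameters of the velocity-threshold detector."""

    k_threshold: float = defaults.K_THRESHOLD
    smooth_window_ms: float = defaults.SMOOTH_WINDOW_MS
    refractory_ms: float = defaults.REFRACTORY_MS
    pre_window_ms: tuple[float, float] = defaults.PRE_WINDOW_MS
    post_window_ms: tuple[float, float] = defaults.POST_WINDOW_MS
    min_magnitude_deg: float = defaults.MIN_MAGNITUDE_DEG
    mode: str = "1d"  # "1d" (horizontal) or "2d"

    def __post_init__(self) -> None:
        if self.mode not in ("1d", "2d"):
            raise ValueError(f"mode must be '1d' or '2d', got {self.mode!r}")
        for name in ("k_threshold", "smooth_window_ms", "refractory_ms", "min_magnitude_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SaccadeEvent:
    """A detected gaze shift."""

    trial_id: int
    onset_ms: float
    direction: int  # −1 left, +1 right (sign of horizontal displacement)
    magnitude_deg: float
    peak_velocity: float  # deg/s
    angle_rad: float | None = None  # 2D mode only
    task: str = ""

    def toward(self, cued_side: str) -> bool:
        """True if this shift points toward the cued side."""
        return (self.direction < 0) == (cued_side == "left")


@dataclass
class TrialDetection:
    """Per-trial detector output: accepted events plus bookkeeping."""

    events: list[SaccadeEvent]
    sub_min_onsets_ms: list[float] = field(default_factory=list)
    discarded: list[tuple[float, str]] = field(default_factory=list)


def compute_velocity(epoch: GazeEpoch, mode: str = "1d") -> np.ndarray:
    """Sample-to-sample gaze speed in deg/s.

    Element ``i`` is the step ending at position sample ``i + 1`` (the
    later sample of the pair), so the array has ``n − 1`` elements.
    Steps involving a missing sample are NaN.
    """
    x = epoch.x_deg
    if x.size < 2:
        return np.empty(0)
    dt_s = (epoch.time_ms[1] - epoch.time_ms[0]) / 1000.0
    dx = np.diff(x)
    if mode == "1d":
        step = np.abs(dx)
    elif mode == "2d":
        step = np.hypot(dx, np.diff(epoch.y_deg))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return step / dt_s


def gaussian_kernel(n_samples: int, alpha: float = 2.5) -> np.ndarray:
    """Gaussian taper over ``n_samples`` points, normalized to sum 1.

    ``alpha`` is the half-width in standard deviations (i.e.
    SD = (n − 1) / (2 alpha)), the convention of common Gaussian
    moving-average filters.
    """
    half = (n_samples - 1) / 2.0
    i = np.arange(n_samples) - half
    w = np.exp(-0.5 * (alpha * i / half) ** 2) if half > 0 else np.ones(1)
    return w / w.sum()


def smooth_velocity(
    v: np.ndarray,
    smooth_window_ms: float = defaults.SMOOTH_WINDOW_MS,
    rate_hz: float = defaults.GAZE_RATE_HZ,
) -> np.ndarray:
    """Gaussian-weighted moving average, NaN-aware.

    Missing samples are excluded from each window with the remaining
    weights renormalized; an output sample is NaN only where every
    sample in its window is missing.  Edges use the in-bounds part of
    the kernel (again renormalized), so constants are preserved exactly.
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return v.copy()
    n_k = max(1, int(round(smooth_window_ms * rate_hz / 1000.0)))
    if n_k % 2 == 0:
        n_k += 1
    w = gaussian_kernel(n_k)
    valid = np.isfinite(v)
    v_fill = np.where(valid, v, 0.0)
    num = np.convolve(v_fill, w, mode="same")
    den = np.convolve(valid.astype(float), w, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _window_mean(x: np.ndarray, start: int, stop: int) -> float:
    """Mean of x[start:stop] ignoring NaN; NaN if empty or all-missing."""
    if start < 0 or stop > x.size or stop <= start:
        return np.nan
    seg = x[start:stop]
    if not np.isfinite(seg).any():
        return np.nan
    return float(np.nanmean(seg))


def detect_saccades(epoch: GazeEpoch, params: DetectParams | None = None) -> TrialDetection:
    """Detect saccades in one epoch.

    Returns accepted events, onsets of sub-minimum (<``min_magnitude_deg``)
    shifts, and discarded crossings with reasons.
    """
    params = params or DetectParams()
    v = compute_velocity(epoch, params.mode)
    if v.size == 0 or np.isfinite(epoch.x_deg).sum() < 2:
        return TrialDetection(events=[])
    vs = smooth_velocity(v, params.smooth_window_ms, epoch.rate_hz)
    valid = np.isfinite(vs)
    if not valid.any():
        return TrialDetection(events=[])
    threshold = params.k_threshold * float(np.median(vs[valid]))

    dt = epoch.time_ms[1] - epoch.time_ms[0]
    above = vs > threshold  # NaN compares False
    prev = np.concatenate(([False], above[:-1]))
    crossing_idx = np.flatnonzero(above & ~prev)

    det = TrialDetection(events=[])
    refractory = params.refractory_ms
    pre_lo, pre_hi = params.pre_window_ms
    post_lo, post_hi = params.post_window_ms
    last_onset_ms = -np.inf
    for ci in crossing_idx:
        pos_i = ci + 1  # velocity sample ci ends at position sample ci+1
        onset_ms = float(epoch.time_ms[pos_i])
        if onset_ms - last_onset_ms < refractory:
            det.discarded.append((onset_ms, "refractory"))
            continue
        # the refractory clock runs on every crossing that survives it,
        # whether or not the shift passes characterization downstream
        last_onset_ms = onset_ms
        pre_a = pos_i + int(round(pre_lo / dt))
        pre_b = pos_i + int(round(pre_hi / dt))
        post_a = pos_i + int(round(post_lo / dt))
        post_b = pos_i + int(round(post_hi / dt))
        pre_x = _window_mean(epoch.x_deg, pre_a, pre_b)
        post_x = _window_mean(epoch.x_deg, post_a, post_b)
        if not (np.isfinite(pre_x) and np.isfinite(post_x)):
            det.discarded.append((onset_ms, "characterization-window-unusable"))
            continue
        dx = post_x - pre_x
        if params.mode == "2d":
            pre_y = _window_mean(epoch.y_deg, pre_a, pre_b)
            post_y = _window_mean(epoch.y_deg, post_a, post_b)
            if not (np.isfinite(pre_y) and np.isfinite(post_y)):
                det.discarded.append((onset_ms, "characterization-window-unusable"))
                continue
            dy = post_y - pre_y
            magnitude = float(np.hypot(dx, dy))
            angle = float(np.arctan2(dy, dx))
        else:
            magnitude = abs(dx)
            angle = None
        if magnitude < params.min_magnitude_deg:
            det.sub_min_onsets_ms.append(onset_ms)
            continue
        seg = vs[ci : ci + max(1, int(round(refractory / dt)))]
        peak_v = float(np.nanmax(seg)) if np.isfinite(seg).any() else float(vs[ci])
        det.events.append(
            SaccadeEvent(
                trial_id=epoch.trial_id,
                onset_ms=onset_ms,
                direction=int(np.sign(dx)) if dx != 0 else 1,
                magnitude_deg=magnitude,
                peak_velocity=peak_v,
                angle_rad=angle,
                task=epoch.task,
            )
        )
    return det


def detect_all(
    epochs: list[GazeEpoch], params: DetectParams | None = None
) -> tuple[pd.DataFrame, dict[int, TrialDetection]]:
    """Run the detector over many epochs; return an event table plus
    the per-trial detections (for sub-minimum bookkeeping)."""
    params = params or DetectParams()
    rows = []
    per_trial: dict[int, TrialDetection] = {}
    for ep in epochs:
        det = detect_saccades(ep, params)
        per_trial[ep.trial_id] = det
        for ev in det.events:
            rows.append(
                {
                    "trial_id": ev.trial_id,
                    "task": ev.task,
                    "onset_ms": ev.onset_ms,
                    "direction": ev.direction,
                    "magnitude_deg": ev.magnitude_deg,
                    "peak_velocity": ev.peak_velocity,
                }
            )
    cols = ["trial_id", "task", "onset_ms", "direction", "magnitude_deg", "peak_velocity"]
    table = pd.DataFrame(rows, columns=cols)
    return table, per_trial


def threshold_sweep(
    epochs: list[GazeEpoch],
    k_values: tuple[float, ...] = (2, 3, 4, 5),
    params: DetectParams | None = None,
    downstream=None,
) -> dict[float, dict]:
    """Re-run detection at several threshold multipliers.

    Returns, per ``k``, the event table and (optionally) the result of a
    ``downstream(event_table)`` summary callable.  On noise-free data the
    event set at a larger ``k`` is a subset of the set at a smaller ``k``.
    """
    base = params or DetectParams()
    out: dict[float, dict] = {}
    for k in k_values:
        p = DetectParams(
            k_threshold=float(k),
            smooth_window_ms=base.smooth_window_ms,
            refractory_ms=base.refractory_ms,
            pre_window_ms=base.pre_window_ms,
            post_window_ms=base.post_window_ms,
            min_magnitude_deg=base.min_magnitude_deg,
            mode=base.mode,
        )
        table, per_trial = detect_all(epochs, p)
        entry: dict = {"events": table, "per_trial": per_trial}
        if downstream is not None:
            entry["summary"] = downstream(table)
        out[float(k)] = entry
    return out
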