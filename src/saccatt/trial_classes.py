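"""Microsaccade-based trial sorting.

Each trial is labeled by the first detected gaze shift inside the
attention window (half-open [150, 400) ms after cue onset): ``toward``
if it points to the cued side, ``away`` otherwise, and ``none`` when no
shift was detected in the window.  Trials with missing gaze samples in
the window, or whose only in-window shifts fall below the 0.05°
magnitude floor, are excluded with a recorded reason.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import defaults
from .gaze_io import GazeEpoch
from .saccade_detect import TrialDetection

EXCL_MISSING = "missing-data"
EXCL_SUBMIN = "sub-minimum-shift"


def classify_trials(
    per_trial: dict[int, TrialDetection],
    gaze_epochs: list[GazeEpoch],
    window_ms: tuple[float, float] = defaults.CLASS_WINDOW_MS,
) -> pd.DataFrame:
    """Build the trial-class table.

    Columns: ``trial_id, task, cued_side, class, exclusion_reason,
    first_saccade_onset_ms``.  ``class`` ∈ {toward, away, none,
    excluded}; non-excluded rows have reason "n/a".
    """
    lo, hi = window_ms
    rows = []
    for ep in gaze_epochs:
        if not ep.cued_side:
            raise ValueError(f"trial {ep.trial_id}: unknown cued_side")
        in_win = (ep.time_ms >= lo) & (ep.time_ms < hi)
        missing = ~(np.isfinite(ep.x_deg[in_win]) & np.isfinite(ep.y_deg[in_win]))
        det = per_trial.get(ep.trial_id, TrialDetection(events=[]))
        cls, reason, onset = "none", "n/a", np.nan
        if missing.any():
            cls, reason = "excluded", EXCL_MISSING
        else:
            ev_in = [e for e in det.events if lo <= e.onset_ms < hi]
            if ev_in:
                first = min(ev_in, key=lambda e: e.onset_ms)
                cls = "toward" if first.toward(ep.cued_side) else "away"
                onset = first.onset_ms
            elif any(lo <= o < hi for o in det.sub_min_onsets_ms):
                cls, reason = "excluded", EXCL_SUBMIN
        rows.append({"trial_id": ep.trial_id, "task": ep.task, "cued_side": ep.cued_side,
                     "class": cls, "exclusion_reason": reason,
                     "first_saccade_onset_ms": onset})
    return pd.DataFrame(rows)


def class_proportions(
    table: pd.DataFrame, by: str | None = "participant"
) -> pd.DataFrame:
    """Per-participant class proportions over non-excluded trials.

    Returns one row per participant (or a single row if ``by`` is None
    or absent from the table) with toward/away/none proportions, plus a
    summary row set ``mean ± SE`` across participants via
    :func:`summarize_proportions`.  Participants with zero usable
    trials are flagged with NaN proportions.
    """
    if by is None or by not in table.columns:
        table = table.assign(_grp=0)
        by = "_grp"
    rows = []
    for g, grp in table.groupby(by):
        usable = grp[grp["class"] != "excluded"]
        n = len(usable)
        row = {by: g, "n_usable": n, "n_excluded": int((grp["class"] == "excluded").sum())}
        for cls in ("toward", "away", "none"):
            row[cls] = (usable["class"] == cls).mean() if n else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if by == "_grp":
        out = out.drop(columns="_grp")
    return out


def summarize_proportions(props: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SE of class proportions across participants."""
    rows = []
    for cls in ("toward", "away", "none"):
        vals = props[cls].dropna().to_numpy()
        rows.append({
            "class": cls,
            "mean": vals.mean() if vals.size else np.nan,
            "se": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
            "n_participants": int(vals.size),
        })
    return pd.DataFrame(rows)
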