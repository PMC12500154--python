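"""Independent rule-replay oracles used by multiple test modules."""

import numpy as np

from saccatt.gaze_io import GazeEpoch
from saccatt.saccade_detect import DetectParams, gaussian_kernel


def naive_detect(epoch: GazeEpoch, params: DetectParams):
    """Literal rule-replay oracle: explicit loops, no vectorized shortcuts."""
    x, y, t = epoch.x_deg, epoch.y_deg, epoch.time_ms
    n = x.size
    dt = t[1] - t[0]
    v = []
    for i in range(n - 1):
        if params.mode == "2d":
            step = np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)
        else:
            step = abs(x[i + 1] - x[i])
        v.append(step / (dt / 1000.0))
    v = np.array(v)
    # Gaussian moving average, renormalized over valid in-window samples
    nk = int(round(params.smooth_window_ms / dt))
    if nk % 2 == 0:
        nk += 1
    half = nk // 2
    kernel = gaussian_kernel(nk)
    vs = np.empty_like(v)
    for i in range(v.size):
        num = den = 0.0
        for j in range(-half, half + 1):
            if 0 <= i + j < v.size and np.isfinite(v[i + j]):
                num += kernel[j + half] * v[i + j]
                den += kernel[j + half]
        vs[i] = num / den if den > 0 else np.nan
    thr = params.k_threshold * np.median(vs[np.isfinite(vs)])
    events, sub_min = [], []
    last = -np.inf
    for i in range(v.size):
        above = np.isfinite(vs[i]) and vs[i] > thr
        prev_above = i > 0 and np.isfinite(vs[i - 1]) and vs[i - 1] > thr
        if not above or prev_above:
            continue
        onset = t[i + 1]
        if onset - last < params.refractory_ms:
            continue
        last = onset
        pos_i = i + 1
        pre = x[pos_i + int(params.pre_window_ms[0]) : pos_i + int(params.pre_window_ms[1])]
        post = x[pos_i + int(params.post_window_ms[0]) : pos_i + int(params.post_window_ms[1])]
        lo = pos_i + int(params.pre_window_ms[0])
        if lo < 0 or pos_i + int(params.post_window_ms[1]) > n:
            continue
        if not (np.isfinite(pre).any() and np.isfinite(post).any()):
            continue
        dx = np.nanmean(post) - np.nanmean(pre)
        if abs(dx) < params.min_magnitude_deg:
            sub_min.append(onset)
            continue
        events.append((onset, 1 if dx > 0 else -1, abs(dx)))
    return events, sub_min

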