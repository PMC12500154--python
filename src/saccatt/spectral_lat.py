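"""Short-time Fourier power and the contra/ipsi lateralization index.

Power is estimated with a Hanning-tapered sliding window (300 ms,
advanced in ~20 ms steps) at integer frequencies 3–40 Hz; the segment
is zero-padded to a power-of-two FFT length whose bin spacing divides
1 Hz, so the requested integer frequencies fall exactly on the grid.
Lateralization is the normalized power difference

    L(f, t) = 100 × (contra − ipsi) / (contra + ipsi)   [percent]

over the PO7/PO8 pair, with power averaged over trials before the
ratio.  The alpha summary averages L over 8–12 Hz and 400–800 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from . import defaults
from .erp_core import EegEpochs


@dataclass
class TfrPower:
    power: np.ndarray  # trials × channels × freqs × frames, amplitude² units
    freqs_hz: np.ndarray
    times_ms: np.ndarray  # frame centers
    ch_names: list[str]


@dataclass
class TfrLateralization:
    L: np.ndarray  # freqs × frames, percent, NaN where contra+ipsi == 0
    freqs_hz: np.ndarray
    times_ms: np.ndarray

    def alpha_summary(
        self,
        band_hz: tuple[float, float] = defaults.ALPHA_BAND_HZ,
        window_ms: tuple[float, float] = defaults.ALPHA_WINDOW_MS,
    ) -> float:
        """Mean L over the alpha band (inclusive) and summary window."""
        fsel = (self.freqs_hz >= band_hz[0]) & (self.freqs_hz <= band_hz[1])
        tsel = (self.times_ms >= window_ms[0]) & (self.times_ms < window_ms[1])
        cell = self.L[np.ix_(fsel, tsel)]
        return float(np.nanmean(cell))

    def to_frame(self) -> pd.DataFrame:
        f, t = np.meshgrid(self.freqs_hz, self.times_ms, indexing="ij")
        return pd.DataFrame({"freq_hz": f.ravel(), "time_ms": t.ravel(),
                             "L_percent": self.L.ravel()})


def _fft_length(n_seg: int, fs: float) -> int:
    """Smallest power of two ≥ max(n_seg, fs): bin spacing fs/n ≤ 1 Hz,
    and exactly 1/2^m Hz when fs itself is a power of two (1024 Hz)."""
    n = 1
    while n < max(n_seg, fs):
        n *= 2
    return n


def stft_power(
    epochs: EegEpochs,
    window_ms: float = defaults.TFR_WINDOW_MS,
    step_ms: float = defaults.TFR_STEP_MS,
    fmin_hz: float = defaults.TFR_FMIN_HZ,
    fmax_hz: float = defaults.TFR_FMAX_HZ,
    chunk_trials: int = 32,
) -> TfrPower:
    """Hanning-tapered sliding-window power at integer frequencies.

    Power is scaled so a pure sinusoid of amplitude ``a`` at a grid
    frequency yields ``a²`` at that bin.
    """
    fs = epochs.sfreq
    freqs = np.arange(fmin_hz, fmax_hz + 1, 1.0)
    if freqs[-1] > fs / 2:
        raise ValueError(f"requested frequency {freqs[-1]} Hz above Nyquist {fs / 2} Hz")
    n_seg = int(round(window_ms * fs / 1000.0))
    if epochs.data.shape[2] < n_seg:
        raise ValueError("epoch shorter than the STFT window")
    hop = max(1, int(round(step_ms * fs / 1000.0)))
    taper = hann(n_seg, sym=False)
    n_fft = _fft_length(n_seg, fs)
    # complex exponentials at exactly the requested integer frequencies
    k = np.round(freqs * n_fft / fs).astype(int)
    if not np.allclose(k * fs / n_fft, freqs):
        raise ValueError("integer-frequency grid not representable at this FFT length")
    phase = np.exp(-2j * np.pi * np.outer(np.arange(n_seg), k) / n_fft)
    basis = (taper[:, None] * phase).astype(np.complex128)
    scale = 2.0 / taper.sum()

    data = epochs.data
    segs = sliding_window_view(data, n_seg, axis=2)[:, :, ::hop, :]  # tr × ch × frames × n_seg
    n_tr, n_ch, n_frames, _ = segs.shape
    power = np.empty((n_tr, n_ch, freqs.size, n_frames), dtype=np.float64)
    for a in range(0, n_tr, chunk_trials):
        block = np.asarray(segs[a : a + chunk_trials], dtype=np.float64)
        spec = block @ basis  # ... × frames × n_freq
        power[a : a + block.shape[0]] = (np.abs(spec) * scale).transpose(0, 1, 3, 2) ** 2
    centers = epochs.times_ms[np.arange(n_frames) * hop + n_seg // 2]
    return TfrPower(power=power, freqs_hz=freqs, times_ms=centers,
                    ch_names=list(epochs.ch_names))


def lateralization_index(
    power: TfrPower,
    metadata: pd.DataFrame,
    pair: tuple[str, str] = ("PO7", "PO8"),
) -> TfrLateralization:
    """Contra/ipsi lateralization of trial-mean power, percent.

    Trial-mean power is assembled as in the ERP analysis: the
    contralateral channel is PO8 on left-cued trials and PO7 on
    right-cued trials.  Cells with contra + ipsi = 0 are NaN and are
    excluded from summaries.
    """
    for ch in pair:
        if ch not in power.ch_names:
            raise ValueError(f"channel {ch!r} not in power array")
    i_left_ch = power.ch_names.index(pair[0])
    i_right_ch = power.ch_names.index(pair[1])
    sides = metadata["cued_side"].to_numpy()
    left = sides == "left"
    right = sides == "right"
    n = left.sum() + right.sum()
    contra = (power.power[left, i_right_ch].sum(axis=0)
              + power.power[right, i_left_ch].sum(axis=0)) / n
    ipsi = (power.power[left, i_left_ch].sum(axis=0)
            + power.power[right, i_right_ch].sum(axis=0)) / n
    denom = contra + ipsi
    with np.errstate(invalid="ignore", divide="ignore"):
        L = 100.0 * (contra - ipsi) / denom
    L[denom == 0] = np.nan
    return TfrLateralization(L=L, freqs_hz=power.freqs_hz, times_ms=power.times_ms)
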