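"""Canonical analysis constants shared across modules.

Every window below is expressed in milliseconds relative to cue onset
(cue at t = 0).  Windows are half-open ``[lo, hi)`` throughout the
package so that adjacent windows tile the epoch without double counting.
"""

#: Padding applied around detected blink (zero-cluster) intervals, ms.
BLINK_PAD_MS = 100

#: Epoch limits relative to cue onset, ms.
EPOCH_WINDOW_MS = (-1000, 1500)

#: Gaze sampling rate, Hz.
GAZE_RATE_HZ = 1000

#: EEG sampling rate, Hz.
EEG_RATE_HZ = 1024

#: Velocity-threshold multiplier applied to the trial median velocity.
K_THRESHOLD = 3.0

#: Gaussian velocity-smoothing window, ms.
SMOOTH_WINDOW_MS = 7

#: Minimum onset-to-onset spacing between accepted saccades, ms.
REFRACTORY_MS = 100

#: Pre-saccade position window used for direction/magnitude, ms rel. onset.
PRE_WINDOW_MS = (-50, 0)

#: Post-saccade position window used for direction/magnitude, ms rel. onset.
POST_WINDOW_MS = (50, 100)

#: Smallest gaze shift treated as a saccade, visual degrees.
MIN_MAGNITUDE_DEG = 0.05

#: Attention window used to classify trials by microsaccade direction, ms.
CLASS_WINDOW_MS = (150, 400)

#: A-priori N2pc measurement window, ms.
N2PC_WINDOW_MS = (200, 300)

#: Pre-cue baseline window subtracted from each EEG trial, ms.
BASELINE_WINDOW_MS = (-250, 0)

#: Gaussian smoothing SD for trial-averaged ERPs, in EEG samples.
ERP_SMOOTH_SD_SAMPLES = 15

#: Alpha band used for the spectral lateralization summary, Hz (inclusive).
ALPHA_BAND_HZ = (8, 12)

#: Time window for the alpha lateralization summary, ms.
ALPHA_WINDOW_MS = (400, 800)

#: Sliding-window length for saccade-rate time courses, ms.
RATE_WINDOW_MS = 50

#: Step for saccade-rate time courses, ms.
RATE_STEP_MS = 1

#: Overlapping saccade-size bin width / increment, degrees.
SIZE_BIN_DEG = 0.2
SIZE_STEP_DEG = 0.04

#: STFT parameters for time-frequency analysis.
TFR_WINDOW_MS = 300
TFR_STEP_MS = 20
TFR_FMIN_HZ = 3
TFR_FMAX_HZ = 40

#: Pointwise two-sided alpha for cluster formation.
CLUSTER_ALPHA = 0.05

#: Default number of sign-flip permutations.
N_PERMUTATIONS = 10_000

#: ERP-image smoothing: fraction of neighboring (sorted) trials, and the
#: time-domain sliding window in ms.
ERP_IMAGE_TRIAL_FRAC = 0.10
ERP_IMAGE_TIME_MS = 50

#: Search window for the per-row extremum in ERP-image alignment, ms.
ALIGN_SEARCH_WINDOW_MS = (150, 500)

#: Behavioral trimming: absolute RT ceiling (ms) and SD cutoff.
RT_CEILING_MS = 3000
RT_SD_CUTOFF = 2.5
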