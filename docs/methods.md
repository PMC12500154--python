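# Methods

`saccatt` re-implements, as a tested pipeline, the analysis chain that links
small fixational eye movements (microsaccades) to the N2pc — the
contralateral-minus-ipsilateral posterior ERP component that indexes covert
and internal shifts of spatial attention. Because the underlying human
recordings are not redistributable, every stage is exercised against a
synthetic gaze + EEG generator with planted ground truth. This note
documents the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## The analysis chain

**Blink masking.** Tracker signal loss is encoded as simultaneous exact
zeros on both gaze axes. Every zero run, padded by ±100 ms, is set to NaN;
padded intervals that overlap merge (interval union). Missing samples are
never interpolated — trials with missing data inside a stage's window of
interest are excluded by that stage, mirroring standard practice.

**Microsaccade detection.** Gaze velocity is the per-sample step length
(horizontal only in 1D mode, Euclidean in 2D), smoothed with a
Gaussian-weighted moving average over a 7 ms window (kernel SD =
(n−1)/(2·2.5) samples, the convention of MATLAB-style Gaussian smoothers;
missing samples are excluded with weight renormalization). A saccade starts
at the first sample whose smoothed velocity exceeds `k` × the median
smoothed velocity of the trial's valid samples (default k = 3). Onsets
within 100 ms of a previous accepted crossing are discarded
(onset-to-onset refractory). Direction and magnitude come from mean gaze
position in fixed windows −50..0 ms before vs 50..100 ms after onset;
shifts below 0.05° are not returned as events but recorded per trial so the
classifier can exclude those trials. Open points resolved as package
choices: the median is taken on smoothed velocity; the refractory period is
onset-to-onset; velocity sample *i* is aligned to the later position sample
of its pair, and the onset is reported at that sample.

**Trial classes.** The attention window is half-open [150, 400) ms after
cue onset. Trials with any missing gaze sample in the window are excluded
(`missing-data`); trials whose only in-window shifts are < 0.05° are
excluded (`sub-minimum-shift`); otherwise the *first* in-window event's
direction relative to the cued side labels the trial `toward` or `away`,
and `none` if no event falls in the window.

**Lateralized ERP.** EEG epochs (−1000..+1500 ms, 1024 Hz) are baseline
corrected against −250..0 ms. The contralateral wave averages PO8 on
left-cued and PO7 on right-cued trials (ipsilateral symmetric); the N2pc is
the contra − ipsi difference averaged over [200, 300) ms. Trial-averaged
waves are smoothed with a Gaussian kernel of SD 15 samples using reflective
edge padding (edge handling was unspecified; reflection avoids edge droop).
Per-participant waves are computed first; grand averages are unweighted
participant means.

**Spectral lateralization.** Power is a Hanning-tapered sliding-window
Fourier transform: 300 ms windows (307 samples), hop 20 samples (19.53 ms —
the closest integer hop to the nominal 20 ms at 1024 Hz), zero-padded to a
1024-point FFT so the integer 3–40 Hz grid is exact. The index is
L = 100·(contra − ipsi)/(contra + ipsi) on trial-mean power (ratio of
means, which is stabler than mean of ratios at realistic trial counts),
computed within participant and then averaged. The alpha summary averages
L over 8–12 Hz (inclusive) and [400, 800) ms.

**Cluster permutation test.** For participants × time paired differences: a
pointwise one-sample t-test, two-sided alpha 0.05; maximal runs of adjacent
same-signed supra-threshold samples form clusters scored by summed t
("mass"). The null distribution of the maximum |mass| is built from
participant-level sign flips; each observed cluster's p is the literal
proportion of permutations whose maximum reaches its |mass| (ties count
against the hypothesis; p = 0 is rendered "< 1/n_perm"; the identity
labeling is not forcibly included). Zero-variance time points have no t
statistic and are treated as non-significant (logged). An exhaustive mode
enumerates all 2^n sign patterns for n ≤ 20. A 2D variant uses
4-connectivity over frequency × time maps.

**ERP images.** Trials of one class, pooled over participants and tasks,
are sorted by the latency of the class-defining (first in-window) saccade
and stacked as rows. Derivations: `HEOG` (sign-aligned so a toward-side
deflection is positive on every row), `Oz`, and `N2pc-diff` (per-trial
contra − ipsi given each trial's cued side). The display matrix is smoothed
across sorted trials (Gaussian kernel spanning 10% of rows) and then across
time (50 ms); "span" names the full window, with kernel SD = span/4.
Because both kernels are separable Gaussians the two orders commute; the
regression test pins the full trials-then-time result.

**Alignment statistic.** To quantify the ridge-vs-band impression, the
per-row latency of the absolute extremum (search window 150–500 ms
post-cue) is Spearman-correlated with the sorted onsets, with a
1,000-resample row bootstrap CI. Latencies are extracted from a lightly
smoothed copy of the rows (trial kernel spanning 1% of rows, same 50 ms
time kernel), *not* from the display matrix: smoothing over 10% of rows
leaves only ~10 statistically independent rows no matter how many trials
are pooled, so a null (cue-locked) correlation estimated from the display
matrix has SD ≈ 0.3 and is uninformative. With the 1% kernel the null SD
is ≈ 0.1 at a few thousand rows while saccade-locked ridges (EOG
deflections ≥ ~5 µV, lambda ≈ 6 µV against a sub-µV smoothed noise floor)
still correlate above 0.9.

**Group statistics.** One-way repeated-measures ANOVA (pingouin;
uncorrected df (k−1, (k−1)(n−1)) — no sphericity correction, matching the
reporting convention this pipeline follows — and partial η² =
SS_effect/(SS_effect+SS_error)), two-sided paired and one-sample t-tests
with Cohen's d = mean(diff)/sd(diff) and Bonferroni adjustment over the
stated family (m = 3 for the pairwise class comparisons). Degenerate
inputs: identical vectors return the t → 0 (F → 0) limit; zero-variance
differences with nonzero mean are an error. Behavioral RTs are trimmed in
two ordered steps — drop RTs > 3,000 ms, then drop RTs beyond ±2.5 SD of
each participant's mean computed on step-1 survivors pooled across classes
(per the unqualified "participant's mean"); a zero SD trims nothing.

## The synthetic experiment

The generator emulates a two-task covert-attention design: 23 participants,
600 trials per task (perceptual vs working-memory selection), objects 5°
left/right of fixation, cue at t = 0, left/right cued exactly equally often
per task (shuffled). Per trial it plants:

- a class label drawn from (p_toward, p_away, p_none) = (0.375, 0.24,
  0.385), matching the reported class mix;
- for toward/away trials, a square-wave microsaccade: an outgoing
  raised-cosine displacement (20 ms duration, magnitude uniform 0.1–1.0°,
  onset uniform 160–390 ms) plus an equal-magnitude return saccade 100–250
  ms later — real microsaccades during fixation typically return, and the
  transient EOG boxcar this produces gives the ERP image a well-defined
  extremum;
- background saccades (Poisson, 0.3 Hz) confined to spans whose saccades
  *and returns* stay outside the 150–400 ms window for every class, so
  out-of-window rates are class-independent and planted labels stay valid;
- fixational drift (smoothed Gaussian-walk velocity, RMS 0.5 deg/s),
  white tracker noise (0.001° SD), and with probability 0.05 one blink
  (100–200 ms zero run);
- EEG on PO7/PO8/Oz/HEOG: a cue-locked N2pc Gaussian bump (SD 25 ms,
  centered 250 ms) on the contralateral channel whose *mean over the
  200–300 ms window* equals the configured class amplitude (toward −1.5,
  none −0.5, away 0 µV) times a per-participant gain ~N(1, 0.25) clipped at
  0.2; an HEOG trace equal to 16 µV/deg times the planted eye position; a
  6 µV lambda bump on Oz 125 ms after each outgoing saccade; a 10 Hz alpha
  rhythm (5 µV, random phase per trial) ramping on at 400 ms with
  contralateral amplitude ×(1−0.2) and ipsilateral ×(1+0.2); and
  equal-variance white + 1/f noise totalling 10 µV SD per channel;
- behavior: lognormal RTs (class means 780/820/860 ms, log-SD 0.3) and
  Bernoulli accuracy (0.90/0.88/0.85).

All randomness flows from one seed through counter-based `SeedSequence`
spawning (participant, task, trial), so any trial regenerates independently
of generation order, and fixed-seed runs are byte-identical.

What the generator does **not** model: binocular signals, oculomotor
overshoot, pupil signals, realistic 64-channel topographies, EEG blink/
muscle artifacts (epochs are generated clean, as after artifact rejection),
overlap between cue- and saccade-locked responses beyond linear
superposition, and any dependence of behavior on EEG. Passing tests
therefore demonstrate that the pipeline recovers what was planted under
realistic noise — not that the physiological claims hold in real data.

## Problem sizes and numerical choices

- The end-to-end validation runs the full design scale (23 × 1,200 trials,
  ≈4 minutes); detector validation uses ≥1,000 planted saccades; the
  type-I-error study uses 500 null datasets of 23 × 1,500 samples with
  1,000 permutations each (the pipeline default for real analyses is
  10,000).
- Permutation t statistics are vectorized over sign-flip blocks using the
  sign-invariance of Σx²; cluster masses are extracted with a flattened
  run-boundary cumulative-sum, identical (tested) to the literal per-row
  scan.
- ERP images pool at most 6,000 rows by default (evenly subsampled in
  sorted order) to bound memory.
- Windows are half-open `[lo, hi)` everywhere; the classification boundary
  behavior (150 in, 400 out) is pinned by regression tests.

## Known limitations

- The alignment statistic's light-kernel choice trades visual smoothness
  for statistical validity; its absolute value depends on pooled row count
  and SNR and should be read as a dissociation index, not an effect size.
- The 1D detector ignores vertical displacement by design (task geometry is
  horizontal); the 2D mode exists and is tested but the pipeline default is
  1D.
- Monte-Carlo cluster p-values use the literal proportion rule; for
  publication-grade inference at small n the exhaustive mode is preferable.
- pingouin's repeated-measures ANOVA applies no sphericity correction here,
  by design; report ε if sphericity is in doubt.
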