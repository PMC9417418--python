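# Methods

This note documents the models and procedures implemented in `sleepod`, the
choices made where the methods literature leaves the design open, and what
the synthetic-data studies do and do not demonstrate.

## Binocular rivalry and the deprivation index

Each 3-minute rivalry block is an ordered, non-overlapping sequence of
percept phases (`deprived_eye`, `nondeprived_eye`, `mixed`). Mean phase
duration (MPD, s) per percept pools raw durations across the blocks of one
measurement before averaging (not a mean of per-block means; a
`include_truncated` switch controls the censoring policy). Two conventions:

* phases cut off by the end of a block are censored — they count toward
  total dominance time but not toward the MPD, avoiding downward bias;
* mixed phases are tallied separately and never enter the eye MPDs.

The deprivation index is
`DI = (MPD_dep_base / MPD_dep_post) · (MPD_ndep_post / MPD_ndep_base)`,
dimensionless and positive. DI = 1 means no change; swapping baseline and
post measurements maps DI to 1/DI; multiplying all durations by a constant
leaves it unchanged. The no-change reference is 1 (a ratio of ratios cannot
be 0 without a degenerate MPD); all tests compare against 1. Morning blocks
carry an acquisition minute and are pooled into the bins 0–8, 10–18 and 30
(inclusive edges); a block falling in none of the bins — e.g. minute 9 — is
excluded with a warning. The extended bin set 0–8 / 10–18 / 30–48 / 60–93 /
120–123 serves the circadian control sessions.

## EEG preprocessing

Signals are microvolts, channels × samples, uniformly sampled (500 Hz
nominal). Steps, each optional and configurable:

* **Mastoid re-referencing** subtracts the mean of the two mastoid channels.
* **Filtering** is zero-phase (forward–backward). The 0.1 Hz high-pass is a
  4th-order Chebyshev II with its stopband edge one octave below the cutoff
  (40 dB design attenuation; the near-DC stopband makes edge transients
  long, so a 5 s pad is used). Mains notches are IIR notches (Q = 30).
* **Bad channels**: per channel variance (log10), skewness and kurtosis;
  a channel is flagged when the robust z-score (median/1.4826·MAD) of any
  moment exceeds 4 *and* the absolute deviation exceeds a floor (0.3 log10
  units ≈ a 2× amplitude change, 0.5 skewness, 1.0 kurtosis). The floor
  prevents spurious flags on homogeneous montages where the MAD is tiny.
  Flagged channels are excluded from ROI averages, not interpolated.
* **NREM selection** returns maximal single-stage N2/N3 runs from the 30 s
  hypnogram, clipped to the recording, minus the artifact-mask intervals.

## Band power

Each NREM segment is tiled into consecutive, non-overlapping windows
(10 s night bands: SWA 0.5–4 Hz, sigma 9–15 Hz; 4 s wake bands:
theta/alpha/low-beta/high-beta/gamma). Windows crossing a segment boundary
are dropped. Per window and channel: demean, Hamming taper, FFT, one-sided
power density, per-bin 10·log10 (floor 1e−12, flagged). A band averages its
bins with the convention lo ≤ f < hi (0.1 Hz resolution at 10 s), and the
channel value averages windows. Doubling the signal amplitude raises every
band by exactly 20·log10 2 ≈ 6.02 dB. Averaging dB per bin follows the
processing order of the source method; a linear-then-dB alternative
(`per_bin_db=False`) exists for sensitivity analyses — a pure tone shows the
difference starkly, since empty bins pin the per-bin-dB average to the floor.

## Sleep macrostructure

From the hypnogram: sleep latency (lights-off to first N2, min), WASO (wake
after the first non-wake epoch, min), stage-shift rate (any stage change per
hour of sleep), fragmentation (transitions to W plus transitions to a
lighter NREM stage per hour of sleep, with depth W < N1 < N2 < N3 and REM
as its own class — entering REM is not a lightening), stage minutes, and
REM latency from sleep onset. Missing N2 or REM flags the corresponding
latency rather than reporting 0.

## Slow-oscillation detection

Detection operates on a slow-band conditioned signal (zero-phase Butterworth
band-pass 0.1–6 Hz, order 2; cutoffs configurable) — raw broadband noise
would make sample-level zero crossings degenerate. Zero crossings are sign
changes through 0 μV of the re-referenced voltage, at sample resolution: a
negative-going crossing is the first sample below zero, a positive-going one
the first at or above zero. For every consecutive down/up crossing pair:

1. separation within 0.3–1.0 s;
2. negative peak between the crossings at or below −80 μV;
3. positive peak in the following positive half-wave, with
   peak-to-peak (NP) amplitude ≥ 140 μV.

"Less than −80 μV" is read as *more negative than* −80 μV. Waves meeting
only the timing criterion are kept as candidates for event completion.
Full-fledged waves across channels whose successive negative peaks are
within 200 ms (chained linkage — the permissive reading of the tolerance)
form one event; channels without a full-fledged member contribute the
closest timing-valid candidate within 200 ms of the event reference if it
clears a relaxed floor (negative peak ≤ −30 μV, NP ≥ 50 μV; both
configurable and recorded in the run manifest). Single-channel events are
retained, so K-complex-like waves are naturally included.

Per-channel features: detection rate in waves per minute of artifact-free
NREM (full-fledged + completion waves; a full-fledged-only rate is emitted
alongside because the source description does not fix which set the rate
counts), mean NP amplitude (μV), mean slope+ = |negative peak| / (t_zc2 −
t_negpeak) in μV/s (the "recovery from the down-state" convention; a
max-derivative alternative is selectable), and the pre-event sigma power:
Hamming FFT of the 1 s window ending at the wave's first zero crossing
(anchor configurable to the negative peak), dB mean over 9–15 Hz. Waves
starting less than 1 s into the recording are skipped and counted.

## Spindle detection

12–16 Hz zero-phase elliptic band-pass, designed at half the target specs so
the forward–backward pass yields ≤ 1 dB ripple at 14 Hz and ≥ 20 dB
attenuation at 11 and 17 Hz (measured: ≈ 29 and 40 dB). The upper and lower
envelopes interpolate the local maxima/minima of the filtered trace with a
shape-preserving cubic (PCHIP; endpoints anchor both envelopes); their
distance, clipped at zero, is the amplitude signal. Per NREM period the
amplitude signal yields mean + 2·SD; the channel threshold θ is the
period-length-weighted average (two periods of 60 s/120 s with values
10/16 μV give θ = 14 μV exactly). Events are runs where the amplitude
signal exceeds **2·θ**, merged across gaps < 0.25 s, kept at 0.3–3.0 s.
The literal composition ×2 × (mean + 2·SD) is unusually strict and the
source description is ambiguous about whether the factor duplicates the
+2·SD step, so the multiplier is a config parameter (default 2) and the
pipeline manifest reports event counts at multipliers {1, 1.5, 2} for
auditing the operating point. Scaling the whole signal by k scales θ and
the amplitude signal by k and leaves the detected set identical.

Event sigma power is 10·log10 of the mean squared filtered signal over the
event (the trace is already band-limited to 12–16 Hz, which keeps the
estimate well-defined for sub-second events where an FFT would have ~1–3
bins in band). Density = events per minute of artifact-free NREM; spindle
power = mean event power (dB).

## Statistics

* **Spearman**: midranks for ties, Pearson on the ranks; two-sided p by
  exhaustive permutation for n ≤ 9 and by the t-approximation above.
  Pairwise deletion for missing values; constant input flags ρ undefined.
* **BH-FDR**: Benjamini–Hochberg step-up (statsmodels), q = 0.05 by default;
  families mirror the test groupings (one family per DI pairing).
* **Wilcoxon signed-rank**: zero differences dropped; all-zero input is
  degenerate with p = 1, not an error.
* **t-tests vs 1**: two-tailed, Cohen's d = |mean − 1| / SD (paired
  analogue on differences); FDR across timepoints.
* **Repeated-measures ANOVA**: one within factor or a 2×2 design with
  interaction, via pingouin; partial η² = SS_effect/(SS_effect+SS_error);
  subjects with missing cells dropped listwise with a warning. Brute-force
  sum-of-squares decompositions serve as test oracles.
* **ROI averaging**: unweighted mean over member channels (bad channels
  excluded; an emptied ROI flags the feature missing). The shipped layout
  (`sleepod/data/roi_layout.yaml`) uses generic 10-20-style labels and is
  plain data, meant to be replaced per montage.

## Synthetic data

The generators define the study conditions the package validates against.

* **NREM EEG**: background is Gaussian noise with a 1/f^α spectrum (α = 1)
  above a 1 Hz knee, rolling off linearly in amplitude below it — recorded
  sleep EEG is AC-coupled and carries little sub-0.5 Hz drift; without the
  rolloff, sustained sub-zero excursions merge the pre-wave zero crossing
  into the wave and stretch measured crossing separations. RMS 20 μV by
  default. Slow oscillations are two concatenated half-sines (down then up)
  with analytically known landmarks: negative peak −115 ± 10 μV clipped at
  [−150, −95], positive peak 0.9·|negative|, crossing separation uniform
  0.4–0.8 s. Spindles are a 12.5–15.5 Hz carrier under a Hann envelope,
  0.8–1.4 s, carrier amplitude 85 ± 8 μV clipped at [70, 105] (envelope
  distance ≈ 170 μV at the peak). Event amplitudes are deliberately
  prominent: the ×2 × (mean+2·SD) spindle threshold self-inflates with event
  occupancy, and the −80 μV criterion must stay clear of in-band noise —
  these defaults make the detectors' operating point testable, they are not
  a model of the physiological amplitude distribution. Events are placed
  uniformly without overlap (capacity error above 50 % occupancy); all
  randomness flows from one integer seed.
* **Rivalry timelines**: alternating eye phases with gamma-distributed
  durations (shape 3.5 — standard rivalry phenomenology; the experiments
  measured, not modelled, the durations), optional mixed interludes at a
  configurable insertion probability, final phase truncated at the block
  end and flagged. A session helper encodes a known DI by splitting the
  post-deprivation MPDs symmetrically (dep = base/√DI, ndep = base·√DI).
* **Cohorts**: a standard-normal latent plasticity score maps through a
  lognormal to the DI before sleep (mean 0.77, SD 0.174); a second latent,
  coupled at Spearman 0.18, drives the DI after sleep (mean 0.87). Each
  feature change mixes the relevant latent at Pearson weight 2·sin(πρ/6),
  which makes the *population* Spearman correlation equal the target exactly
  (bivariate-normal identity). `noise_sd` adds measurement noise on top
  (attenuating the correlation); the default is 0. The sample Spearman at
  n = 15 is biased toward zero by ≈ 0.03–0.04 at |ρ| ≈ 0.7 — recovery
  checks compare the mean over replicate cohorts within ±0.05.

What the synthetic studies do **not** show: performance on real high-density
recordings with non-stationary background, arousals, true K-complex
morphology, movement artifacts, volume-conducted correlated noise across
channels, or realistic (much broader and lower) event-amplitude
distributions. Passing the recovery criteria demonstrates that the
implementations realize the stated criteria faithfully and that the
statistical chain is calibrated, not that the detectors would reach the same
recall on clinical data.

## Problem sizes

Validation studies use 8-channel, 10-minute recordings for detector
recovery; 19-subject night cohorts and 17-subject dark-exposure cohorts with
2 blocks per timepoint (5 morning blocks); 500 replicate cohorts for the
feature-correlation means and 1,000 for parameter recovery and FDR control.
These sizes put Monte-Carlo error well inside the comparison tolerances
while keeping a full run in seconds.

## Known limitations

* EDF is read (via mne) but not written; the native interchange format is a
  matrix (NPZ/CSV) with a JSON sidecar carrying labels, rate and units.
* The exhaustive zero-crossing enumeration reports landmarks at sample
  resolution; no sub-sample interpolation is attempted.
* The cited upstream detector implementations may impose constraints beyond
  the printed criteria (e.g. a positive-peak search window); only the
  printed criteria are normative here.
* On an exactly-zero background (no noise), the conditioning filter's
  DC-removal tails dominate the sample-level zero crossings; noiseless
  exact-recovery checks therefore run on the already band-limited synthetic
  signal.
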