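# sleepod

Sleep EEG oscillations and ocular-dominance homeostatic plasticity analysis.

Short-term monocular deprivation (MD) in adult humans transiently *boosts*
the deprived eye — a homeostatic gain change measured with binocular rivalry
— and NREM sleep stabilizes that boost. `sleepod` implements the complete
computational chain needed to study this interaction:

* **Binocular rivalry / deprivation index.** From percept timelines
  (deprived eye / non-deprived eye / mixed), mean phase durations (MPD) are
  pooled across blocks, and the deprivation index is the ratio of ratios

  ```
  DI = (MPD_dep^base / MPD_dep^post) * (MPD_ndep^post / MPD_ndep^base)
  ```

  DI = 1 means no change; DI < 1 means the deprived eye is boosted.
  Morning blocks are pooled into acquisition-minute bins (0–8, 10–18, 30;
  extended control bins supported).

* **Sleep slow oscillations (SSO).** Per channel, a full-fledged SSO has two
  zero crossings 0.3–1.0 s apart (the first negative-going), a negative peak
  below −80 μV between them, and a negative-to-positive peak amplitude of at
  least 140 μV. Near-simultaneous waves (negative peaks within 200 ms,
  chained) cluster into multi-channel events, completed by concurrent
  sub-threshold waves on the remaining channels. Features: detection rate
  (waves/min of artifact-free NREM), NP amplitude, slope+ (|negative peak| /
  time to the next zero crossing), and sigma power (9–15 Hz) in the 1 s
  window preceding each wave.

* **Sleep spindles.** 12–16 Hz zero-phase band-pass (≥ 20 dB down at 11 and
  17 Hz), envelope-distance amplitude signal (upper minus lower envelope
  through the local extrema), per-NREM-period mean + 2·SD combined into a
  length-weighted per-channel threshold θ, and events where the amplitude
  signal exceeds 2·θ for 0.3–3 s. Features: density (events/min) and spindle
  power (mean event sigma power, dB).

* **Band power & macrostructure.** Hamming-windowed FFT on consecutive 10 s
  NREM windows, per-bin dB, band averages for slow-wave activity (0.5–4 Hz)
  and sigma (9–15 Hz); a 4 s wake-band variant; sleep latency, WASO,
  stage-shift and fragmentation rates, stage durations, REM latency.

* **Statistics.** ROI averaging (occipital / prefrontal / sensorimotor),
  MD-minus-control change scores, Spearman correlations (midranks, exact
  permutation p for n ≤ 9) with Benjamini–Hochberg FDR, Wilcoxon signed-rank,
  one-sample/paired t-tests against 1 with Cohen's d, and repeated-measures
  ANOVA with partial η².

* **Synthetic data.** Seeded generators for NREM EEG (1/f background with
  embedded slow-oscillation and spindle templates whose landmarks are known
  analytically), gamma-distributed rivalry timelines, and subject cohorts in
  which a latent plasticity score induces an exact target Spearman
  correlation between the deprivation index and each sleep-feature change
  (Gaussian copula, r = 2·sin(πρ/6)).

## Worked example

```bash
python analysis/01_simulate_night.py      # synthetic 8-channel NREM night
python analysis/02_detect_events.py       # detect + score vs ground truth
python analysis/03_rivalry_deprivation_index.py
python analysis/04_sleep_feature_correlations.py
```

The second step prints the detector scores on a 10-minute, 8-channel night
with noise RMS 20 μV:

```
detector  recall  precision  n_true  n_detected
     sso  0.9750        1.0     320         312
 spindle  0.9688        1.0     160         155
```

i.e. 97.5 % of the injected slow oscillations and 96.9 % of the spindles are
recovered with no false detections. The third step re-estimates every
deprivation index from raw simulated timelines of a 19-subject cohort:

```
night sessions (n=19), mean deprivation index per timepoint:
  before    0.764
  after     0.876
  morning1  0.888
before sleep vs 1: t(18) = -6.07, p_fdr = 3e-05, d = 1.39
time course: F(4,72) = 6.71, p = 0.00012, partial eta2 = 0.27
```

The deprived-eye boost (DI ≈ 0.76 < 1) is highly significant right after
patch removal, persists attenuated after sleep, and the five-timepoint
repeated-measures ANOVA confirms the time course; the dark-exposure control
decays back to DI ≈ 1 within two hours. The fourth step shows that the
feature-vs-plasticity rank correlations are recovered (with the expected
small-sample shrinkage of Spearman's ρ at n = 15) and that BH-FDR holds the
false-discovery proportion on null features under q = 0.05.

A `sleepod` command-line interface wraps the same library
(`simulate`, `rivalry`, `bandpower`, `detect-sso`, `detect-spindles`,
`correlate`, `run`); `sleepod run --config cfg.yaml` executes the full
pipeline and writes event tables, feature tables, and a manifest with the
config hash and input checksums.

## Documentation

See `docs/methods.md` for the model and procedure details, parameter
defaults with units, what the synthetic generators do and do not emulate,
and known limitations.
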