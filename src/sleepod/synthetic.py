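"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators, all driven by a single integer seed:

* :func:`generate_nrem_eeg` - multichannel NREM-like EEG: 1/f^alpha background
  noise with embedded biphasic slow-oscillation templates (two half-sines with
  analytically known landmarks) and 12-16 Hz spindle packets under a
  raised-cosine envelope, together with the hypnogram, an (empty by default)
  artifact mask, and the list of every injected event.
* :func:`generate_rivalry_timeline` - a binocular-rivalry block whose phase
  durations follow a gamma law (shape 3.5 by default, a standard description
  of rivalry phenomenology) with optional mixed interludes.
* :func:`generate_cohort` - a subject cohort in which a latent plasticity
  score drives both the deprivation index and each sleep-feature change
  through a Gaussian copula, so the population Spearman correlation equals a
  requested target exactly (via the bivariate-normal identity
  r = 2 sin(pi * rho / 6)).

Defaults mirror the study conditions the detectors are meant for: 500 Hz
sampling, slow-oscillation negative peaks around -115 uV with NP amplitudes
near 220 uV, spindle envelopes of ~170 uV peak-to-peak, a 19-subject cohort
with mean deprivation index 0.77 (SD 0.17) before sleep and 0.87 after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preproc import ArtifactMask, EEGRecording, Hypnogram
from .rivalry import DEPRIVED, MIXED, NONDEPRIVED, RivalryEvent, RivalryTimeline


class CapacityError(ValueError):
    """Requested events cannot be placed without exceeding the occupancy cap."""


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TrueSSO:
    channel: str
    t_negpeak: float
    neg_amp: float
    np_amp: float
    duration: float  # zero-crossing separation of the negative half-wave, s

    @property
    def t_onset(self) -> float:
        return self.t_negpeak - self.duration / 2.0


@dataclass
class TrueSpindle:
    channel: str
    onset: float
    offset: float
    carrier_hz: float
    peak_env: float  # peak of the envelope-distance signal, uV


@dataclass
class GroundTruth:
    sso_events: list[TrueSSO] = field(default_factory=list)
    spindle_events: list[TrueSpindle] = field(default_factory=list)
    cohort_params: dict = field(default_factory=dict)

    def validate(self, duration: float) -> None:
        for e in self.sso_events:
            assert 0 <= e.t_negpeak <= duration and np.isfinite(e.neg_amp)
        for s in self.spindle_events:
            assert 0 <= s.onset < s.offset <= duration and np.isfinite(s.peak_env)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic NREM recording."""

    duration: float = 600.0
    n_channels: int = 8
    sfreq: float = 500.0
    noise_exponent: float = 1.0
    noise_rms: float = 20.0
    noise_knee_hz: float = 1.0
    sso_rate_per_min: float = 4.0
    sso_neg_amp: tuple[float, float] = (-115.0, 10.0)  # mean, sd (clipped)
    sso_neg_amp_bounds: tuple[float, float] = (-150.0, -95.0)
    sso_down_dur: tuple[float, float] = (0.4, 0.8)  # uniform bounds, s
    sso_up_dur: tuple[float, float] = (0.4, 0.8)
    sso_pos_frac: float = 0.9  # positive peak as a fraction of |negative peak|
    spindle_rate_per_min: float = 2.0
    spindle_amp: tuple[float, float] = (85.0, 8.0)  # carrier amplitude mean, sd
    spindle_amp_bounds: tuple[float, float] = (70.0, 105.0)
    spindle_dur: tuple[float, float] = (0.8, 1.4)
    spindle_carrier: tuple[float, float] = (12.5, 15.5)
    stage: str = "N2"
    max_occupancy: float = 0.5
    min_gap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 60:
            raise ValueError("simulated recordings must last at least 60 s")
        if self.sfreq <= 2 * max(self.spindle_carrier):
            raise ValueError("sampling rate below Nyquist for the spindle carrier")
        if self.sso_rate_per_min < 0 or self.spindle_rate_per_min < 0:
            raise ValueError("event rates must be non-negative")


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------


def sso_template(
    sfreq: float, neg_amp: float, pos_amp: float, down_dur: float, up_dur: float
) -> np.ndarray:
    """Biphasic slow oscillation: negative then positive half-sine.

    The zero crossings fall exactly ``down_dur`` apart, the negative peak
    (``neg_amp`` < 0) at the centre of the first half-wave, the positive peak
    at the centre of the second.
    """
    n1 = int(round(down_dur * sfreq))
    n2 = int(round(up_dur * sfreq))
    down = neg_amp * np.abs(np.sin(np.pi * np.arange(n1) / n1))
    up = pos_amp * np.abs(np.sin(np.pi * np.arange(n2) / n2))
    return np.concatenate([down, up])


def spindle_template(
    sfreq: float, duration: float, carrier_hz: float, amp: float
) -> np.ndarray:
    """12-16 Hz sinusoid under a raised-cosine (Hann) envelope."""
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    env = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    return env * np.sin(2.0 * np.pi * carrier_hz * t)


def one_over_f_noise(
    rng: np.random.Generator,
    n: int,
    sfreq: float,
    exponent: float,
    rms: float,
    knee_hz: float = 0.5,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum above the knee.

    Below the knee the spectrum rolls off linearly in amplitude, emulating the
    AC coupling of EEG acquisition (recorded sleep background carries little
    sub-0.5 Hz drift).
    """
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    with np.errstate(divide="ignore"):
        shaping = np.where(
            f >= knee_hz,
            np.maximum(f, 1e-12) ** (-exponent / 2.0),
            (f / knee_hz) * knee_hz ** (-exponent / 2.0),
        )
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    durations: np.ndarray,
    total: float,
    min_gap: float,
    max_occupancy: float,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Non-overlapping start times; CapacityError if they cannot fit."""
    if n_events == 0:
        return np.empty(0)
    if (durations.sum() + min_gap * n_events) / total > max_occupancy:
        raise CapacityError(
            f"{n_events} events of total {durations.sum():.0f} s exceed "
            f"{max_occupancy:.0%} occupancy of a {total:.0f} s recording"
        )
    placed: list[tuple[float, float]] = []
    starts = np.empty(n_events)
    for k in range(n_events):
        d = durations[k]
        for _ in range(max_tries):
            s = rng.uniform(min_gap, total - d - min_gap)
            if all(s + d + min_gap <= a or s >= b + min_gap for a, b in placed):
                placed.append((s, s + d))
                starts[k] = s
                break
        else:
            raise CapacityError("could not place events without overlap")
    return starts


# ---------------------------------------------------------------------------
# EEG generator
# ---------------------------------------------------------------------------


def generate_nrem_eeg(
    spec: SimulationSpec,
) -> tuple[EEGRecording, Hypnogram, ArtifactMask, GroundTruth]:
    """Synthesize an NREM recording with known embedded events.

    Events are placed independently per channel, never overlapping within a
    channel.  The ground truth lists every injected slow oscillation (time of
    negative peak, amplitudes, zero-crossing separation) and spindle (onset,
    offset, carrier, peak of the envelope-distance signal = twice the carrier
    envelope peak).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sfreq))
    ch_names = [f"ch{i + 1}" for i in range(spec.n_channels)]
    data = np.empty((spec.n_channels, n))
    truth = GroundTruth()

    minutes = spec.duration / 60.0
    n_sso = int(round(spec.sso_rate_per_min * minutes))
    n_sp = int(round(spec.spindle_rate_per_min * minutes))

    for ci, ch in enumerate(ch_names):
        x = one_over_f_noise(
            rng, n, spec.sfreq, spec.noise_exponent, spec.noise_rms,
            spec.noise_knee_hz,
        )
        # draw all event shapes first so placement sees their durations
        down = rng.uniform(*spec.sso_down_dur, n_sso)
        up = rng.uniform(*spec.sso_up_dur, n_sso)
        neg = np.clip(
            rng.normal(spec.sso_neg_amp[0], spec.sso_neg_amp[1], n_sso),
            spec.sso_neg_amp_bounds[0], spec.sso_neg_amp_bounds[1],
        )
        sp_dur = rng.uniform(*spec.spindle_dur, n_sp)
        sp_amp = np.clip(
            rng.normal(spec.spindle_amp[0], spec.spindle_amp[1], n_sp),
            spec.spindle_amp_bounds[0], spec.spindle_amp_bounds[1],
        )
        sp_car = rng.uniform(*spec.spindle_carrier, n_sp)

        durations = np.concatenate([down + up, sp_dur])
        starts = _place_events(
            rng, n_sso + n_sp, durations, spec.duration, spec.min_gap,
            spec.max_occupancy,
        )
        for k in range(n_sso):
            tpl = sso_template(
                spec.sfreq, neg[k], spec.sso_pos_frac * abs(neg[k]), down[k], up[k]
            )
            i0 = int(round(starts[k] * spec.sfreq))
            x[i0 : i0 + len(tpl)] += tpl[: n - i0]
            truth.sso_events.append(
                TrueSSO(
                    channel=ch,
                    t_negpeak=starts[k] + down[k] / 2.0,
                    neg_amp=float(neg[k]),
                    np_amp=float((1.0 + spec.sso_pos_frac) * abs(neg[k])),
                    duration=float(down[k]),
                )
            )
        for k in range(n_sp):
            j = n_sso + k
            tpl = spindle_template(spec.sfreq, sp_dur[k], sp_car[k], sp_amp[k])
            i0 = int(round(starts[j] * spec.sfreq))
            x[i0 : i0 + len(tpl)] += tpl[: n - i0]
            truth.spindle_events.append(
                TrueSpindle(
                    channel=ch,
                    onset=float(starts[j]),
                    offset=float(starts[j] + sp_dur[k]),
                    carrier_hz=float(sp_car[k]),
                    peak_env=float(2.0 * sp_amp[k]),
                )
            )
        data[ci] = x

    rec = EEGRecording(data=data, ch_names=ch_names, sfreq=spec.sfreq,
                       reference="synthetic")
    n_epochs = int(math.ceil(spec.duration / 30.0))
    hyp = Hypnogram(stages=[spec.stage] * n_epochs)
    truth.validate(spec.duration)
    return rec, hyp, ArtifactMask(), truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def match_events(
    true_times: Sequence[float],
    detected_times: Sequence[float],
    tol: float = 0.25,
) -> tuple[int, int, int]:
    """Greedy one-to-one interval matching: (hits, misses, false alarms)."""
    true_left = sorted(true_times)
    det = sorted(detected_times)
    hits = 0
    used = [False] * len(det)
    for t in true_left:
        best, best_d = None, tol
        for i, d in enumerate(det):
            if used[i]:
                continue
            dd = abs(d - t)
            if dd <= best_d:
                best, best_d = i, dd
        if best is not None:
            used[best] = True
            hits += 1
    return hits, len(true_left) - hits, len(det) - hits


def recall_precision(hits: int, misses: int, fas: int) -> tuple[float, float]:
    recall = hits / (hits + misses) if hits + misses else float("nan")
    precision = hits / (hits + fas) if hits + fas else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# rivalry generator
# ---------------------------------------------------------------------------


def generate_rivalry_timeline(
    mean_dur_a: float,
    mean_dur_b: float,
    mixed_fraction: float = 0.0,
    block_len: float = 180.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    gamma_shape: float = 3.5,
    mixed_mean: float = 1.5,
    labels: tuple[str, str] = (DEPRIVED, NONDEPRIVED),
    block_id: str = "",
    minutes_after: float | None = None,
) -> RivalryTimeline:
    """One rivalry block with gamma-distributed alternating phases.

    Percepts alternate between the two eyes; before each dominance phase a
    mixed interlude is inserted with probability ``mixed_fraction``.  The
    final phase is truncated at the block end and flagged as censored.
    """
    if mean_dur_a <= 0 or mean_dur_b <= 0:
        raise ValueError("mean phase durations must be positive")
    if not 0 <= mixed_fraction < 1:
        raise ValueError("mixed_fraction must lie in [0, 1)")
    if block_len <= 0:
        raise ValueError("block length must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    means = {labels[0]: mean_dur_a, labels[1]: mean_dur_b}
    events: list[RivalryEvent] = []
    t = 0.0
    which = int(rng.integers(2))
    while t < block_len:
        if events and mixed_fraction > 0 and rng.random() < mixed_fraction:
            d = rng.gamma(gamma_shape, mixed_mean / gamma_shape)
            percept = MIXED
        else:
            percept = labels[which]
            d = rng.gamma(gamma_shape, means[percept] / gamma_shape)
            which = 1 - which
        end = min(t + d, block_len)
        events.append(
            RivalryEvent(percept=percept, onset=t, offset=end,
                         truncated=end < t + d)
        )
        t += d
    return RivalryTimeline(events=events, block_len=block_len, block_id=block_id,
                           minutes_after=minutes_after)


def generate_rivalry_session(
    true_di: float,
    baseline_mpd: float = 2.5,
    n_blocks: int = 2,
    block_len: float = 180.0,
    mixed_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[RivalryTimeline], list[RivalryTimeline]]:
    """Baseline and post-deprivation blocks encoding a known deprivation index.

    The post-measurement mean phase durations are split symmetrically:
    deprived-eye MPD = baseline / sqrt(DI), non-deprived = baseline * sqrt(DI),
    so the population deprivation index equals ``true_di``.
    """
    if true_di <= 0:
        raise ValueError("the deprivation index must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    s = math.sqrt(true_di)
    base = [
        generate_rivalry_timeline(
            baseline_mpd, baseline_mpd, mixed_fraction, block_len, rng=rng,
            block_id=f"base{b}",
        )
        for b in range(n_blocks)
    ]
    post = [
        generate_rivalry_timeline(
            baseline_mpd / s, baseline_mpd * s, mixed_fraction, block_len,
            rng=rng, block_id=f"post{b}",
        )
        for b in range(n_blocks)
    ]
    return base, post


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

#: default feature couplings: (anchor DI, Spearman target as a multiple of the
#: requested target_rho; 0.0 marks a null feature)
DEFAULT_FEATURES: dict[str, tuple[str, float]] = {
    "sso_rate": ("di_before", 1.0),
    "sso_slope_pos": ("di_before", 1.0),
    "spindle_power": ("di_before", 1.0),
    "spindle_density_prefrontal": ("di_after", 1.0),
    "swa_power": ("di_before", 0.0),
    "sigma_power_sensorimotor": ("di_after", 0.0),
}

#: lognormal parameters matched to the observed deprivation-index moments
#: (mean 0.77, SD 0.174 before sleep; mean 0.87, SD 0.174 after)
_DI_BEFORE = (0.77, 0.174)
_DI_AFTER = (0.87, 0.174)
_RHO_BEFORE_AFTER = 0.18


def spearman_to_pearson(rho: float) -> float:
    """Exact bivariate-normal conversion r = 2 sin(pi * rho / 6)."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def generate_cohort(
    n_subjects: int = 19,
    target_rho: float = -0.66,
    noise_sd: float = 0.0,
    seed: int | None = None,
    feature_rhos: dict[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Cohort table coupling the deprivation index to sleep-feature changes.

    A latent plasticity score (one standard normal per subject) maps
    monotonically to the deprivation index before sleep; a second, weakly
    coupled latent drives the DI after sleep.  Each feature change is a
    Gaussian mixed with the relevant DI latent at Pearson weight
    ``2 sin(pi*rho/6)``, which makes the population Spearman correlation equal
    the requested target exactly.  ``noise_sd`` adds independent measurement
    noise to the observed feature changes (attenuating the correlation);
    the default of zero reproduces the copula targets exactly.

    The returned frame has one row per subject with columns ``di_before``,
    ``di_after``, ``plasticity`` (the latent score) and ``delta_<feature>``;
    ``frame.attrs['true_rho']`` records each feature's population target.
    """
    if n_subjects < 4:
        raise ValueError("rank correlations need at least 4 subjects")
    if not abs(target_rho) <= 1:
        raise ValueError("|target_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    features = dict(feature_rhos) if feature_rhos is not None else {
        name: (anchor, scale * target_rho)
        for name, (anchor, scale) in DEFAULT_FEATURES.items()
    }

    z_before = rng.standard_normal(n_subjects)
    r_ab = spearman_to_pearson(_RHO_BEFORE_AFTER)
    z_after = r_ab * z_before + math.sqrt(1 - r_ab**2) * rng.standard_normal(
        n_subjects
    )
    mu_b, sg_b = _lognormal_params(*_DI_BEFORE)
    mu_a, sg_a = _lognormal_params(*_DI_AFTER)
    di_before = np.exp(mu_b + sg_b * z_before)
    di_after = np.exp(mu_a + sg_a * z_after)

    out = pd.DataFrame(
        {
            "subject": [f"s{i + 1:02d}" for i in range(n_subjects)],
            "plasticity": -z_before,  # high plasticity <-> low DI before
            "di_before": di_before,
            "di_after": di_after,
        }
    )
    true_rho = {}
    for name, (anchor, rho) in features.items():
        if abs(rho) > 1:
            raise ValueError(f"feature {name!r} target rho out of range")
        z = z_before if anchor == "di_before" else z_after
        r = spearman_to_pearson(rho)
        latent = r * z + math.sqrt(1 - r**2) * rng.standard_normal(n_subjects)
        out[f"delta_{name}"] = latent + noise_sd * rng.standard_normal(n_subjects)
        true_rho[name] = {"anchor": anchor, "rho": rho}
    out.attrs["true_rho"] = true_rho
    out.attrs["noise_sd"] = noise_sd
    return out
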