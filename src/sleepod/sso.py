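"""Sleep slow-oscillation (SSO) detection and characterization.

A full-fledged SSO on a channel is a wave satisfying three criteria on the
slow-band signal:

1. two zero crossings separated by 0.3-1.0 s, the first with negative slope;
2. a negative peak below -80 uV between the two crossings;
3. a negative-to-positive peak amplitude (NP amp) of at least 140 uV, the
   positive peak being taken in the positive half-wave that follows the
   second crossing.

Full-fledged waves that are near-simultaneous across channels (negative peaks
within 200 ms, chained linkage) form one multi-channel event; channels without
a full-fledged wave contribute a concurrent "completion" wave when a
timing-valid wave with relaxed amplitudes (negative peak <= -30 uV, NP amp
>= 50 uV by default) has its negative peak within the tolerance of the event
reference.  Single-channel events are retained (this family of criteria
naturally includes K-complexes).

Per-channel features: detection rate (waves/min of artifact-free NREM), mean
NP amplitude, mean slope+ (|negative peak| / time from negative peak to the
next zero crossing, uV/s), and the sigma power (9-15 Hz) in the 1 s window
preceding each wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preproc import EEGRecording, Segment, band_bins

#: printed detection criteria (uV, s)
NEG_PEAK_MAX_UV = -80.0
NP_AMP_MIN_UV = 140.0
DURATION_BOUNDS_S = (0.3, 1.0)
CLUSTER_TOL_S = 0.2

#: relaxed floor for sub-threshold completion waves (configurable)
COMPLETION_NEG_PEAK_UV = -30.0
COMPLETION_NP_AMP_UV = 50.0


@dataclass
class SSOWave:
    """Landmarks of one slow-oscillation wave on one channel (seconds, uV)."""

    channel: str
    t_zc1: float
    t_negpeak: float
    t_zc2: float
    t_pospeak: float
    neg_amp: float
    pos_amp: float
    full_fledged: bool

    @property
    def np_amp(self) -> float:
        return self.pos_amp - self.neg_amp

    @property
    def duration(self) -> float:
        """Separation of the two zero crossings."""
        return self.t_zc2 - self.t_zc1

    @property
    def slope_pos(self) -> float:
        """|negative peak| / (t_zc2 - t_negpeak), uV/s."""
        return abs(self.neg_amp) / (self.t_zc2 - self.t_negpeak)


@dataclass
class SSOEvent:
    """Multi-channel clustered SSO event."""

    waves: list[SSOWave]

    @property
    def ref_time(self) -> float:
        """Earliest member negative-peak time."""
        return min(w.t_negpeak for w in self.waves)

    @property
    def channels(self) -> set[str]:
        return {w.channel for w in self.waves}

    @property
    def n_fullfledged(self) -> int:
        return sum(w.full_fledged for w in self.waves)


def condition_slow(rec: EEGRecording, band: tuple[float, float] = (0.1, 6.0),
                   order: int = 2) -> EEGRecording:
    """Zero-phase band-pass to the slow band before zero-crossing analysis."""
    sos = sps.butter(order, band, btype="bandpass", output="sos", fs=rec.sfreq)
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=-1)
    return out


def _enumerate_waves(
    x: np.ndarray,
    sfreq: float,
    t0: float,
    channel: str,
    duration_bounds: tuple[float, float],
) -> list[SSOWave]:
    """All waves with a valid zero-crossing pair in one contiguous trace.

    Zero crossings are located at sample resolution: a negative-going crossing
    is the first sample with x < 0 after a sample with x >= 0, a positive-going
    crossing the first sample with x >= 0 after a sample with x < 0.
    """
    neg = x < 0
    down = np.flatnonzero(~neg[:-1] & neg[1:]) + 1  # first negative sample
    up = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1  # first non-negative sample
    waves: list[SSOWave] = []
    lo, hi = duration_bounds
    for i in down:
        j_idx = np.searchsorted(up, i)
        if j_idx >= len(up):
            break
        j = up[j_idx]
        sep = (j - i) / sfreq
        if not (lo <= sep <= hi):
            continue
        negseg = x[i:j]
        ipeak = i + int(np.argmin(negseg))
        # positive half-wave: up to the next negative-going crossing (or end)
        k_idx = np.searchsorted(down, j)
        k = down[k_idx] if k_idx < len(down) else len(x)
        if k <= j:
            continue
        posseg = x[j:k]
        ppeak = j + int(np.argmax(posseg))
        waves.append(
            SSOWave(
                channel=channel,
                t_zc1=t0 + i / sfreq,
                t_negpeak=t0 + ipeak / sfreq,
                t_zc2=t0 + j / sfreq,
                t_pospeak=t0 + ppeak / sfreq,
                neg_amp=float(x[ipeak]),
                pos_amp=float(x[ppeak]),
                full_fledged=False,
            )
        )
    return waves


def detect_candidate_waves(
    signal: np.ndarray,
    sfreq: float,
    segments: Sequence[Segment] | None = None,
    channel: str = "ch",
    duration_bounds: tuple[float, float] = DURATION_BOUNDS_S,
    neg_peak_max: float = NEG_PEAK_MAX_UV,
    np_amp_min: float = NP_AMP_MIN_UV,
) -> list[SSOWave]:
    """Timing-valid waves inside the NREM segments, with full-fledged flags.

    ``signal`` is one channel of the slow-band-conditioned recording.  When
    ``segments`` is None the whole trace is analysed as one segment.
    """
    x = np.asarray(signal, dtype=float)
    if segments is None:
        segments = [Segment(0.0, len(x) / sfreq, "N2")]
    waves: list[SSOWave] = []
    for seg in segments:
        i0 = int(np.ceil(seg.start * sfreq))
        i1 = min(int(np.floor(seg.end * sfreq)), len(x))
        if i1 - i0 < int(duration_bounds[0] * sfreq) + 2:
            continue
        for w in _enumerate_waves(x[i0:i1], sfreq, i0 / sfreq, channel,
                                  duration_bounds):
            w.full_fledged = (
                w.neg_amp <= neg_peak_max and w.np_amp >= np_amp_min
            )
            waves.append(w)
    return waves


def detect_fullfledged_ssos(
    signal: np.ndarray,
    sfreq: float,
    segments: Sequence[Segment] | None = None,
    channel: str = "ch",
    **kwargs,
) -> list[SSOWave]:
    """Waves passing all three printed criteria, at sample resolution."""
    return [
        w
        for w in detect_candidate_waves(signal, sfreq, segments, channel, **kwargs)
        if w.full_fledged
    ]


def cluster_sso_events(
    waves_by_channel: dict[str, list[SSOWave]],
    candidates_by_channel: dict[str, list[SSOWave]] | None = None,
    tol: float = CLUSTER_TOL_S,
    completion_neg_peak: float = COMPLETION_NEG_PEAK_UV,
    completion_np_amp: float = COMPLETION_NP_AMP_UV,
) -> list[SSOEvent]:
    """Cluster full-fledged waves into events and add completion members.

    Full-fledged waves (any channel) whose successive negative peaks are within
    ``tol`` seconds (chained linkage) form one event.  For channels without a
    full-fledged member, a timing-valid candidate wave with negative peak
    within ``tol`` of the event reference joins as a sub-threshold member if it
    clears the relaxed amplitude floor.  Channel order is irrelevant.
    """
    full = sorted(
        (w for ws in waves_by_channel.values() for w in ws if w.full_fledged),
        key=lambda w: (w.t_negpeak, w.channel),
    )
    events: list[SSOEvent] = []
    for w in full:
        if events and w.t_negpeak - events[-1].waves[-1].t_negpeak <= tol:
            events[-1].waves.append(w)
        else:
            events.append(SSOEvent(waves=[w]))
    if candidates_by_channel:
        for ev in events:
            ref = ev.ref_time
            have = ev.channels
            for ch, cands in sorted(candidates_by_channel.items()):
                if ch in have:
                    continue
                best = None
                for c in cands:
                    if c.full_fledged:
                        continue
                    if (
                        abs(c.t_negpeak - ref) <= tol
                        and c.neg_amp <= completion_neg_peak
                        and c.np_amp >= completion_np_amp
                    ):
                        if best is None or abs(c.t_negpeak - ref) < abs(
                            best.t_negpeak - ref
                        ):
                            best = c
                if best is not None:
                    ev.waves.append(best)
    return events


@dataclass
class SSOFeatureSet:
    """Per-channel SSO summary over one recording."""

    table: pd.DataFrame  # index channel; rate, rate_fullfledged, np_amp, slope_pos
    nrem_minutes: float


def characterize_sso(
    events: Sequence[SSOEvent],
    nrem_minutes: float,
    channels: Sequence[str] | None = None,
) -> SSOFeatureSet:
    """Detection rate (waves/min), mean NP amplitude, and mean slope+.

    The rate counts full-fledged plus completion waves assigned to the channel;
    a full-fledged-only rate is reported alongside.  Channels without waves get
    rate 0 and undefined (NaN) amplitude/slope.
    """
    if nrem_minutes <= 0:
        raise ValueError("NREM time must be positive")
    per_ch: dict[str, list[SSOWave]] = {}
    for ev in events:
        for w in ev.waves:
            per_ch.setdefault(w.channel, []).append(w)
    if channels is None:
        channels = sorted(per_ch)
    rows = {}
    for ch in channels:
        ws = per_ch.get(ch, [])
        ff = [w for w in ws if w.full_fledged]
        rows[ch] = {
            "rate": len(ws) / nrem_minutes,
            "rate_fullfledged": len(ff) / nrem_minutes,
            "np_amp": float(np.mean([w.np_amp for w in ws])) if ws else np.nan,
            "slope_pos": float(np.mean([w.slope_pos for w in ws])) if ws else np.nan,
            "n_waves": len(ws),
        }
    return SSOFeatureSet(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        nrem_minutes=nrem_minutes,
    )


def pre_sso_sigma(
    rec: EEGRecording,
    events: Sequence[SSOEvent],
    band: tuple[float, float] = (9.0, 15.0),
    window_s: float = 1.0,
    anchor: str = "zc1",
) -> tuple[pd.Series, int]:
    """Sigma power (dB) in the 1 s window preceding each wave, per channel.

    The window ends at the wave's first zero crossing (``anchor='zc1'``) or at
    its negative peak (``anchor='negpeak'``).  Waves starting less than one
    window from the recording onset are skipped and counted.  Returns the
    per-channel mean (NaN where no usable wave) and the skip count.
    """
    if anchor not in ("zc1", "negpeak"):
        raise ValueError("anchor must be 'zc1' or 'negpeak'")
    n = int(round(window_s * rec.sfreq))
    w = sps.get_window("hamming", n)
    freqs = np.fft.rfftfreq(n, 1.0 / rec.sfreq)
    sel = band_bins(freqs, *band)
    scale = 2.0 / (rec.sfreq * np.sum(w**2))
    vals: dict[str, list[float]] = {ch: [] for ch in rec.ch_names}
    skipped = 0
    for ev in events:
        for wave in ev.waves:
            t_end = wave.t_zc1 if anchor == "zc1" else wave.t_negpeak
            i1 = int(round(t_end * rec.sfreq))
            i0 = i1 - n
            if i0 < 0:
                skipped += 1
                continue
            seg = rec.channel(wave.channel)[i0:i1]
            spec = np.fft.rfft((seg - seg.mean()) * w)
            p = np.abs(spec) ** 2 * scale
            p[0] /= 2.0
            if n % 2 == 0:
                p[-1] /= 2.0
            db = 10.0 * np.log10(np.maximum(p[sel], 1e-12))
            vals[wave.channel].append(float(db.mean()))
    out = pd.Series(
        {ch: (float(np.mean(v)) if v else np.nan) for ch, v in vals.items()},
        name="pre_sso_sigma_db",
    )
    return out, skipped


def waves_to_frame(events: Sequence[SSOEvent]) -> pd.DataFrame:
    """Tidy event table (one row per member wave)."""
    rows = []
    for k, ev in enumerate(events):
        for w in ev.waves:
            rows.append(
                {
                    "event_id": k,
                    "channel": w.channel,
                    "t_zc1": w.t_zc1,
                    "t_negpeak": w.t_negpeak,
                    "t_zc2": w.t_zc2,
                    "t_pospeak": w.t_pospeak,
                    "neg_amp": w.neg_amp,
                    "np_amp": w.np_amp,
                    "slope_pos": w.slope_pos,
                    "full_fledged": w.full_fledged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "channel", "t_zc1", "t_negpeak", "t_zc2", "t_pospeak",
            "neg_amp", "np_amp", "slope_pos", "full_fledged",
        ],
    )
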