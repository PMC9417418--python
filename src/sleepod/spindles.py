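"""Sleep spindle detection via the envelope-distance amplitude signal.

The recording is band-pass filtered to 12-16 Hz (at least 20 dB down at 11
and 17 Hz).  The upper and lower envelopes of the filtered trace are
interpolated through its local extrema (shape-preserving piecewise cubic) and
their point-by-point distance is the non-negative *amplitude signal*.  For
each NREM period the amplitude signal yields mean + 2*SD; the per-channel
threshold theta is the period-length-weighted average of those values, and
spindles are the fluctuations of the amplitude signal exceeding
``multiplier * theta`` (multiplier 2 by default, exposed because the
composition of the two factors of two is a known ambiguity of this detector
family), merged across sub-250 ms gaps and kept when 0.3-3.0 s long.

Per-channel measures: density (events per minute of artifact-free NREM) and
spindle power (mean over events of the 12-16 Hz power of the event, dB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .preproc import EEGRecording, Segment

SIGMA_BAND = (12.0, 16.0)
STOP_BAND = (11.0, 17.0)
DEFAULT_MULTIPLIER = 2.0
MERGE_GAP_S = 0.25
DURATION_BOUNDS_S = (0.3, 3.0)


@lru_cache(maxsize=8)
def _sigma_sos(sfreq: float, lo: float, hi: float, stop_lo: float,
               stop_hi: float) -> np.ndarray:
    # Elliptic design; forward-backward application doubles both the passband
    # ripple and the stopband attenuation, so design at half the target specs.
    n, wn = sps.ellipord([lo, hi], [stop_lo, stop_hi], gpass=0.4, gstop=13.0,
                         fs=sfreq)
    return sps.ellip(n, 0.4, 13.0, wn, btype="bandpass", output="sos", fs=sfreq)


def sigma_bandpass(
    rec: EEGRecording,
    band: tuple[float, float] = SIGMA_BAND,
    stopband: tuple[float, float] = STOP_BAND,
) -> EEGRecording:
    """Zero-phase 12-16 Hz band-pass (>= 20 dB attenuation at 11 and 17 Hz)."""
    if rec.sfreq < 100:
        raise ValueError("sigma filtering needs a sampling rate >= 100 Hz")
    sos = _sigma_sos(rec.sfreq, band[0], band[1], stopband[0], stopband[1])
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=-1)
    return out


def amplitude_signal(filtered: np.ndarray) -> np.ndarray:
    """Upper-minus-lower envelope distance of a sigma-band trace.

    The upper (lower) envelope interpolates successive local maxima (minima)
    with a shape-preserving cubic; the first and last samples anchor both
    envelopes.  The distance is clipped at zero; a trace without interior
    extrema yields an identically-zero amplitude signal.
    """
    x = np.asarray(filtered, dtype=float)
    n = len(x)
    if n < 3:
        return np.zeros(n)

    def _envelope(sign: float) -> np.ndarray:
        pk, _ = sps.find_peaks(sign * x)
        if len(pk) == 0:
            return x.copy()
        knots = np.concatenate(([0], pk, [n - 1]))
        return PchipInterpolator(knots, x[knots])(np.arange(n))

    upper = _envelope(1.0)
    lower = _envelope(-1.0)
    return np.clip(upper - lower, 0.0, None)


@dataclass
class ChannelThreshold:
    """Adaptive per-channel detection level with per-period provenance."""

    channel: str
    theta: float
    periods: list[tuple[float, float, float]] = field(default_factory=list)
    # (length_s, mean_uV, sd_uV) per NREM period


def spindle_threshold(
    amp: np.ndarray,
    sfreq: float,
    segments: Sequence[Segment],
    channel: str = "ch",
    min_period_s: float = 30.0,
) -> ChannelThreshold:
    """Length-weighted mean of per-period (mean + 2*SD) of the amplitude signal."""
    comps: list[tuple[float, float, float]] = []
    num = 0.0
    den = 0.0
    for seg in segments:
        i0 = int(np.ceil(seg.start * sfreq))
        i1 = min(int(np.floor(seg.end * sfreq)), len(amp))
        if i1 <= i0:
            continue
        a = amp[i0:i1]
        length = (i1 - i0) / sfreq
        m, sd = float(a.mean()), float(a.std())
        comps.append((length, m, sd))
        num += length * (m + 2.0 * sd)
        den += length
    if den == 0:
        raise ValueError("no usable NREM period for thresholding")
    if max(c[0] for c in comps) < min_period_s:
        import warnings

        warnings.warn(
            f"longest NREM period {max(c[0] for c in comps):.0f} s < "
            f"{min_period_s:.0f} s; threshold may be unstable"
        )
    return ChannelThreshold(channel=channel, theta=num / den, periods=comps)


@dataclass
class SpindleEvent:
    channel: str
    onset: float
    offset: float
    peak_amp: float
    sigma_power_db: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_spindles(
    amp: np.ndarray,
    filtered: np.ndarray,
    threshold: ChannelThreshold,
    sfreq: float,
    segments: Sequence[Segment] | None = None,
    multiplier: float = DEFAULT_MULTIPLIER,
    merge_gap: float = MERGE_GAP_S,
    duration_bounds: tuple[float, float] = DURATION_BOUNDS_S,
) -> list[SpindleEvent]:
    """Threshold the amplitude signal, merge close runs, filter by duration.

    The event sigma power is the mean power of the (already 12-16 Hz
    band-limited) filtered trace over the event interval, in dB.
    """
    amp = np.asarray(amp, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if segments is None:
        segments = [Segment(0.0, len(amp) / sfreq, "N2")]
    level = multiplier * threshold.theta
    lo, hi = duration_bounds
    events: list[SpindleEvent] = []
    for seg in segments:
        i0 = int(np.ceil(seg.start * sfreq))
        i1 = min(int(np.floor(seg.end * sfreq)), len(amp))
        if i1 <= i0:
            continue
        above = amp[i0:i1] > level
        if not above.any():
            continue
        runs = _runs(above)
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if (s - merged[-1][1]) / sfreq < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            dur = (e - s) / sfreq
            if not (lo <= dur <= hi):
                continue
            a, b = i0 + s, i0 + e
            power = float(np.mean(filtered[a:b] ** 2))
            events.append(
                SpindleEvent(
                    channel=threshold.channel,
                    onset=a / sfreq,
                    offset=b / sfreq,
                    peak_amp=float(amp[a:b].max()),
                    sigma_power_db=10.0 * np.log10(max(power, 1e-12)),
                )
            )
    return events


def spindle_metrics(
    events: Sequence[SpindleEvent], nrem_minutes: float
) -> tuple[float, float]:
    """(density events/min, mean spindle power dB); power NaN without events."""
    if nrem_minutes <= 0:
        raise ValueError("NREM time must be positive")
    density = len(events) / nrem_minutes
    power = (
        float(np.mean([e.sigma_power_db for e in events])) if events else float("nan")
    )
    return density, power


def events_to_frame(events: Sequence[SpindleEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": e.channel,
                "onset_s": e.onset,
                "offset_s": e.offset,
                "duration_s": e.duration,
                "peak_amp": e.peak_amp,
                "sigma_power_db": e.sigma_power_db,
            }
            for e in events
        ],
        columns=["channel", "onset_s", "offset_s", "duration_s", "peak_amp",
                 "sigma_power_db"],
    )
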