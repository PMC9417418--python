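"""Binocular-rivalry timelines, mean phase durations, and the deprivation index.

During binocular rivalry the observer continuously reports which of two
incompatible monocular stimuli dominates (or a mixed percept).  The mean
phase duration (MPD, seconds) of each eye indexes its perceptual strength.
Short-term monocular deprivation boosts the deprived eye; the deprivation
index quantifies the shift relative to a baseline measurement:

    DI = (MPD_dep_base / MPD_dep_post) * (MPD_ndep_post / MPD_ndep_base)

DI = 1 means no change; DI < 1 means the deprived (previously dominant) eye
is boosted.  Phases truncated by the end of a block are censored and excluded
from MPDs; mixed phases are tallied separately and never enter eye MPDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

DEPRIVED = "deprived_eye"
NONDEPRIVED = "nondeprived_eye"
MIXED = "mixed"
PERCEPTS = (DEPRIVED, NONDEPRIVED, MIXED)

#: morning-awakening block bins, minutes since patch removal (inclusive edges)
MORNING_BINS: dict[str, tuple[float, float]] = {
    "0-8": (0.0, 8.0),
    "10-18": (10.0, 18.0),
    "30": (30.0, 30.0),
}

#: extended bins for the circadian control sessions
CONTROL_BINS: dict[str, tuple[float, float]] = {
    "0-8": (0.0, 8.0),
    "10-18": (10.0, 18.0),
    "30-48": (30.0, 48.0),
    "60-93": (60.0, 93.0),
    "120-123": (120.0, 123.0),
}


@dataclass
class RivalryEvent:
    percept: str
    onset: float
    offset: float
    truncated: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class RivalryTimeline:
    """Ordered percept record of one 3-minute rivalry block."""

    events: list[RivalryEvent]
    block_len: float = 180.0
    block_id: str = ""
    minutes_after: float | None = None  # acquisition minute for morning binning
    eye_map: Mapping[str, str] | None = None  # e.g. {"deprived_eye": "cw"}

    def __post_init__(self) -> None:
        prev_end = 0.0
        for ev in self.events:
            if ev.percept not in PERCEPTS:
                raise ValueError(f"unknown percept {ev.percept!r}")
            if ev.offset <= ev.onset:
                raise ValueError(f"non-positive phase at t={ev.onset}")
            if ev.onset < prev_end - 1e-9 or ev.offset > self.block_len + 1e-9:
                raise ValueError("events must be ordered, non-overlapping, in-block")
            prev_end = ev.offset


@dataclass
class PhaseStats:
    """Pooled mean phase duration, total dominance time, and count per percept."""

    mpd: dict[str, float]
    total: dict[str, float]
    count: dict[str, int]
    undefined: list[str] = field(default_factory=list)

    def require(self, percept: str, label: str) -> float:
        v = self.mpd.get(percept, float("nan"))
        if percept in self.undefined or not v > 0:
            raise ValueError(f"MPD of {percept!r} undefined for {label}")
        return v


@dataclass
class DeprivationIndex:
    value: float
    timepoint: str = ""


def compute_phase_stats(
    timelines: Sequence[RivalryTimeline], include_truncated: bool = False
) -> PhaseStats:
    """Pool phase durations across blocks and average per percept.

    Durations are pooled before averaging (not a mean of per-block means).
    Truncated (block-end-censored) phases are excluded from MPDs by default
    but always counted in the total dominance time.
    """
    if not timelines:
        raise ValueError("at least one rivalry block required")
    if all(not tl.events for tl in timelines):
        raise ValueError("rivalry blocks contain no percept events")
    durs: dict[str, list[float]] = {p: [] for p in PERCEPTS}
    total = {p: 0.0 for p in PERCEPTS}
    for tl in timelines:
        for ev in tl.events:
            total[ev.percept] += ev.duration
            if include_truncated or not ev.truncated:
                durs[ev.percept].append(ev.duration)
    mpd = {}
    count = {}
    undefined = []
    for p in PERCEPTS:
        count[p] = len(durs[p])
        if durs[p]:
            mpd[p] = sum(durs[p]) / len(durs[p])
        else:
            mpd[p] = float("nan")
            undefined.append(p)
    return PhaseStats(mpd=mpd, total=total, count=count, undefined=undefined)


def compute_deprivation_index(
    base: PhaseStats, post: PhaseStats, timepoint: str = ""
) -> DeprivationIndex:
    """Ratio-of-ratios deprivation index from baseline and post phase stats."""
    b_dep = base.require(DEPRIVED, "baseline")
    p_dep = post.require(DEPRIVED, "post")
    b_nd = base.require(NONDEPRIVED, "baseline")
    p_nd = post.require(NONDEPRIVED, "post")
    value = (b_dep / p_dep) * (p_nd / b_nd)
    return DeprivationIndex(value=value, timepoint=timepoint)


def bin_morning_blocks(
    blocks: Sequence[RivalryTimeline],
    bins: Mapping[str, tuple[float, float]] | None = None,
    include_truncated: bool = False,
) -> dict[str, PhaseStats]:
    """Pool morning blocks into acquisition-minute bins.

    Each block must carry ``minutes_after``; blocks outside every bin are
    excluded with a warning.  Bins without any block are omitted.
    """
    bins = dict(bins) if bins is not None else dict(MORNING_BINS)
    assigned: dict[str, list[RivalryTimeline]] = {name: [] for name in bins}
    for tl in blocks:
        if tl.minutes_after is None:
            raise ValueError(f"block {tl.block_id!r} lacks an acquisition minute")
        hit = None
        for name, (lo, hi) in bins.items():
            if lo <= tl.minutes_after <= hi:
                hit = name
                break
        if hit is None:
            warnings.warn(
                f"block {tl.block_id!r} at {tl.minutes_after} min falls outside "
                f"all bins and is excluded"
            )
            continue
        assigned[hit].append(tl)
    return {
        name: compute_phase_stats(tls, include_truncated)
        for name, tls in assigned.items()
        if tls
    }
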