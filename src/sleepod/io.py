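"""Readers and writers for the supported on-disk formats.

EEG travels either as EDF (read via :mod:`mne`, imported lazily) or as a
matrix container with a JSON sidecar: ``.npz`` (key ``data``, channels x
samples) or a plain ``.csv`` (one row per channel).  The sidecar
``<stem>.json`` holds ``ch_names``, ``sfreq``, ``reference`` and ``units``
("uV"); a mismatch between matrix and sidecar is an error, and unit
ambiguity is never resolved by silent rescaling.

Hypnograms are two-column TSVs (epoch index, stage), artifact masks CSVs
(start_s, end_s, reason), rivalry blocks CSVs (percept, onset_s, offset_s)
with a JSON sidecar (block id, acquisition minute, eye mapping), and ground
truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preproc import ArtifactInterval, ArtifactMask, EEGRecording, Hypnogram
from .rivalry import RivalryEvent, RivalryTimeline
from .synthetic import GroundTruth, TrueSSO, TrueSpindle


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as .npz or .csv plus its JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, data=rec.data)
    elif path.suffix == ".csv":
        np.savetxt(path, rec.data, delimiter=",")
    else:
        raise ValueError(f"unsupported EEG output format {path.suffix!r}")
    sidecar = {
        "ch_names": rec.ch_names,
        "sfreq": rec.sfreq,
        "reference": rec.reference,
        "units": "uV",
        "n_samples": rec.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_eeg(path: str | Path) -> EEGRecording:
    """Read EDF (via mne) or a matrix + JSON sidecar; channels in uV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        # mne returns volts; EDF physical dimensions are checked upstream
        return EEGRecording(
            data=raw.get_data() * 1e6,
            ch_names=list(raw.ch_names),
            sfreq=float(raw.info["sfreq"]),
            reference="as-recorded",
        )
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    if meta.get("units") != "uV":
        raise ValueError(
            f"ambiguous units {meta.get('units')!r} in {sidecar_file}; expected 'uV'"
        )
    if path.suffix == ".npz":
        try:
            data = np.load(path)["data"]
        except Exception as err:
            raise IOError(f"corrupt or truncated matrix file {path}: {err}") from err
    elif path.suffix == ".csv":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r}")
    if data.shape[0] != len(meta["ch_names"]) or (
        "n_samples" in meta and data.shape[1] != meta["n_samples"]
    ):
        raise ValueError(
            f"matrix shape {data.shape} does not match sidecar {sidecar_file}"
        )
    return EEGRecording(
        data=data,
        ch_names=list(meta["ch_names"]),
        sfreq=float(meta["sfreq"]),
        reference=meta.get("reference", "unknown"),
    )


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# epoch_len={hyp.epoch_len} lights_off_epoch={hyp.lights_off_epoch}"]
    lines += [f"{i}\t{s}" for i, s in enumerate(hyp.stages)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    path = Path(path)
    epoch_len, lights_off = 30.0, 0
    stages: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                key, _, val = tok.partition("=")
                if key == "epoch_len":
                    epoch_len = float(val)
                elif key == "lights_off_epoch":
                    lights_off = int(val)
            continue
        _, _, stage = line.partition("\t")
        stages.append(stage.strip())
    return Hypnogram(stages=stages, epoch_len=epoch_len, lights_off_epoch=lights_off)


def write_mask(mask: ArtifactMask, path: str | Path) -> Path:
    pd.DataFrame(
        [{"start_s": iv.start, "end_s": iv.end, "reason": iv.reason}
         for iv in mask.intervals],
        columns=["start_s", "end_s", "reason"],
    ).to_csv(path, index=False)
    return Path(path)


def read_mask(path: str | Path) -> ArtifactMask:
    df = pd.read_csv(path)
    return ArtifactMask(
        intervals=[
            ArtifactInterval(float(r.start_s), float(r.end_s), str(r.reason))
            for r in df.itertuples()
        ]
    )


def write_rivalry(tl: RivalryTimeline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"percept": e.percept, "onset_s": e.onset, "offset_s": e.offset,
             "truncated": int(e.truncated)}
            for e in tl.events
        ]
    ).to_csv(path, index=False)
    sidecar = {
        "block_id": tl.block_id,
        "block_len": tl.block_len,
        "minutes_after": tl.minutes_after,
        "eye_map": dict(tl.eye_map) if tl.eye_map else None,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_rivalry(path: str | Path) -> RivalryTimeline:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    if _sidecar_path(path).exists():
        meta = json.loads(_sidecar_path(path).read_text())
    events = [
        RivalryEvent(
            percept=str(r.percept),
            onset=float(r.onset_s),
            offset=float(r.offset_s),
            truncated=bool(getattr(r, "truncated", 0)),
        )
        for r in df.itertuples()
    ]
    return RivalryTimeline(
        events=events,
        block_len=float(meta.get("block_len", 180.0)),
        block_id=str(meta.get("block_id", path.stem)),
        minutes_after=meta.get("minutes_after"),
        eye_map=meta.get("eye_map"),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    payload = {
        "sso_events": [dataclasses.asdict(e) for e in truth.sso_events],
        "spindle_events": [dataclasses.asdict(e) for e in truth.spindle_events],
        "cohort_params": truth.cohort_params,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        sso_events=[TrueSSO(**e) for e in payload.get("sso_events", [])],
        spindle_events=[TrueSpindle(**e) for e in payload.get("spindle_events", [])],
        cohort_params=payload.get("cohort_params", {}),
    )
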