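#!/usr/bin/env python
"""Run the full detection pipeline on the simulated night and score it.

Reads the recording written by 01_simulate_night.py, runs preprocessing,
band power, slow-oscillation and spindle detection, writes the event and
feature tables under results/night/, and scores both detectors against the
injected ground truth (one-to-one matching within 0.25 s).
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from sleepod import io as sio
from sleepod.pipeline import PipelineConfig, run_pipeline
from sleepod.synthetic import match_events, recall_precision


def main() -> None:
    night = ROOT / "results" / "night"
    eeg = ROOT / "scratch" / "night" / "eeg.npz"
    if not eeg.exists():
        sys.exit("run 01_simulate_night.py first")

    cfg = PipelineConfig(
        eeg_path=str(eeg),
        hypnogram_path=str(night / "hypnogram.tsv"),
        mask_path=str(night / "mask.csv"),
        out_dir=str(night / "pipeline"),
    )
    out = run_pipeline(cfg)
    truth = sio.read_ground_truth(night / "ground_truth.json")

    sso = pd.read_csv(out / "sso_events.csv")
    sso_ff = sso[sso.full_fledged]
    h = m = f = hs = ms = fs = 0
    spn = pd.read_csv(out / "spindle_events.csv")
    for ch in sorted({e.channel for e in truth.sso_events}):
        det = sso_ff[sso_ff.channel == ch].t_negpeak.tolist()
        tt = [e.t_negpeak for e in truth.sso_events if e.channel == ch]
        a, b, c = match_events(tt, det)
        h, m, f = h + a, m + b, f + c
        dsp = spn[spn.channel == ch]
        mids = ((dsp.onset_s + dsp.offset_s) / 2).tolist()
        tm = [(e.onset + e.offset) / 2 for e in truth.spindle_events
              if e.channel == ch]
        a, b, c = match_events(tm, mids)
        hs, ms, fs = hs + a, ms + b, fs + c

    r1, p1 = recall_precision(h, m, f)
    r2, p2 = recall_precision(hs, ms, fs)
    summary = pd.DataFrame(
        [
            {"detector": "sso", "recall": r1, "precision": p1,
             "n_true": h + m, "n_detected": h + f},
            {"detector": "spindle", "recall": r2, "precision": p2,
             "n_true": hs + ms, "n_detected": hs + fs},
        ]
    )
    summary.to_csv(night / "detection_scores.csv", index=False)
    print(summary.round(4).to_string(index=False))
    print(f"event/feature tables -> {out}")


if __name__ == "__main__":
    main()
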