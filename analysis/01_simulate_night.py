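#!/usr/bin/env python
"""Simulate one synthetic NREM night and write it to disk.

Generates an 8-channel, 10-minute NREM recording (1/f background, embedded
slow oscillations and spindles at study-scale amplitudes, noise RMS 20 uV),
and stores the recording (NPZ + JSON sidecar, under scratch/ because the
matrix is binary), the hypnogram, artifact mask, and the injected-event
ground truth (under results/).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from sleepod import io as sio
from sleepod.synthetic import SimulationSpec, generate_nrem_eeg


def main(seed: int = 1) -> None:
    out = ROOT / "results" / "night"
    scratch = ROOT / "scratch" / "night"
    out.mkdir(parents=True, exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    spec = SimulationSpec(duration=600.0, n_channels=8, noise_rms=20.0,
                          seed=seed)
    rec, hyp, mask, truth = generate_nrem_eeg(spec)
    sio.write_eeg(rec, scratch / "eeg.npz")
    sio.write_hypnogram(hyp, out / "hypnogram.tsv")
    sio.write_mask(mask, out / "mask.csv")
    sio.write_ground_truth(truth, out / "ground_truth.json")
    print(
        f"wrote {rec.n_channels}-channel, {rec.duration:.0f} s recording: "
        f"{len(truth.sso_events)} slow oscillations and "
        f"{len(truth.spindle_events)} spindles injected "
        f"({spec.sso_rate_per_min:.0f}/min and "
        f"{spec.spindle_rate_per_min:.0f}/min per channel)"
    )
    print(f"EEG -> {scratch / 'eeg.npz'}; annotations -> {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
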