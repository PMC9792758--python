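#!/usr/bin/env python
"""Preprocess the exported recording through the study's signal chain.

Reads scratch/sub00_RG.edf (written by 01_simulate.py), applies 50 Hz notch,
30 Hz FIR low-pass, 1000 -> 200 Hz resampling, epoch extraction with
baseline removal, and +/-100 uV artifact rejection, then reports the epoch
bookkeeping.

Writes: results/preprocess_summary.json
"""

import json
from pathlib import Path

from vepsource.pipeline import preprocess_recording
from vepsource.simulate import read_recording

OUT = Path("results")


def main() -> None:
    rec = read_recording(Path("scratch") / "sub00_RG.edf")
    epochs, report = preprocess_recording(rec)
    labels = list(epochs.labels)
    summary = {
        "fs_hz": epochs.fs,
        "n_epochs_kept": epochs.n_epochs,
        "n_epochs_rejected": len(report.removed),
        "samples_per_epoch": int(epochs.data.shape[2]),
        "per_color_counts": {c: labels.count(c) for c in sorted(set(labels))},
        "rejected_indices": list(report.removed),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "preprocess_summary.json").write_text(
        json.dumps(summary, indent=1))
    print(json.dumps(summary))


if __name__ == "__main__":
    main()
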