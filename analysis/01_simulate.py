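#!/usr/bin/env python
"""Simulate the synthetic color-VEP study and export one subject's recording.

Generates the default paradigm (three color-pair teams, 3 trials x 70
one-second epochs, 59 channels at 1000 Hz) for a configurable number of
subjects, reports the design bookkeeping, and writes subject 0's RG-team
recording as EDF + events TSV so downstream scripts (and external tools)
can read it back.

Writes: results/design_summary.json, scratch/sub00_RG.edf(.events.tsv)
"""

import json
from pathlib import Path

from vepsource.pipeline import stage_seed
from vepsource.simulate import (Paradigm, count_design, simulate_subject,
                                write_recording)

SEED = 1
OUT = Path("results")
SCRATCH = Path("scratch")


def main() -> None:
    par = Paradigm()
    design = count_design(par)
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    summary = {
        "epochs_per_trial": design.epochs_per_trial,
        "epochs_per_team": design.epochs_per_team,
        "epochs_per_subject": design.epochs_per_subject,
        "stimulus_ms_per_team": design.team_ms,
        "stimulus_ms_per_subject": design.subject_ms,
        "train_per_repeat": design.train_per_repeat,
        "test_per_repeat": design.test_per_repeat,
    }
    (OUT / "design_summary.json").write_text(json.dumps(summary, indent=1))
    print("design summary:", json.dumps(summary))

    rec = simulate_subject(par, "RG",
                           seed=stage_seed(SEED, "simulate", 0, "RG"))
    path = SCRATCH / "sub00_RG.edf"
    write_recording(rec, path)
    print(f"subject 0, team RG: {len(rec.events)} events, "
          f"{rec.n_samples / rec.fs:.0f} s at {rec.fs:.0f} Hz -> {path}")


if __name__ == "__main__":
    main()
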