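#!/usr/bin/env python
"""Channel-wise decoding topography, region comparison, and ROC analysis.

Simulates N_SUBJECTS subjects of the RG team, decodes every channel with the
linear SVM over repeated stratified 80/20 splits, and reports: the accuracy
topography, the V1-vs-other rank-sum comparison, and the ROC over all
subject x channel points with POz-O2 as the positive state.

Writes: results/accuracy_RG.tsv, results/roc_RG.json,
        results/region_comparison_RG.json
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from vepsource.decode import (build_accuracy_map, compare_regions,
                              roc_over_channels)
from vepsource.montage import build_standard_montage
from vepsource.pipeline import preprocess_recording, stage_seed
from vepsource.simulate import Paradigm, simulate_subject

SEED = 1
N_SUBJECTS = 6          # desk-scale subset of the 20-subject design
N_REPEATS = 10
OUT = Path("results")


def main() -> None:
    montage = build_standard_montage()
    par = Paradigm()
    epoch_sets = []
    for subject in range(N_SUBJECTS):
        rec = simulate_subject(
            par, "RG", montage=montage, subject=subject,
            seed=stage_seed(SEED, "simulate", subject, "RG"))
        epochs, _ = preprocess_recording(rec)
        epoch_sets.append(epochs)
        print(f"subject {subject}: {epochs.n_epochs} epochs")

    amap = build_accuracy_map(epoch_sets, classifier="svm",
                              n_repeats=N_REPEATS,
                              seed=stage_seed(SEED, "decode", team="RG"),
                              pair="RG")
    OUT.mkdir(exist_ok=True)
    lines = ["subject\tchannel_code\tchannel_name\taccuracy"]
    for s in range(N_SUBJECTS):
        for c in range(59):
            lines.append(f"{s}\t{c + 1}\t{montage.names[c]}"
                         f"\t{amap.accuracy[s, c]:.4f}")
    (OUT / "accuracy_RG.tsv").write_text("\n".join(lines) + "\n")

    cmp_res = compare_regions(amap, montage)
    roc = roc_over_channels(amap)
    (OUT / "region_comparison_RG.json").write_text(
        json.dumps(asdict(cmp_res), indent=1))
    (OUT / "roc_RG.json").write_text(json.dumps(asdict(roc), indent=1))

    mean = amap.accuracy.mean(axis=0)
    top = np.argsort(-mean)[:5]
    print("top channels:", [(montage.names[i], round(float(mean[i]), 3))
                            for i in top])
    print(f"V1 median {cmp_res.median_posterior:.3f} vs other "
          f"{cmp_res.median_other:.3f}, rank-sum p={cmp_res.p_value:.2e}")
    print(f"ROC: AUC {roc.auc:.3f} +/- {roc.std_error:.3f}, "
          f"n_pos {roc.n_positive}, n_neg {roc.n_negative}")


if __name__ == "__main__":
    main()
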