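#!/usr/bin/env python
"""ERP latency statistics and the decoding-vs-VEP-power spatial correlation.

Simulates subjects across all three teams, detects the first-peak latency of
every V1 channel's color-averaged ERP, summarizes the per-color quartiles
(the study's latency box statistics), computes the 0-30 Hz VEP power
topography, and correlates it with the decoding accuracy topography from
03_decode.py (re-derived here per subject).

Writes: results/latency_stats.json, results/latencies.tsv,
        results/power_RG.tsv, results/accuracy_power_correlation.json
"""

import json
from pathlib import Path

from vepsource.decode import build_accuracy_map
from vepsource.erp import (collect_latencies, latency_statistics,
                           spatial_correlation, vep_power_map)
from vepsource.montage import build_standard_montage, region_codes
from vepsource.pipeline import preprocess_recording, stage_seed
from vepsource.simulate import Paradigm, simulate_subject

SEED = 1
N_SUBJECTS = 3
OUT = Path("results")


def main() -> None:
    montage = build_standard_montage()
    par = Paradigm()
    v1 = region_codes(montage, "posterior_v1")
    samples = []
    rg_sets = []
    for team in ("RG", "RB", "GB"):
        for subject in range(N_SUBJECTS):
            rec = simulate_subject(
                par, team, montage=montage, subject=subject,
                seed=stage_seed(SEED, "simulate", subject, team))
            epochs, _ = preprocess_recording(rec)
            samples.extend(collect_latencies(epochs, v1))
            if team == "RG":
                rg_sets.append(epochs)

    OUT.mkdir(exist_ok=True)
    lines = ["subject\tcolor\tchannel_code\tlatency_ms"]
    lines += [f"{s.subject}\t{s.color}\t{s.channel_code}\t{s.latency_ms:.1f}"
              for s in samples]
    (OUT / "latencies.tsv").write_text("\n".join(lines) + "\n")

    stats = {}
    for color in ("red", "green", "blue"):
        lat = [s.latency_ms for s in samples if s.color == color]
        st = latency_statistics(color, lat)
        stats[color] = {"q25": st.lower_quartile_ms, "median": st.median_ms,
                        "q75": st.upper_quartile_ms, "mean": st.mean_ms,
                        "n": len(lat)}
        print(f"{color}: median {st.median_ms:.0f} ms, quartiles "
              f"({st.lower_quartile_ms:.0f}, {st.upper_quartile_ms:.0f}), "
              f"mean {st.mean_ms:.1f} ms, n={len(lat)}")
    (OUT / "latency_stats.json").write_text(json.dumps(stats, indent=1))

    amap = build_accuracy_map(rg_sets, classifier="svm", n_repeats=10,
                              seed=stage_seed(SEED, "decode", team="RG"),
                              pair="RG")
    correlations = []
    for s, epochs in enumerate(rg_sets):
        pmap = vep_power_map(epochs)
        r, p = spatial_correlation(amap.accuracy[s], pmap)
        correlations.append({"subject": s, "r": r, "p": p})
        print(f"subject {s}: accuracy~power r={r:.3f}, p={p:.2e}")
    (OUT / "accuracy_power_correlation.json").write_text(
        json.dumps(correlations, indent=1))

    pmap = vep_power_map(rg_sets[0])
    power_lines = ["channel_code\tpower"]
    power_lines += [f"{c + 1}\t{pmap.power[c]:.6g}" for c in range(59)]
    (OUT / "power_RG.tsv").write_text("\n".join(power_lines) + "\n")


if __name__ == "__main__":
    main()
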