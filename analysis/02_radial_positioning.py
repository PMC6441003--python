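"""Erosion-shell radial positioning on the simulated FISH fields.

Segments nuclei from the DNA channel, partitions each into 5 equal-area
shells, quantifies the probe/DNA ratio per shell, aggregates per condition
and runs per-shell Welch tests between treated (peripheral bias) and control
(uniform). Writes per-nucleus profiles, condition summaries and the shell
comparison under results/fish/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibroquant import fish, io

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "fish"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = io.read_manifest(ROOT / "scratch" / "demo_fields" / "manifest.tsv")

    profiles: dict[str, list] = {}
    for _, row in manifest.iterrows():
        dna = io.read_channel(row["dna_path"])
        probe = io.read_channel(row["probe_path"])
        for nuc in fish.segment_nuclei(dna, min_area=100):
            part = fish.erode_equal_area_shells(nuc, 5)
            profiles.setdefault(row["condition"], []).append(
                fish.quantify_shells(part, dna, probe)
            )

    summary_rows = []
    for cond, profs in profiles.items():
        io.write_shell_profiles(profs, OUT / f"profiles_{cond}.tsv")
        s = fish.aggregate_condition(profs, cond, n_min=50)
        print(f"{cond}: {s.n_nuclei} nuclei, mean shell ratios "
              f"{np.round(s.mean_ratio, 2).tolist()}")
        for k in range(5):
            summary_rows.append(
                {"condition": cond, "shell": k + 1,
                 "mean_ratio": s.mean_ratio[k], "sem_ratio": s.sem_ratio[k]}
            )
    pd.DataFrame(summary_rows).to_csv(OUT / "condition_summary.tsv", sep="\t", index=False)

    cmp = fish.compare_conditions(
        np.vstack([p.ratio for p in profiles["treated"]]),
        np.vstack([p.ratio for p in profiles["control"]]),
    )
    io.write_shell_comparison(cmp, OUT / "compare_treated_vs_control.tsv")
    flagged = [k + 1 for k in range(5) if cmp.significant[k]]
    print(f"shells significantly different at alpha 0.05: {flagged} "
          f"(p = {np.format_float_scientific(cmp.p.min(), 2)} at the extremes)")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
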