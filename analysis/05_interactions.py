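#!/usr/bin/env python
"""Pairwise co-occurrence / mutual-exclusivity analysis of the called
presence matrix (hypergeometric test, BH adjustment, alpha 0.05), with the
red/blue heatmap. Checks that the planted HRd/ROS exclusivity and the
APOBEC/HRd co-occurrence are recovered from the pipeline's own presence
calls."""

from pathlib import Path

import pandas as pd

from mutsig import interaction_matrix
from mutsig.cli_report import render_interaction_heatmap
from mutsig.interactions import results_to_frame

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    profiles = pd.read_csv(OUT / "profiles.tsv", sep="\t", index_col=0)
    presence = profiles[[c for c in profiles.columns if c.startswith("present_")]].rename(
        columns=lambda c: c[len("present_"):]
    )
    results = interaction_matrix(presence, alpha=0.05, adjust="BH")
    frame = results_to_frame(results)
    frame.to_csv(OUT / "interactions.tsv", sep="\t", index=False, float_format="%.6g")
    render_interaction_heatmap(results, OUT / "interactions.png")

    def find(a, b):
        hit = frame[(frame.group_a.isin([a, b])) & (frame.group_b.isin([a, b]))]
        return hit.iloc[0] if len(hit) else None

    called = frame[frame.direction.isin(["co-occurring", "exclusive"])]
    print(f"{len(called)} of {len(frame)} pairs called at q <= 0.05:")
    print(called[["group_a", "group_b", "k", "q", "direction"]].to_string(index=False))
    hrd_ros = find("HRd", "ROS")
    apo_hrd = find("APOBEC", "HRd")
    print(f"\nplanted HRd/ROS exclusivity recovered: {hrd_ros is not None and hrd_ros.direction == 'exclusive'}")
    print(f"planted APOBEC/HRd co-occurrence recovered: {apo_hrd is not None and apo_hrd.direction == 'co-occurring'}")


if __name__ == "__main__":
    main()
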