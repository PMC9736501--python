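#!/usr/bin/env python
"""Group-level statistical analysis (GLSA): mixed-effects activation maps.

Reads the subject-level contrast table, fits the per-channel cell-means linear
mixed-effects model (random intercept per subject) and writes the per-group
activation maps and the early-vs-moderate contrast maps to
results/study/group_maps.tsv. Prints the region-level summary of the
contralateral sensorimotor responses and the group contrasts.
"""

import argparse
from pathlib import Path

import pandas as pd

from graspnirs.io import write_result_table
from graspnirs.pipeline import glsa
from graspnirs.roi import roi_average
from graspnirs.simulate import SimulationParams, default_roi_config

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    betas = pd.read_csv(OUT / "subject_glm.tsv", sep="\t")
    maps = glsa(betas)
    write_result_table(OUT / "group_maps.tsv", maps)

    membership = default_roi_config(SimulationParams().n_channels).membership()
    act = maps[(maps["map"] == "group-activation") & (maps.chromophore == "hbo")
               & (maps.condition == "RG")]
    print("L-SMN right-grasp HbO2 activation (ROI-averaged t):")
    for group in ("ePD", "mPD"):
        sel = act[act.group == group].set_index("channel")
        roi_t = roi_average(sel["t"], {"L-SMN": membership["L-SMN"]})
        print(f"  {group}: t = {roi_t['mean'].iloc[0]:+.2f}")
    con = maps[(maps["map"] == "group-contrast") & (maps.chromophore == "hbo")
               & (maps.condition == "RG")].set_index("channel")
    roi_t = roi_average(con["t"], {"L-SMN": membership["L-SMN"]})
    n_sig = int((con["p"] < 0.05).sum())
    print(f"ePD-vs-mPD right-grasp HbO2 contrast: L-SMN mean t = "
          f"{roi_t['mean'].iloc[0]:+.2f}; {n_sig} channels p < 0.05 map-wide")
    print(f"wrote {OUT / 'group_maps.tsv'}")


if __name__ == "__main__":
    main()
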