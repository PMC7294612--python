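"""Signed rare-allele GRS and windowed responder classification.

Each rare-allele copy contributes +1 (risk-increasing prior association) or
−1 (protective). ΔTG = post-supplementation − post-control TG; participants
whose ΔTG stays within ±0.25 mmol/l (the mean intra-individual TG variation)
are non-responders.
"""

import pandas as pd

from n3grs import (
    classify_cohort,
    compute_grs,
    estimate_window,
    filter_hwe,
    grs_frame,
    labels_frame,
    simulate_study,
    study_like_preset,
)

config = study_like_preset(seed=3)
bundle = simulate_study(config)
matrix, profiles = bundle["genotypes"], bundle["profiles"]

panel, _ = filter_hwe(matrix, config.panel, alpha=0.05)
scores = grs_frame(compute_grs(matrix, panel))
print("GRS distribution:")
print(scores.grs.describe().round(2).to_string())

w = estimate_window(profiles)
print(f"\nestimated window from 4 off-treatment repeats: ±{w:.3f} mmol/l "
      f"(study value ±0.25)")

labels = labels_frame(classify_cohort(profiles, window=0.25), 0.25)
print("\nclass counts per treatment:")
print(labels.groupby(["treatment", "label"]).size().unstack(fill_value=0))
# R = TG fell by more than the window, AR = rose by more, NR = stayed inside.
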