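#!/usr/bin/env python
"""Step 5 — Mahalanobis placement of the hybrids.

Places every animal's mean call-parameter vector relative to the two
parent-species centroids (pooled within-parent covariance metric), flags
intermediate hybrids, names each hybrid's nearer parent, and writes the
placement scatter to results/mahalanobis.png.
"""

import pandas as pd
from _common import CONFIG, RESULTS

from volecall.pipeline import PARENT_GROUPS, plot_placement
from volecall.stats import (individual_means, intermediacy_summary,
                            mahalanobis_placement)

df = pd.read_csv(RESULTS / "measurements.csv")
parents = df[df["group"].isin(PARENT_GROUPS)]
means = individual_means(df, features=CONFIG.features)
pl = mahalanobis_placement(parents, means, PARENT_GROUPS,
                           features=CONFIG.features)
inter = intermediacy_summary(pl)

ga, gb = PARENT_GROUPS
print(f"squared Mahalanobis distances (d2_a -> {ga}, d2_b -> {gb}):")
print(pl.table.round(2).to_string(index=False))
print(f"\nhybrids intermediate on both axes: {inter.n_intermediate} of "
      f"{len(inter.per_hybrid)}")
print(f"nearer-parent counts: {inter.nearer_counts}")
print(f"majority nearer parent: {inter.majority_nearer}")

plot_placement({"_placement": pl}, RESULTS / "mahalanobis.png")
print(f"\nwrote {RESULTS / 'mahalanobis.png'}")
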