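#!/usr/bin/env python
"""Step 3 — univariate group comparisons.

One-way ANOVA with Tukey HSD on the main call parameters and the
Kruskal-Wallis + median test on peak frequency, on the measurements from
step 2.
"""

import pandas as pd
from _common import RESULTS

from volecall.pipeline import ANOVA_PARAMETERS, GROUP_ORDER
from volecall.stats import kruskal_wallis_median, one_way_anova

df = pd.read_csv(RESULTS / "measurements.csv")
names = [g for g in GROUP_ORDER if g in set(df["group"])]

print("one-way ANOVA (Tukey HSD rejections at alpha = 0.05):")
for p in ANOVA_PARAMETERS:
    samples = [df.loc[df["group"] == g, p].dropna().to_numpy() for g in names]
    if any(len(s) < 2 for s in samples):
        print(f"  {p:14s}  skipped (too few voiced calls in a group)")
        continue
    r = one_way_anova(samples, names=names)
    rej = ", ".join(f"{a}!={b}" for (a, b), v in r.posthoc.items() if v)
    print(f"  {p:14s}  F({r.df_between},{r.df_within}) = {r.F:8.2f}"
          f"  p = {r.p:.3g}   [{rej or 'none'}]")

kw = kruskal_wallis_median(
    [df.loc[df["group"] == g, "peak_hz"].to_numpy() for g in names],
    names=names)
print("\npeak frequency (nonparametric):")
print(f"  Kruskal-Wallis H = {kw.H:.2f}, p = {kw.p_kruskal:.3g}")
print(f"  median test chi2 = {kw.median_chi2:.2f}, p = {kw.p_median:.3g}, "
      f"grand median = {kw.grand_median:.0f} Hz")
for g in names:
    print(f"  median peak {g:10s} = "
          f"{df.loc[df['group'] == g, 'peak_hz'].median():7.0f} Hz")
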