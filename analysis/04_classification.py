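#!/usr/bin/env python
"""Step 4 — parent-species discriminant analysis.

Fits the two-group equal-priors linear DFA (duration, 50% quartile,
entropy) on the measured Tien Shan and bank-vole calls, reports
resubstitution and split-half cross-validated attribution, the
label-permutation chance level, and the chi-squared comparisons.
"""

import pandas as pd
from _common import CONFIG, RESULTS

from volecall.pipeline import PARENT_GROUPS
from volecall.stats import (classify, compare_proportions_chi2, fit_dfa,
                            randomization_null, split_half_cv)

df = pd.read_csv(RESULTS / "measurements.csv")
parents = df[df["group"].isin(PARENT_GROUPS)]

model = fit_dfa(parents, groups=PARENT_GROUPS, features=CONFIG.features)
resub = classify(model, parents)
cv = split_half_cv(parents, groups=PARENT_GROUPS, features=CONFIG.features,
                   seed=CONFIG.seed)
null = randomization_null(parents, groups=PARENT_GROUPS,
                          features=CONFIG.features,
                          n_reps=CONFIG.n_randomization, seed=CONFIG.seed)
n = len(parents)
chi_cv = compare_proportions_chi2(resub.percent_correct, n, cv, n - n // 2)
chi_null = compare_proportions_chi2(resub.percent_correct, n,
                                    null.mean_percent, n)

print(f"parent DFA on {list(CONFIG.features)} ({n} calls):")
print(f"  resubstitution        {resub.percent_correct:6.1f}% correct")
print(f"  split-half CV         {cv:6.1f}% correct")
print(f"  permutation null      {null.mean_percent:6.2f} +- "
      f"{null.se_percent:.2f}% ({null.n_reps} reps)")
print(f"  chi2 resub vs CV      {chi_cv[0]:6.2f}  (p = {chi_cv[1]:.3g})")
print(f"  chi2 resub vs null    {chi_null[0]:6.2f}  (p = {chi_null[1]:.3g})")
print(f"  Wilks lambda          {resub.wilks_lambda:6.3f}")
print("  partial lambdas (smaller = more discriminative):")
for f, v in sorted(resub.wilks_partial.items(), key=lambda kv: kv[1]):
    print(f"    {f:12s} {v:.3f}")
print("  confusion matrix (rows true, cols predicted):")
print(resub.confusion.to_string())
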