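"""The nested cross-validated SVM protocol on subject features.

Feature subsets are enumerated and RBF hyperparameters grid-searched inside
each outer training fold (so the held-out fold never informs selection),
repeated to give percentile confidence intervals.  Here one feature truly
separates the groups; the protocol should find it and classify near
perfectly, while permuted labels stay at chance.
"""

import numpy as np

from alphacoupling import nested_cv_classify

rng = np.random.default_rng(0)
n = 56
X = rng.normal(size=(n, 4))
y = np.array(["HC"] * (n // 2) + ["MCI"] * (n // 2))
X[y == "MCI", 0] += 8.0  # feature 0 separates the groups

kw = dict(
    c_grid=(2.0**-3, 2.0, 2.0**5),
    g_grid=(2.0**-7, 2.0**-3, 2.0),
    max_subset_size=1,
    k=10,
    reps=10,
)
rep = nested_cv_classify(X, y, seed=1, **kw)
s = rep.summary
print("separable cohort:")
for m in ("accuracy", "auc", "sensitivity", "specificity", "ppv", "npv"):
    print(f"  {m:>12}: {s.loc[m,'mean']:.3f} "
          f"(95% CI {s.loc[m,'ci_lo']:.3f}-{s.loc[m,'ci_hi']:.3f})")
picks = [s["subset"][0] for s in rep.selections]
print(f"  feature 0 selected in {np.mean(np.array(picks) == 0):.0%} "
      "of outer folds")

y_perm = rng.permutation(y)
null = nested_cv_classify(X[:, 1:], y_perm, seed=1, **kw)
print(f"\npermuted labels, noise features: accuracy "
      f"{null.summary.loc['accuracy','mean']:.3f} (chance = 0.5)")
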