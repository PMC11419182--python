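"""Quantify distribution shift between groups with the learned-feature MMD.

A shared multi-head MLP is trained to predict group membership; its trunk
embedding is the canonical feature map, and the unbiased MMD^2 statistic
with permutation p-values measures how far apart the groups sit.  Three
groups are simulated: two identically distributed, one shifted.
"""

import numpy as np

import cohortshift as cs

rng = np.random.default_rng(0)
X = np.vstack(
    [
        rng.standard_normal((150, 10)),
        rng.standard_normal((150, 10)),        # same distribution as the first
        rng.standard_normal((150, 10)) + 1.0,  # shifted by 1 sigma everywhere
    ]
)
groups = np.array(["g1"] * 150 + ["g2"] * 150 + ["g3"] * 150)

fm = cs.train_feature_map(X, {"group": groups}, epochs=120, seed=1)
report = cs.pairwise_shift(fm, X, groups, attribute="group", B=999, seed=2)

print("groups:", report.groups)
print("pairwise MMD^2 (learned features):")
print(np.round(report.mmd2, 3))
print("permutation p-values:")
print(np.round(report.p_values, 4))
# The statistic for g1-g2 is an order of magnitude below the pairs
# involving g3: orderings are the interpretable output.  Absolute values
# (and p-values) are inflated because the network is trained to tell the
# groups apart on these very rows, so it memorizes chance differences even
# between identically distributed groups; compare pairs, or compute
# features on held-out rows when calibrated p-values matter.
first = report.linkage_matrix[0, :2].astype(int)
print("dendrogram joins first:", [report.groups[i] for i in first])
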