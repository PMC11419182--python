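"""Generate a synthetic multi-group cohort with shift, missingness and MCI labels.

Two groups share 20 numeric features (think regional brain volumes plus
clinical covariates); group B is mean-shifted by 1 sigma on five of them.
Sparse missingness is injected into non-imaging-like columns, and an MCI
stratum receives pMCI/sMCI/nMCI progression labels tilted along the
diagnostic direction.
"""

import numpy as np

import cohortshift as cs

spec = cs.CohortSpec(
    n_per_group={"A": 500, "B": 100},
    n_numeric=20,
    shift_vector={"B": np.r_[np.ones(5), np.zeros(15)]},
    lognormal_columns=[18, 19],  # skewed columns, e.g. lesion volumes
    class_balance=0.5,
    seed=1,
)
cohort = cs.generate_cohort(spec)
print(f"cohort: {len(cohort.frame)} subjects, groups {dict(cohort.group.value_counts())}")

masked = cs.inject_missingness(cohort, {"x015": 0.4, "sex": 0.2, "apoe4": 0.5}, seed=2)
print("missing fractions:", {c: round(masked.frame[c].isna().mean(), 2) for c in ("x015", "sex", "apoe4")})

mci = cs.generate_cohort(cs.CohortSpec(n_per_group={"MCI": 300}, n_numeric=20, seed=3))
mci = cs.make_progression_labels(
    mci, np.r_[np.ones(5), np.zeros(15)], class_priors={"pMCI": 0.3, "sMCI": 0.5, "nMCI": 0.2}, seed=4
)
print("progression label counts:", dict(mci.frame["progression"].value_counts()))
# pMCI subjects carry higher latent severity than nMCI by construction,
# which is what lets an AD-trained classifier separate them later.

masked.to_csv("scratch_cohort.csv") if False else None  # pass a path to persist
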