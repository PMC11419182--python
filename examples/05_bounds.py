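"""Use the target-risk bound to reason about the mixing weight alpha.

The bound 4*sqrt((a^2/n + (1-a)^2/m)(V - log delta)) + 2(1-a)d trades the
variance of the weighted estimate against the source-target discrepancy d.
"""

import numpy as np

import cohortshift as cs
from cohortshift.bounds import BoundParams

delta = float(np.exp(-1.0))  # V - log(delta) = V + 1

for d in (0.0, 0.3, 0.8, 2.0):
    p = BoundParams(m=1000, n=50, V=1.0, delta=delta, d=d)
    a_star = cs.optimal_alpha(p)
    print(f"d = {d:>3}: alpha* = {a_star:.4f}   bound at alpha* = {cs.target_risk_bound(a_star, p):.4f}")
# alpha* grows with the discrepancy: the more the groups differ, the more
# weight the scarce target samples deserve.

p = BoundParams(m=1000, n=50, V=1.0, delta=delta, d=1.0)
thr = cs.alpha_one_threshold(p)
print(f"\nwith d = 1: once n >= {thr:.0f} target samples, alpha* = 1 and source data stops helping")
for n in (int(thr) - 1, int(thr) + 1):
    q = BoundParams(m=1000, n=n, V=1.0, delta=delta, d=1.0)
    print(f"  n = {n}: alpha* = {cs.optimal_alpha(q):.4f}")
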