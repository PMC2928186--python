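"""The four divergence measures, including the generalized-average sweep.

The GA distance 1 - X/B_lambda interpolates classical binary overlap
dissimilarities as its exponent grows: Simpson (min), geometric-mean
(cosine/Ochiai), Dice (arithmetic mean), and maximum-overlap.
"""

import math

import numpy as np

from exprdiv import correlation_distance, euclidean_distance, ga_distance

u_rel = np.array([0.70, 0.05, 0.05, 0.05, 0.05, 0.04, 0.03, 0.03])
v_rel = np.array([0.60, 0.10, 0.06, 0.06, 0.05, 0.05, 0.04, 0.04])
print(f"euclidean(u, v)   = {euclidean_distance(u_rel, v_rel):.4f}")
print(f"correlation(u, v) = {correlation_distance(u_rel, v_rel):.4f}")

u = [1, 1, 1, 0, 0, 0, 0, 0]  # m = 3 ones
v = [1, 1, 0, 0, 0, 0, 0, 0]  # n = 2 ones, X = 2 shared
print("\nGA sweep for m=3, n=2, X=2 (non-decreasing in lambda):")
for lam, name in [(-math.inf, "Simpson"), (0.0, "geometric"), (1.0, "Dice"),
                  (10.0, ""), (math.inf, "max-overlap")]:
    print(f"  lambda={lam!s:>5}: d = {ga_distance(u, v, lam):.4f}  {name}")
# Simpson gives 0 (the smaller support is contained in the larger);
# max-overlap charges the unmatched third tissue, giving 1/3.
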