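"""The rank machinery behind the pipeline's comparisons.

Shows joint MWU ranking with tie handling, the mean-rank-ratio permeability
index for an accumulating tracer, and the sham-referenced 3-SD exceedance
classifier.
"""

import numpy as np

from bbbkit import stats

# joint average ranks with ties
a, b = [3.0, 1.0, 4.0], [1.0, 5.0]
ra, rb = stats.mwu_rank(a, b)
print(f"pool {a} vs {b}: ranks {ra.ranks} / {rb.ranks}")
print(f"mean-rank ratio = {stats.mean_rank_ratio(ra, rb):.4f}")

# two-sample tests: exact for small pools, asymptotic above
stat, p = stats.two_sample_test([1, 2, 3], [10, 11, 12])
print(f"separated 3v3 samples: U = {stat:.0f}, exact two-tailed p = {p}")

rng = np.random.default_rng(0)
stat, p = stats.two_sample_test(rng.normal(size=50), rng.normal(size=50))
print(f"null 50v50 samples: p = {p:.3f} (should usually exceed 0.05)")

# the dysfunction classifier: a shift is called only when it exceeds the
# sham mean by more than three sham standard deviations
null = stats.ShamNull.from_shifts([0.5, -1.2, 2.0, 0.8, -0.3, 1.1])
for shift in (2.0, 17.9):
    flag = stats.classify_exceedance(shift, null)
    print(f"shift {shift:+.1f}% vs null {null.mean:+.2f} +/- {null.sd:.2f}% "
          f"-> dysfunction: {flag}")
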