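"""The multiple-knockoff filter on a tiny hand-checkable example.

Five variants, one knockoff copy each (M=1). The first three carry real
signal (their squared Z beats the knockoff's), the fourth is a null
whose knockoff happens to win, the fifth is a weak null.
"""

import numpy as np

from zknock import feature_stats, select

z = np.sqrt([5.0, 4.0, 3.0, 0.5, 1.0])          # original |Z| per variant
z_knock = np.sqrt([[0.0], [0.0], [0.0], [2.5], [0.0]])  # one knockoff copy

stats = feature_stats(z, z_knock, tie_seed=0)
print("kappa (0 = original wins):", stats.kappa)
print("tau   (winning margin)   :", stats.tau)
print("W     (selection evidence):", stats.W)

res = select(stats, target_fdr=0.35)
print("\nthreshold at target FDR 0.35:", res.threshold)
print("q-values:", np.round(res.qvalue, 3))
print("selected variant indices:", res.selected)
# The three signal variants clear the threshold; the knockoff-winning
# variant gets q = 1 and can never be selected.
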