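"""Depth and the detection of differentially expressed genes.

Simulates a 2-vs-2 negative-binomial experiment with planted fold
changes, runs the NB test, then scales the counts down 10-fold and shows
that modestly changed genes (2-5x) are lost at reduced depth much faster
than strongly changed genes (>10x).
"""

import numpy as np
import pandas as pd

import depthgauge as dg

rng = np.random.default_rng(4)
n = 2_000
means_a = rng.lognormal(4.0, 1.0, n)
fold = np.ones(n)
means_a[:150] = 40.0; fold[:150] = 3.0     # modest changes
means_a[150:300] = 40.0; fold[150:300] = 15.0  # strong changes
alpha = 0.1
r = 1.0 / alpha


def nb(means, n_samples):
    p = r / (r + means[:, None])
    return rng.negative_binomial(r, p, size=(n, n_samples))


matrix = pd.DataFrame(
    np.hstack([nb(means_a, 2), nb(means_a * fold, 2)]),
    columns=["a1", "a2", "b1", "b2"],
)
conds = ["A", "A", "B", "B"]

res = dg.run_de(matrix, conds, "A", "B")
print(f"significant at full depth (fold >= 2, p < 1e-3): "
      f"{int(res.table['significant'].sum())} genes")

table = dg.de_depth_experiment(
    matrix, conds, "A", "B", scale_fractions=[1.0, 0.1],
    true_fold=pd.Series(fold, index=matrix.index),
)
print(table.pivot(index="fold_bin", columns="scale_fraction",
                  values="n_significant").to_string())
# Reading the table: a 10-fold depth cut removes most of the 2-5x genes
# from the significant list but leaves the >10x genes essentially intact —
# depth matters most for subtle expression changes.
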