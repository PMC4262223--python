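"""Visualize sample compositions with robust compositional PCA.

Proportion vectors live on a simplex, so ordinary PCA is inappropriate;
the centered-log-ratio transform maps them to a zero-sum Euclidean space
first.  Normal and anomalous compositions should separate in the first
two components.
"""

import numpy as np

from aspire import ProportionMatrix, clr_pca_2d

rng = np.random.default_rng(0)
normal = rng.dirichlet([50, 30, 20, 0.5], size=12)     # consistent makeup
anomalous = rng.dirichlet([10, 10, 30, 50], size=4)    # distorted makeup
values = np.vstack([normal, anomalous])
ids = [f"normal_{i}" for i in range(12)] + [f"anom_{i}" for i in range(4)]
features = ProportionMatrix(values, ids, [0, 1, 2, 3])

coords = clr_pca_2d(features)
print("sample          PC1      PC2")
for sid, (x, y) in zip(ids, coords):
    print(f"{sid:12s} {x: 8.2f} {y: 8.2f}")
# The four anomalous samples should form a clearly displaced group in the
# (PC1, PC2) plane relative to the twelve normal samples.
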