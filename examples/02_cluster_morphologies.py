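"""Cluster a synthetic cohort's feature vectors into the three morphologies.

Draws 900 participants (300 per generating archetype) in the Δ% feature
space, fits k-means++ with k = 3, names the clusters by their stabilization-
point coordinate and prints the quality metrics used to judge the solution.
"""

import numpy as np

from orthomorph import (cluster_quality, draw_feature_matrix, fit_kmeans,
                        label_morphologies)

X, truth = draw_feature_matrix(["iOHYPO", "OHYPO", "OHYPER"], [300, 300, 300],
                               rng=0)
model = fit_kmeans(X, k=3, rng=0)
quality = cluster_quality(X, model, n_boot=50, rng=0)
names = label_morphologies(model)

print(f"converged after {model.i_conv} Lloyd iterations, "
      f"inertia {model.inertia:.0f}")
for j in range(3):
    c = model.centroids[j]
    print(f"  {names[j]:7s} n={np.sum(model.labels == j):3d} centroid "
          f"({c[0]:+6.1f}, {c[1]:+6.1f}, {c[2]:+6.1f}) Δ%  "
          f"d_c={quality.d_c[j]:5.2f}  diameter={quality.diameter[j]:5.2f}")
d = quality.d_cc[np.triu_indices(3, 1)]
print(f"centroid distances: {np.sort(d).round(2)}")
print(f"silhouette: {quality.silhouette:.2f}   bootstrap Jaccard: "
      f"{quality.jaccard:.2f}")
print()
print("A silhouette of ~0.3-0.4 is expected: the three morphologies overlap")
print("in feature space, as real cohorts do, while the solution itself is")
print("highly reproducible under resampling (Jaccard near 1).")
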