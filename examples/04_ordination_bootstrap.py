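"""Exploring trajectory structure: ordination, bootstrap error, clustering.

Builds specimen-level data with two bundles of similar directions, ordinates
the unit change vectors via the trait-side eigendecomposition, quantifies
per-lineage directional sampling error by bootstrap, and clusters.
"""

import numpy as np

from parallevo import (SpecimenModel, biplot, bootstrap_directions,
                       change_vectors, eigen_A, kmeans_grouping, normalize,
                       sample_specimens)

rng = np.random.default_rng(3)
p, per_bundle = 8, 4
b1, b2 = rng.standard_normal(p), rng.standard_normal(p)
diffs = np.vstack([b1 + 0.2 * rng.standard_normal((per_bundle, p)),
                   b2 + 0.2 * rng.standard_normal((per_bundle, p))])
anc = rng.standard_normal((2 * per_bundle, p))
model = SpecimenModel(ancestor_means=anc, descendant_means=anc + diffs,
                      sd=0.25, n_specimens=12)
specimens = sample_specimens(model, seed=4)

uz = normalize(change_vectors(specimens))
layout = biplot(uz, alpha_scaling=1.0)
print("ordination scores (components 1-2):")
print(layout.scores.round(3).to_string())
print(f"explained proportion: {layout.explained_proportion.round(3)}")

cloud = bootstrap_directions(specimens, eigen_A(uz), replicates=1000, seed=5)
print("\n95% bootstrap ellipse semi-axes per lineage:")
print(cloud.ellipses[["lineage", "semi_major", "semi_minor"]]
      .round(4).to_string(index=False))

labels, wss = kmeans_grouping(uz, k_range=[2, 3], restarts=30, seed=6)
print("\nk-means labels:")
print(labels.to_string())
print(wss.round(3).to_string(index=False))
print("-> the two programmed bundles separate on component 1; ellipse size")
print("   measures how much sampling noise alone could move each direction,")
print("   and k=2 recovers the generating groups with the lowest within-"
      "group sum of squares gain.")
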