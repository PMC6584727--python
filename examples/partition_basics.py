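"""Partitions, label switching, and the cluster mismatch error.

Builds a few labelings of six points, shows that label-permuted labelings
induce the same canonical partition, and evaluates the error measures used
throughout the package.
"""

from mvclust import (
    Labeling,
    canonicalize,
    cluster_mismatch_error,
    enumerate_partitions,
    partition_cost,
    partition_distance,
)

truth = Labeling([1, 1, 1, 2, 2, 2])
pred_a = Labeling([2, 2, 2, 1, 1, 1])  # same grouping, labels swapped
pred_b = Labeling([1, 1, 2, 2, 2, 1])  # two points moved

pa, pb = canonicalize(pred_a), canonicalize(pred_b)
print("canonical partition of label-swapped prediction:", pa.serialize())
print("identical to truth's partition:", pa == canonicalize(truth))

# cluster mismatch error absorbs label switching: pred_a is perfect, pred_b
# misplaces 2 of 6 points
print("error of pred_a:", cluster_mismatch_error(pa, truth))
print("error of pred_b:", cluster_mismatch_error(pb, truth))

# partition cost is the same quantity between two partitions, and the
# partition distance is its un-normalized (Hamming) form
print("cost(pa, pb):", round(partition_cost(pa, pb), 4))
print("distance(pa, pb):", partition_distance(pa, pb))

# the candidate space for two clusters: 2^(n-1) partitions
n_parts = sum(1 for _ in enumerate_partitions(6, 2))
n_balanced = sum(1 for _ in enumerate_partitions(6, 2, sizes=(3, 3)))
print(f"partitions of 6 points into <=2 blocks: {n_parts} (2^5)")
print(f"...with balanced sizes (3,3): {n_balanced}")
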