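"""Validate an enclave clustering against a reference with VI.

Compares the bottom-enclave clustering to the planted ground truth with
the variation of information (VI, in nats), then judges significance
against 500 random clusterings drawn from trees matching the real
tree's topology and node sizes — the empirical P-value (r+1)/(n+1).
"""

from hicenclave import (
    boxcox_scale, build_partition_tree, empirical_p, enclave_flat_clustering,
    generate_matrix, kr_balance, label_enclaves, nested_binary,
    variation_of_information, vi_null_distribution,
)

spec = nested_binary(n_bins=96, level_weights=(3.0, 6.0, 12.0, 24.0),
                     block_weight=60.0)
matrix, truth = generate_matrix(spec, n_bins=96, resolution=50_000, seed=1)
scaled, _ = boxcox_scale(kr_balance(matrix))
tree = build_partition_tree(scaled)
labels = label_enclaves(tree)
enclaves = enclave_flat_clustering(tree, labels)

observed = variation_of_information(enclaves, truth)
print(f"observed VI(enclaves, planted blocks) = {observed.vi:.4f} nats")
print(f"  entropies H = {observed.h_c:.3f} / {observed.h_cprime:.3f}, "
      f"mutual information I = {observed.mi:.3f}")

nulls = vi_null_distribution(tree, truth, n_draws=500, seed=2)
res = empirical_p(observed.vi, nulls)
print(f"random-clustering null: mean VI = {nulls.mean():.3f} "
      f"over {len(nulls)} draws")
print(f"empirical P = ({res.r}+1)/({res.n}+1) = {res.p:.4g}")
print("VI near 0 with P below 0.01 means the enclaves match the "
      "reference far better than size-matched random clusterings")
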