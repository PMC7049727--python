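"""Score every locus by nestedness.

Nestedness places each tree node on a fixed 0-1 scale anchored at the
topologically invariant landmarks — 0 at top enclaves, 0.5 at bottom
enclaves, 1 at leaves — so chromosomes with different tree shapes
become comparable.  Each locus inherits the score of the deepest scored
cluster containing it.
"""

import numpy as np

from hicenclave import (
    boxcox_scale, build_partition_tree, core_shell, generate_matrix, kr_balance,
    label_enclaves, nestedness,
)

# core-shell structures produce strip branchings high in the tree, so
# the full nestedness range (top enclave -> leaf) is populated
matrix, _ = generate_matrix(core_shell(), n_bins=120, resolution=50_000, seed=8)
scaled, _ = boxcox_scale(kr_balance(matrix))
tree = build_partition_tree(scaled)
labels = label_enclaves(tree)
ns = nestedness(tree, labels)

for nid in sorted(labels.top_enclaves):
    print(f"top enclave {nid}: NS = {ns.node_ns[nid]}")
for nid in sorted(labels.bottom_enclaves):
    print(f"bottom enclave {nid}: NS = {ns.node_ns[nid]}")

values = np.array(sorted(ns.locus_ns.values()))
print(f"per-locus NS: min {values.min():.2f}, median "
      f"{np.median(values):.2f}, max {values.max():.2f}")
hist, edges = np.histogram(values, bins=np.linspace(0, 1, 6))
for count, lo, hi in zip(hist, edges[:-1], edges[1:]):
    print(f"  NS in [{lo:.1f}, {hi:.1f}): {count} loci")
print("loci near 0 sit in loose shells of the first strips; loci near 1 "
      "survive to the deepest, most compact clusters")
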