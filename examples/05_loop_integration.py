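"""Ask whether DNA loops stay inside single bottom enclaves.

Builds an enclave hierarchy, then simulates a BEDPE loop set in which
two thirds of the loops connect loci of one bottom enclave and one
third bridges two different enclaves.  The integration statistic — the
percentage of loops with both anchors in the same enclave — should
recover the planted share.
"""

import numpy as np
import pandas as pd

from hicenclave import (
    boxcox_scale, build_partition_tree, generate_matrix, kr_balance, label_enclaves,
    loop_integration, nested_binary,
)

spec = nested_binary(n_bins=96, level_weights=(3.0, 6.0, 12.0, 24.0),
                     block_weight=60.0)
matrix, _ = generate_matrix(spec, n_bins=96, resolution=50_000, seed=1)
scaled, _ = boxcox_scale(kr_balance(matrix))
tree = build_partition_tree(scaled)
labels = label_enclaves(tree)
enclaves = sorted(labels.bottom_enclaves)
print(f"{len(enclaves)} bottom enclaves")

rng = np.random.default_rng(8)
bins = {b.index: b for b in tree.bins}
rows = []
for k in range(60):
    if k % 3 < 2:  # both anchors in one enclave
        loci = sorted(tree.nodes[enclaves[int(rng.integers(len(enclaves)))]].loci)
        a, b = rng.choice(loci, 2)
    else:  # anchors in two different enclaves
        i, j = rng.choice(len(enclaves), 2, replace=False)
        a = rng.choice(sorted(tree.nodes[enclaves[i]].loci))
        b = rng.choice(sorted(tree.nodes[enclaves[j]].loci))
    rows.append({"chrom1": tree.chrom, "start1": bins[int(a)].start + 1_000,
                 "end1": bins[int(a)].start + 3_000,
                 "chrom2": tree.chrom, "start2": bins[int(b)].start + 1_000,
                 "end2": bins[int(b)].start + 3_000})

pct, table = loop_integration(pd.DataFrame(rows), tree, labels)
print(f"loops with both anchors in the same bottom enclave: {pct:.1f}% "
      f"of {len(table)}")
print("the planted share was 66.7%, so matching it shows anchors are "
      "assigned to the enclaves that actually contain them")
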