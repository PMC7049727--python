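"""Relate an epigenomic track to nestedness.

Plants a feature track at a 10-fold site rate on high-nestedness loci,
then measures per-locus feature enrichment (FE: each locus's overlap
count divided by the mean over its top enclave) and tests nestedness
bins against the genome-wide site rate with exact Poisson ratio tests
(BH-corrected).
"""

import numpy as np
from scipy.stats import spearmanr

from hicenclave import (
    boxcox_scale, build_partition_tree, core_shell, feature_enrichment,
    fe_significance_threshold, generate_matrix, generate_track, kr_balance,
    label_enclaves, nestedness, ns_bin_poisson_tests,
)

matrix, _ = generate_matrix(core_shell(), n_bins=120, resolution=50_000, seed=8)
scaled, _ = boxcox_scale(kr_balance(matrix))
tree = build_partition_tree(scaled)
labels = label_enclaves(tree)
ns = nestedness(tree, labels)

median_ns = np.median([ns.locus_ns[i] for i in sorted(tree.universe)])
target = [i for i in sorted(tree.universe) if ns.locus_ns[i] >= median_ns]
track = generate_track(tree.bins, target, seed=21, base_rate=1.0,
                       enrichment=10.0)
print(f"planted {len(track.intervals)} sites, 10-fold rate on "
      f"{len(target)} high-NS loci")

results = feature_enrichment(tree, labels, ns, track, metric="count")
pairs = [(r.ns, r.fe) for r in results if r.fe is not None]
rho, p = spearmanr([a for a, _ in pairs], [b for _, b in pairs])
print(f"Spearman FE vs NS: rho = {rho:.3f} (P = {p:.2e}) over "
      f"{len(pairs)} loci")

table = ns_bin_poisson_tests(results, tree.resolution, track,
                             genome_bp=tree.resolution * len(tree.bins))
print("per-NS-bin Poisson ratio tests (BH-adjusted):")
for _, row in table.iterrows():
    flag = "*" if row.p_adjusted < 0.05 else " "
    print(f"  NS [{row.ns_lo:.1f},{row.ns_hi:.1f}) rate ratio "
          f"{row.rate_ratio:.2f} p_adj {row.p_adjusted:.2e} {flag}")

fes = [r.fe for r in results if r.fe is not None]
thr = fe_significance_threshold(fes)
print(f"FE significance threshold (75th pct + 2 IQR) = {thr:.2f}; "
      f"{sum(fe > thr for fe in fes)} loci above it")
print("a positive rho with significant high-NS bins recovers the "
      "planted coupling between nesting depth and feature density")
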