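"""Comparison of loci clusterings.

Variation of information (VI) between two flat clusterings of the same
loci universe, a tree-matched random-clustering null, and the empirical
P-value for the agreement between an enclave clustering and a reference
clustering (TADs, compartments).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import entropy
from sklearn.metrics import mutual_info_score

from .errors import PreconditionError, UniverseMismatchError
from .tree import EnclaveLabels, PartitionTree, TreeNode

UNCLUSTERED = "unclustered"


@dataclass(frozen=True)
class FlatClustering:
    """Disjoint assignment of every locus of a universe to one cluster."""

    assignment: dict[int, object]

    @property
    def universe(self) -> frozenset[int]:
        return frozenset(self.assignment)

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, loci: list[int]) -> np.ndarray:
        return np.array([self.assignment[i] for i in loci], dtype=object)


@dataclass(frozen=True)
class VIResult:
    vi: float
    h_c: float
    h_cprime: float
    mi: float


def variation_of_information(c: FlatClustering, cprime: FlatClustering) -> VIResult:
    """VI(C, C') = H(C) + H(C') - 2 I(C, C'), in nats.

    Entropies and mutual information use the empirical cluster and joint
    frequencies over the shared loci universe, with 0 log 0 = 0.
    """
    if c.universe != cprime.universe:
        raise UniverseMismatchError(
            c.universe - cprime.universe, cprime.universe - c.universe
        )
    loci = sorted(c.universe)
    la = c.labels_for(loci)
    lb = cprime.labels_for(loci)
    h_c = float(entropy(pd.Series(la).value_counts().to_numpy()))
    h_cp = float(entropy(pd.Series(lb).value_counts().to_numpy()))
    mi = float(mutual_info_score(la, lb))
    vi = max(0.0, h_c + h_cp - 2.0 * mi)
    return VIResult(vi, h_c, h_cp, mi)


@dataclass(frozen=True)
class EmpiricalPValue:
    r: int  # null draws with VI strictly smaller than observed
    n: int  # total clusterings considered (draws + 1)
    p: float


def empirical_p(observed_vi: float, null_vis) -> EmpiricalPValue:
    """Empirical P = (r+1)/(n+1), with r the count of null VIs strictly
    below the observed one and n the total number of clusterings
    considered (number of draws + 1).  Ties count as not smaller."""
    null_vis = list(null_vis)
    if not null_vis:
        raise PreconditionError("empty null sample")
    r = int(sum(v < observed_vi for v in null_vis))
    n = len(null_vis) + 1
    return EmpiricalPValue(r, n, (r + 1) / (n + 1))


def enclave_flat_clustering(
    tree: PartitionTree, labels: EnclaveLabels, level: str = "bottom"
) -> FlatClustering:
    """Flatten the chosen enclave level into a disjoint clustering.

    Each chosen enclave becomes one cluster named by its node id; loci
    covered by no chosen enclave fall into a single catch-all
    ``unclustered`` cluster.
    """
    chosen = {"bottom": labels.bottom_enclaves, "top": labels.top_enclaves}[level]
    assignment: dict[int, object] = {i: UNCLUSTERED for i in tree.universe}
    seen: dict[int, str] = {}
    for nid in sorted(chosen):
        for locus in tree.nodes[nid].loci:
            if locus in seen:  # cannot occur on a valid level
                raise PreconditionError(
                    f"locus {locus} covered by enclaves {seen[locus]} and {nid}"
                )
            seen[locus] = nid
            assignment[locus] = nid
    return FlatClustering(assignment)


def random_tree_clustering(
    template: PartitionTree, seed: int
) -> tuple[PartitionTree, FlatClustering]:
    """Draw a random tree matching the template's topology and node sizes.

    Starting from the full universe at the root, every bisection of the
    template is replayed with memberships drawn uniformly at random
    without replacement, so each node of the random tree has exactly the
    loci count of its template counterpart.  The induced flat clustering
    is extracted from the random tree's bottom enclaves exactly as for
    the real tree.
    """
    from .tree import label_enclaves  # local import to avoid cycle at import time

    rng = np.random.default_rng(seed)
    new_nodes: dict[str, TreeNode] = {}

    def recurse(nid: str, loci: frozenset[int]) -> None:
        tnode = template.nodes[nid]
        new_nodes[nid] = dc_replace(tnode, loci=loci, aux_loci=frozenset(),
                                    children=list(tnode.children))
        if not tnode.children:
            return
        pool = np.array(sorted(loci), dtype=int)
        rng.shuffle(pool)
        offset = 0
        for cid in tnode.children:
            size = len(template.nodes[cid].loci)
            subset = frozenset(int(x) for x in pool[offset : offset + size])
            offset += size
            recurse(cid, subset)
        if tnode.branch_kind == "strip":
            new_nodes[nid].aux_loci = frozenset(int(x) for x in pool[offset:])

    recurse(template.root, template.universe)
    random_tree = PartitionTree(
        new_nodes, template.root, template.resolution, template.chrom,
        list(template.bins),
    )
    labels = label_enclaves(random_tree)
    return random_tree, enclave_flat_clustering(random_tree, labels)


def vi_null_distribution(
    template: PartitionTree,
    reference: FlatClustering,
    n_draws: int = 500,
    seed: int = 1234,
) -> np.ndarray:
    """VI of ``n_draws`` tree-matched random clusterings vs a reference."""
    seeds = np.random.SeedSequence(seed).generate_state(n_draws) % (2**31 - 1)
    return np.array(
        [
            variation_of_information(
                random_tree_clustering(template, int(s))[1], reference
            ).vi
            for s in seeds
        ]
    )


def reference_bed_clustering(path, bins) -> FlatClustering:
    """Read a labeled reference BED (chrom, start, end, label) onto bins.

    Each bin takes the label of the interval with the largest overlap;
    uncovered bins go to the catch-all ``unclustered`` cluster.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "label"], usecols=range(4),
    )
    assignment: dict[int, object] = {}
    for b in bins:
        sub = df[(df.chrom == b.chrom) & (df.start < b.end) & (df.end > b.start)]
        if len(sub) == 0:
            assignment[b.index] = UNCLUSTERED
            continue
        ov = np.minimum(sub.end, b.end) - np.maximum(sub.start, b.start)
        assignment[b.index] = sub.label.iloc[int(np.argmax(ov.to_numpy()))]
    return FlatClustering(assignment)
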