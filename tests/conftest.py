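"""Shared fixtures and independent brute-force oracles.

The oracles deliberately recompute quantities with naive enumeration or
textbook formulas, independent of the library's implementation paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hicenclave import (
    ContactMatrix,
    GenomicBin,
    PartitionTree,
    TreeNode,
)


# ---------------------------------------------------------------------------
# matrix helpers


def random_symmetric_matrix(rng: np.random.Generator, n: int,
                            positive: bool = True) -> np.ndarray:
    w = rng.uniform(0.5 if positive else 0.0, 2.0, size=(n, n))
    w = 0.5 * (w + w.T)
    return w


def contact_matrix_from_weights(w: np.ndarray, resolution: int = 50_000,
                                chrom: str = "chrT",
                                stage: str = "raw") -> ContactMatrix:
    n = w.shape[0]
    bins = [GenomicBin(chrom, i * resolution, (i + 1) * resolution, i)
            for i in range(n)]
    return ContactMatrix(bins, np.asarray(w, dtype=float), resolution, chrom, stage)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# oracles


def brute_expansion(w: np.ndarray, c1, c2) -> float:
    """Ordered-pair expansion by explicit double loops."""
    num = 0.0
    for x in c1:
        for y in c2:
            num += w[x, y]
    den = 0.0
    for x in c1:
        for y in c1:
            den += w[x, y]
    return num / den


def brute_vi(labels_a, labels_b) -> float:
    """VI from the joint contingency table, by hand."""
    labels_a, labels_b = list(labels_a), list(labels_b)
    n = len(labels_a)
    ka, kb = sorted(set(labels_a), key=str), sorted(set(labels_b), key=str)
    joint = np.zeros((len(ka), len(kb)))
    for a, b in zip(labels_a, labels_b):
        joint[ka.index(a), kb.index(b)] += 1
    joint /= n
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)

    def xlogx(p):
        p = p[p > 0]
        return float((p * np.log(p)).sum())

    h_a, h_b = -xlogx(pa), -xlogx(pb)
    mi = 0.0
    for i in range(len(ka)):
        for j in range(len(kb)):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
    return h_a + h_b - 2.0 * mi


def normalized_cut(w: np.ndarray, side: frozenset[int]) -> float:
    n = w.shape[0]
    other = frozenset(range(n)) - side
    cross = sum(w[i, j] for i in side for j in other)
    vol_a = sum(w[i, j] for i in side for j in range(n))
    vol_b = sum(w[i, j] for i in other for j in range(n))
    return cross / vol_a + cross / vol_b


def best_bipartitions_by_ncut(w: np.ndarray):
    """All bipartitions of a small graph sorted by normalized cut."""
    n = w.shape[0]
    seen = []
    for bits in range(1, 2 ** (n - 1)):  # fix node 0 on one side
        side = frozenset(i for i in range(n) if bits >> i & 1)
        if not side or len(side) == n:
            continue
        seen.append((normalized_cut(w, side), side))
    seen.sort(key=lambda t: t[0])
    return seen


def naive_interval_overlap(intervals, site_start, site_end) -> int:
    """bp overlap of one site with a list of disjoint intervals, by loop."""
    total = 0
    for s, e in intervals:
        total += max(0, min(e, site_end) - max(s, site_start))
    return total


def poisson_tail_oracle(observed: int, mu: float) -> float:
    """Minimum-likelihood two-sided exact Poisson P-value via cdf/sf.

    Locates the cut points by scanning the pmf on each side of the mode
    and combines the two tails through cdf/sf calls — an arrangement
    independent of a single pmf mask-and-sum.
    """
    from scipy.stats import poisson

    d = poisson.pmf(observed, mu) * (1 + 1e-7)
    mode = int(np.floor(mu))
    if observed == mode:
        return 1.0
    if observed > mode:
        upper = float(poisson.sf(observed - 1, mu))
        k = mode
        while k >= 0 and poisson.pmf(k, mu) > d:
            k -= 1
        lower = float(poisson.cdf(k, mu)) if k >= 0 else 0.0
    else:
        lower = float(poisson.cdf(observed, mu))
        k = mode
        while poisson.pmf(k, mu) > d:
            k += 1
        upper = float(poisson.sf(k - 1, mu))
    return min(1.0, lower + upper)


# ---------------------------------------------------------------------------
# hand-built trees


def make_tree(shape: dict, resolution: int = 50_000,
              chrom: str = "chrT") -> PartitionTree:
    """Build a PartitionTree from {id: (parent, branch_kind, loci)}."""
    nodes = {}
    for nid, (parent, kind, loci) in shape.items():
        nodes[nid] = TreeNode(
            id=nid, loci=frozenset(loci), parent=parent, branch_kind=kind,
            root_distance=0 if parent is None else nid.count("."),
        )
    for nid, node in nodes.items():
        if node.parent is not None:
            nodes[node.parent].children.append(nid)
    for node in nodes.values():
        node.children.sort()
    root = next(nid for nid, n in nodes.items() if n.parent is None)
    universe = sorted(nodes[root].loci)
    bins = [GenomicBin(chrom, i * resolution, (i + 1) * resolution, i)
            for i in universe]
    return PartitionTree(nodes, root, resolution, chrom, bins)


def random_topology_tree(rng: np.random.Generator, n_loci: int = 24,
                         max_depth: int = 5) -> PartitionTree:
    """Random tree with split/strip branchings for labeling/NS tests."""
    nodes: dict[str, TreeNode] = {}

    def recurse(nid, parent, loci, depth):
        nodes[nid] = TreeNode(id=nid, loci=frozenset(loci), parent=parent,
                              root_distance=depth)
        if parent is not None:
            nodes[parent].children.append(nid)
        if len(loci) <= 2 or depth >= max_depth or rng.random() < 0.15:
            return
        loci = list(loci)
        rng.shuffle(loci)
        cut = int(rng.integers(1, len(loci)))
        a, b = loci[:cut], loci[cut:]
        if rng.random() < 0.5:
            nodes[nid].branch_kind = "split"
            recurse(f"{nid}.0", nid, a, depth + 1)
            recurse(f"{nid}.1", nid, b, depth + 1)
        else:
            nodes[nid].branch_kind = "strip"
            keep, aux = (a, b) if len(a) >= len(b) else (b, a)
            nodes[nid].aux_loci = frozenset(aux)
            recurse(f"{nid}.0", nid, keep, depth + 1)

    recurse("R", None, list(range(n_loci)), 0)
    bins = [GenomicBin("chrT", i * 50_000, (i + 1) * 50_000, i)
            for i in range(n_loci)]
    return PartitionTree(nodes, "R", 50_000, "chrT", bins)
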