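"""Recursive partition tree of a chromosome.

The chromosome's loci set is recursively bisected with spectral
clustering.  Each resulting part is scored with the expansion metric —
the ratio of edge weight crossing the part to edge weight inside it — and
a part is called insulated when its expansion is below 1.  A bisection
yielding two insulated parts is a *split*, one insulated part a *strip*
(only the insulated part is recursed; the loose partner is kept on the
node as auxiliary loci), and none stops the branch.  The resulting
rooted tree of nested, possibly non-contiguous loci clusters (enclaves)
is then annotated:

* *top enclaves* — strip-branching nodes with only split branchings above;
* *bottom enclaves* — children of a split below which only strip
  branchings occur;
* *leaves* — childless nodes;

and every node/locus receives a nestedness score in [0, 1] interpolated
between those anchors (0 at top enclaves, 0.5 at bottom enclaves, 1 at
leaves).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateSplitError,
    InsulationUndefinedError,
    PreconditionError,
)
from .matrix import ContactMatrix, GenomicBin
from .spectral import Bisection, fiedler_bisect

SPLIT = "split"
STRIP = "strip"
STOP = "stop"
NONE = "none"


# ---------------------------------------------------------------------------
# expansion metric and bisection classification


def expansion_metric(w: np.ndarray, c1, c2) -> float:
    """Expansion of part ``c1`` against its bisection partner ``c2``.

    Sum of weights over ordered pairs C1 x C2 divided by the sum over
    ordered pairs C1 x C1 (internal edges counted twice, the diagonal
    once).  Below 1 means the part keeps the majority of its edge weight
    inside itself — it is insulated.
    """
    c1 = np.fromiter(c1, dtype=int)
    c2 = np.fromiter(c2, dtype=int)
    if c1.size == 0 or c2.size == 0:
        raise PreconditionError("both parts must be non-empty")
    if np.intersect1d(c1, c2).size:
        raise PreconditionError("parts must be disjoint")
    cross = float(w[np.ix_(c1, c2)].sum())
    internal = float(w[np.ix_(c1, c1)].sum())
    if internal == 0:
        raise InsulationUndefinedError(
            "part has zero internal weight; insulation undefined"
        )
    return cross / internal


def _expansion_or_inf(w, c1, c2) -> float:
    try:
        return expansion_metric(w, c1, c2)
    except InsulationUndefinedError:
        return np.inf


def classify_bisection(w: np.ndarray, bisection: Bisection):
    """Classify a bisection as split / strip / stop.

    Returns ``(kind, expansion_a, expansion_b)``.  A part with undefined
    insulation (zero internal weight) counts as not insulated.
    """
    a, b = bisection.part_a, bisection.part_b
    ea = _expansion_or_inf(w, a, b)
    eb = _expansion_or_inf(w, b, a)
    ins_a, ins_b = ea < 1, eb < 1
    if ins_a and ins_b:
        kind = SPLIT
    elif ins_a or ins_b:
        kind = STRIP
    else:
        kind = STOP
    return kind, ea, eb


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    """One node of the partition tree (a loci cluster)."""

    id: str
    loci: frozenset[int]
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    branch_kind: str = NONE  # branching this node itself produced
    expansion: float | None = None  # this node's expansion within its bisection
    aux_loci: frozenset[int] = frozenset()  # strip partner, not recursed
    root_distance: int = 0
    termination: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PartitionTree:
    """Rooted tree of nested loci clusters for one chromosome."""

    nodes: dict[str, TreeNode]
    root: str
    resolution: int
    chrom: str
    bins: list[GenomicBin] = field(default_factory=list)

    @property
    def universe(self) -> frozenset[int]:
        return self.nodes[self.root].loci

    def ancestors(self, node_id: str):
        node = self.nodes[node_id]
        while node.parent is not None:
            node = self.nodes[node.parent]
            yield node

    def descendants(self, node_id: str):
        stack = list(self.nodes[node_id].children)
        while stack:
            child = self.nodes[stack.pop()]
            yield child
            stack.extend(child.children)

    def validate(self) -> None:
        seen = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise PreconditionError(f"cycle or duplicate node id {nid}")
            seen.add(nid)
            node = self.nodes[nid]
            for cid in node.children:
                child = self.nodes[cid]
                if not child.loci <= node.loci:
                    raise PreconditionError(f"child {cid} loci not nested in {nid}")
                if child.parent != nid:
                    raise PreconditionError(f"broken parent link at {cid}")
            if node.branch_kind == SPLIT:
                a, b = (self.nodes[c].loci for c in node.children)
                if a & b or (a | b) != node.loci:
                    raise PreconditionError(f"split children of {nid} do not partition it")
            stack.extend(node.children)
        if seen != set(self.nodes):
            raise PreconditionError("unreachable nodes present")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "resolution": self.resolution,
            "root": self.root,
            "bins": [[b.chrom, b.start, b.end, b.index] for b in self.bins],
            "nodes": {
                nid: {
                    "parent": n.parent,
                    "children": list(n.children),
                    "branch_kind": n.branch_kind,
                    "expansion": n.expansion,
                    "loci": sorted(n.loci),
                    "aux_loci": sorted(n.aux_loci),
                    "root_distance": n.root_distance,
                    "termination": n.termination,
                }
                for nid, n in sorted(self.nodes.items())
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionTree":
        nodes = {
            nid: TreeNode(
                id=nid,
                loci=frozenset(nd["loci"]),
                parent=nd["parent"],
                children=list(nd["children"]),
                branch_kind=nd["branch_kind"],
                expansion=nd["expansion"],
                aux_loci=frozenset(nd.get("aux_loci", [])),
                root_distance=nd["root_distance"],
                termination=nd.get("termination"),
            )
            for nid, nd in d["nodes"].items()
        }
        bins = [GenomicBin(c, s, e, i) for c, s, e, i in d.get("bins", [])]
        return cls(nodes, d["root"], d["resolution"], d["chrom"], bins)

    @classmethod
    def from_json(cls, path) -> "PartitionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# tree construction


def build_partition_tree(
    m: ContactMatrix,
    master_seed: int = 1234,
    n_seedings: int = 5,
    require_scaled: bool = True,
) -> PartitionTree:
    """Build the partition tree by recursive spectral bisection.

    Depth-first from the full retained-loci set.  At every node with more
    than two loci the subgraph is bisected on the Fiedler vector and the
    bisection classified by the expansion metric; insulated parts become
    children (ids are deterministic path strings: root ``R``, children
    ``R.0``/``R.1``) and are themselves recursed.  Branches end at stop
    classifications, at parts with at most two loci, and on degenerate
    spectra.  Expansion is always evaluated on the full-chromosome
    weights restricted to the relevant loci.
    """
    if require_scaled and m.stage != "boxcox_scaled":
        raise PreconditionError(
            f"expected a boxcox_scaled matrix, got stage '{m.stage}' "
            "(pass require_scaled=False to override)"
        )
    w = m.weights
    nodes: dict[str, TreeNode] = {}

    def recurse(loci: frozenset[int], nid: str, parent: str | None,
                expansion: float | None, depth: int) -> None:
        node = TreeNode(
            id=nid, loci=loci, parent=parent, expansion=expansion,
            root_distance=depth,
        )
        nodes[nid] = node
        if parent is not None:
            nodes[parent].children.append(nid)
        if len(loci) <= 2:
            node.termination = "min_size"
            return
        idx = np.array(sorted(loci), dtype=int)
        sub = w[np.ix_(idx, idx)]
        try:
            bisection = fiedler_bisect(sub, n_seedings=n_seedings,
                                       master_seed=master_seed)
        except DegenerateSplitError:
            node.termination = "degenerate_spectrum"
            return
        # map local part indices back to chromosome bin indices
        part_a = frozenset(int(idx[i]) for i in bisection.part_a)
        part_b = frozenset(int(idx[i]) for i in bisection.part_b)
        kind, ea, eb = classify_bisection(w, Bisection(
            part_a, part_b, bisection.fiedler_value, bisection.fiedler_vector))
        if kind == STOP:
            node.branch_kind = NONE
            node.termination = "stop"
            return
        node.branch_kind = kind
        if kind == SPLIT:
            recurse(part_a, f"{nid}.0", nid, ea, depth + 1)
            recurse(part_b, f"{nid}.1", nid, eb, depth + 1)
        else:  # strip: recurse only the insulated part
            ins, aux, e_ins = (part_a, part_b, ea) if ea < 1 else (part_b, part_a, eb)
            node.aux_loci = aux
            recurse(ins, f"{nid}.0", nid, e_ins, depth + 1)

    recurse(frozenset(range(m.n)), "R", None, None, 0)
    tree = PartitionTree(nodes, "R", m.resolution, m.chrom, list(m.bins))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# enclave labels


@dataclass(frozen=True)
class EnclaveLabels:
    top_enclaves: frozenset[str]
    bottom_enclaves: frozenset[str]
    leaves: frozenset[str]


def label_enclaves(tree: PartitionTree) -> EnclaveLabels:
    """Identify top enclaves, bottom enclaves, and leaves.

    Top enclaves are strip-branching nodes all of whose ancestors branch
    as splits (first strips).  Bottom enclaves are non-leaf children of a
    split whose entire subtree (themselves included) contains no split
    branching (last splits).  Leaves are childless nodes.  A node
    qualifying as both first strip and last split is classified as a
    bottom enclave, so the three sets are pairwise disjoint.
    """
    leaves = frozenset(nid for nid, n in tree.nodes.items() if n.is_leaf)

    # bottom-up: does the subtree rooted at nid (inclusive) contain a split?
    has_split: dict[str, bool] = {}

    def fill(nid: str) -> bool:
        node = tree.nodes[nid]
        child_vals = [fill(c) for c in node.children]  # fill all subtrees
        val = node.branch_kind == SPLIT or any(child_vals)
        has_split[nid] = val
        return val

    fill(tree.root)

    bottom = set()
    for nid, node in tree.nodes.items():
        if node.is_leaf or node.parent is None:
            continue
        if tree.nodes[node.parent].branch_kind == SPLIT and not has_split[nid]:
            bottom.add(nid)

    top = set()
    for nid, node in tree.nodes.items():
        if node.branch_kind != STRIP or nid in bottom:
            continue
        if all(a.branch_kind == SPLIT for a in tree.ancestors(nid)):
            top.add(nid)

    return EnclaveLabels(frozenset(top), frozenset(bottom), leaves)


# ---------------------------------------------------------------------------
# nestedness


@dataclass
class NestednessMap:
    """Per-node and per-locus nestedness scores in [0, 1].

    ``node_ns[nid]`` is ``None`` when the node is not spanned by any
    top-enclave-rooted segment (e.g. pure-split region above all top
    enclaves, or a side branch with no bottom enclave below).
    """

    node_ns: dict[str, float | None]
    locus_ns: dict[int, float]


def nestedness(tree: PartitionTree, labels: EnclaveLabels) -> NestednessMap:
    """Interpolate nestedness between the enclave anchors.

    Anchors: 0 at top enclaves, 0.5 at bottom enclaves, 1 at leaves.
    Between a top and a bottom enclave:
    ``NS = 0.5 (D - Dmin) / ((Dmax - Dmin) + 1)`` with ``Dmin`` the root
    distance of the nearest top enclave above and ``Dmax`` that of the
    furthest bottom enclave below (the +1 keeps these values strictly
    under 0.5).  Between a bottom enclave and a leaf:
    ``NS = 0.5 (D - Dmin) / (Dmax - Dmin) + 0.5`` anchored on the nearest
    bottom enclave above and furthest leaf below.  Each locus takes the
    score of the deepest scored node containing it; loci confined to the
    pure-split region above all top enclaves score 0.
    """
    node_ns: dict[str, float | None] = {}

    def nearest_above(nid: str, member: frozenset[str]) -> str | None:
        for anc in tree.ancestors(nid):
            if anc.id in member:
                return anc.id
            # segments do not cross another anchor of either kind
            if anc.id in labels.top_enclaves or anc.id in labels.bottom_enclaves:
                return None
        return None

    for nid, node in tree.nodes.items():
        if nid in labels.bottom_enclaves:
            node_ns[nid] = 0.5
            continue
        if node.is_leaf:
            node_ns[nid] = 1.0
            continue
        if nid in labels.top_enclaves:
            node_ns[nid] = 0.0
            continue
        d = node.root_distance
        below_bottom = nearest_above(nid, labels.bottom_enclaves)
        if below_bottom is not None:
            dmin = tree.nodes[below_bottom].root_distance
            leaf_ds = [x.root_distance for x in tree.descendants(nid) if x.is_leaf]
            dmax = max(leaf_ds)
            node_ns[nid] = 0.5 * (d - dmin) / (dmax - dmin) + 0.5
            continue
        below_top = nearest_above(nid, labels.top_enclaves)
        bottoms_below = [
            x.root_distance
            for x in tree.descendants(nid)
            if x.id in labels.bottom_enclaves
        ]
        if below_top is not None and bottoms_below:
            dmin = tree.nodes[below_top].root_distance
            dmax = max(bottoms_below)
            node_ns[nid] = 0.5 * (d - dmin) / ((dmax - dmin) + 1)
        else:
            node_ns[nid] = None  # unspanned: pure-split region or dead side branch

    # per-locus: deepest scored node containing the locus
    locus_ns: dict[int, float] = {i: 0.0 for i in tree.universe}
    locus_depth: dict[int, int] = {i: -1 for i in tree.universe}
    for nid, ns in node_ns.items():
        if ns is None:
            continue
        node = tree.nodes[nid]
        for locus in node.loci:
            if node.root_distance > locus_depth[locus]:
                locus_depth[locus] = node.root_distance
                locus_ns[locus] = ns
    return NestednessMap(node_ns, locus_ns)


def write_nestedness_bed(tree: PartitionTree, ns_map: NestednessMap, path) -> None:
    """Write per-locus nestedness as BED with NS in the score column."""
    by_index = {b.index: b for b in tree.bins}
    with open(path, "w") as fh:
        for locus in sorted(ns_map.locus_ns):
            b = by_index[locus]
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\tlocus_{locus}\t"
                f"{ns_map.locus_ns[locus]:.6f}\n"
            )
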