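"""Synthetic Hi-C matrices and feature tracks with planted ground truth.

The generator emulates the salient structure of a per-chromosome Hi-C
contact map: a power-law distance-decay background plus planted nested
(optionally non-contiguous) high-interaction blocks — the "plaid"
patterns that recursive spectral clustering is meant to recover —
with Poisson (optionally negative-binomial) counting noise.  Feature
tracks are placed with a controllable rate ratio on a target loci set so
enrichment analyses can be validated against a known signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError
from .matrix import ContactMatrix, GenomicBin, STAGE_RAW
from .compare import FlatClustering, UNCLUSTERED
from .features import FeatureInterval, FeatureTrack


@dataclass
class PlantedBlock:
    """One planted cluster: a loci set with extra within-cluster weight.

    ``core`` restricts the extra weight of *children* relative to this
    block; children must be nested inside the parent's loci, and sibling
    loci sets must be disjoint.
    """

    name: str
    loci: np.ndarray  # bin indices, need not be contiguous
    within_weight: float
    children: list["PlantedBlock"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PlantedHierarchy:
    """Ground-truth structure for one synthetic chromosome."""

    blocks: list[PlantedBlock]  # top-level planted clusters
    background: float = 1.0
    decay_exponent: float = 1.0  # alpha of the |i-j|^-alpha background

    def validate(self, n_bins: int) -> None:
        if self.background < 0 or self.decay_exponent < 0:
            raise PreconditionError("background and decay exponent must be >= 0")

        def check(block: PlantedBlock, parent_loci: set[int] | None) -> None:
            loci = set(int(x) for x in block.loci)
            if not loci:
                raise PreconditionError(f"block {block.name} is empty")
            if max(loci) >= n_bins or min(loci) < 0:
                raise PreconditionError(f"block {block.name} exceeds n_bins")
            if block.within_weight <= 0:
                raise PreconditionError(f"block {block.name} weight must be > 0")
            if parent_loci is not None and not loci <= parent_loci:
                raise PreconditionError(f"block {block.name} not nested in parent")
            seen: set[int] = set()
            for child in block.children:
                child_loci = set(int(x) for x in child.loci)
                if child_loci & seen:
                    raise PreconditionError(
                        f"children of {block.name} overlap each other"
                    )
                seen |= child_loci
                check(child, loci)

        seen_top: set[int] = set()
        for block in self.blocks:
            top_loci = set(int(x) for x in block.loci)
            if top_loci & seen_top:
                raise PreconditionError("top-level blocks overlap each other")
            seen_top |= top_loci
            check(block, None)

    def all_blocks(self):
        for block in self.blocks:
            yield from block.walk()

    def leaf_blocks(self):
        return [b for b in self.all_blocks() if not b.children]


def expected_matrix(spec: PlantedHierarchy, n_bins: int) -> np.ndarray:
    """Noise-free expected weights: decay background + planted blocks."""
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    np.fill_diagonal(dist, 1.0)  # self-interaction decays like distance 1
    expected = spec.background * dist ** (-spec.decay_exponent)
    for block in spec.all_blocks():
        loci = np.asarray(block.loci, dtype=int)
        expected[np.ix_(loci, loci)] += block.within_weight
    return expected


def generate_matrix(
    spec: PlantedHierarchy,
    n_bins: int,
    resolution: int,
    seed: int,
    chrom: str = "chrS",
    noise: str = "poisson",
    dispersion: float | None = None,
) -> tuple[ContactMatrix, FlatClustering]:
    """Sample a raw contact matrix and the planted leaf-block clustering.

    Counts on the upper triangle are drawn independently from a Poisson
    (or, with ``dispersion`` set, negative-binomial with that size
    parameter) around the expected weights and mirrored.  Bins whose
    realized row sum is zero are dropped, with the planted clustering
    re-indexed accordingly.  Identical seed and spec give bit-identical
    output.
    """
    spec.validate(n_bins)
    expected = expected_matrix(spec, n_bins)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_bins)
    mu = expected[iu]
    if noise == "poisson":
        counts = rng.poisson(mu)
    elif noise == "negative_binomial":
        if dispersion is None or dispersion <= 0:
            raise PreconditionError("negative_binomial noise needs dispersion > 0")
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p)
    else:
        raise PreconditionError(f"unknown noise model '{noise}'")
    w = np.zeros((n_bins, n_bins))
    w[iu] = counts
    w = np.triu(w) + np.triu(w, 1).T

    keep = w.sum(axis=1) > 0
    dropped = [int(i) * resolution for i in np.nonzero(~keep)[0]]
    w = w[np.ix_(keep, keep)]
    old_to_new = {int(old): new for new, old in enumerate(np.nonzero(keep)[0])}
    bins = [
        GenomicBin(chrom, int(old) * resolution, (int(old) + 1) * resolution, new)
        for new, old in enumerate(np.nonzero(keep)[0])
    ]
    m = ContactMatrix(bins, w.astype(float), resolution, chrom, STAGE_RAW, dropped)
    m.validate()

    assignment: dict[int, object] = {i: UNCLUSTERED for i in range(len(bins))}
    for block in spec.leaf_blocks():
        for locus in block.loci:
            if int(locus) in old_to_new:
                assignment[old_to_new[int(locus)]] = block.name
    return m, FlatClustering(assignment)


# ---------------------------------------------------------------------------
# presets


def nested_two_level(
    n_bins: int = 200,
    background: float = 1.0,
    super_weight: float = 5.0,
    block_weight: float = 10.0,
    non_contiguous: bool = False,
) -> PlantedHierarchy:
    """Two superblocks each containing two nested blocks.

    With ``non_contiguous=True`` the first superblock's two blocks
    interleave two distant genomic segments each, exercising the
    defining capability of enclaves over contiguous domains.
    """
    half = n_bins // 2
    quarter = half // 2
    s1 = np.arange(0, half)
    s2 = np.arange(half, n_bins)
    if non_contiguous:
        # block A takes the first and third quarters of superblock 1
        a = np.concatenate([s1[: quarter // 2], s1[quarter : quarter + quarter // 2]])
        b = np.setdiff1d(s1, a)
    else:
        a, b = s1[:quarter], s1[quarter:]
    c, d = s2[: len(s2) // 2], s2[len(s2) // 2 :]
    return PlantedHierarchy(
        blocks=[
            PlantedBlock("S1", s1, super_weight, [
                PlantedBlock("S1.A", a, block_weight),
                PlantedBlock("S1.B", b, block_weight),
            ]),
            PlantedBlock("S2", s2, super_weight, [
                PlantedBlock("S2.C", c, block_weight),
                PlantedBlock("S2.D", d, block_weight),
            ]),
        ],
        background=background,
    )


def nested_binary(
    n_bins: int = 48,
    level_weights: tuple[float, ...] = (3.0, 6.0, 12.0),
    block_weight: float = 30.0,
    background: float = 1.0,
    non_contiguous: bool = False,
) -> PlantedHierarchy:
    """Balanced binary nesting with geometrically increasing weights.

    The chromosome is halved recursively; each nesting level *multiplies*
    contact intensity over its parent (weights roughly doubling per
    level), emulating the fractal-globule-like picture of chromatin
    folding where ever-smaller clusters pack ever more densely.  The
    deepest level consists of compact leaf blocks (3 loci at the
    defaults), which makes the planted leaf clustering identifiable
    against counting noise.  With ``non_contiguous=True`` genomic
    positions are interleaved between the two chromosome halves, so
    every planted cluster is scattered across distant genomic segments —
    the defining enclave case.
    """
    depth = len(level_weights) + 1
    if n_bins % (2**depth):
        raise PreconditionError(f"n_bins must be a multiple of {2 ** depth}")
    positions = np.arange(n_bins)
    if non_contiguous:
        positions = np.arange(n_bins).reshape(2, -1).T.ravel()

    def build(loci: np.ndarray, level: int, name: str) -> PlantedBlock:
        if level == len(level_weights):
            return PlantedBlock(name, loci, block_weight)
        half = len(loci) // 2
        return PlantedBlock(name, loci, level_weights[level], [
            build(loci[:half], level + 1, name + "0"),
            build(loci[half:], level + 1, name + "1"),
        ])

    half = n_bins // 2
    return PlantedHierarchy(
        blocks=[build(positions[:half], 0, "L"), build(positions[half:], 0, "R")],
        background=background,
    )


def core_shell(
    n_bins: int = 120,
    background: float = 0.5,
    shell_weight: float = 4.0,
    core_weight: float = 8.0,
    block_weight: float = 16.0,
) -> PlantedHierarchy:
    """Two core-plus-shell structures producing strip branchings.

    Each half of the chromosome is one planted structure: every locus of
    the structure shares ``shell_weight``, a dense core adds
    ``core_weight``, and two sub-blocks inside the core add
    ``block_weight``.  Bisecting a structure insulates only the core
    (the loose shell keeps most of its weight pointing at the core), so
    the structure branches as a strip — the top-enclave pattern — while
    the core then splits into the two sub-blocks (bottom enclaves).
    """
    half = n_bins // 2

    def structure(lo: int, tag: str) -> PlantedBlock:
        loci = np.arange(lo, lo + half)
        core = loci[: int(0.75 * half)]
        b1 = core[: len(core) // 2]
        b2 = core[len(core) // 2 :]
        return PlantedBlock(f"{tag}", loci, shell_weight, [
            PlantedBlock(f"{tag}.core", core, core_weight, [
                PlantedBlock(f"{tag}.core.1", b1, block_weight),
                PlantedBlock(f"{tag}.core.2", b2, block_weight),
            ])
        ])

    return PlantedHierarchy(
        blocks=[structure(0, "T1"), structure(half, "T2")],
        background=background,
    )


# ---------------------------------------------------------------------------
# feature tracks


def generate_track(
    bins,
    target_loci,
    seed: int,
    base_rate: float = 0.5,
    enrichment: float = 1.0,
    site_length: int = 400,
    name: str = "synthetic_track",
) -> FeatureTrack:
    """Place feature sites with an elevated rate on target loci.

    Per bin, the expected number of sites is ``base_rate`` (times
    ``enrichment`` for bins in ``target_loci``); counts are Poisson,
    positions uniform within the bin, lengths exponential around
    ``site_length`` (at least 50 bp, clipped to the bin), intensities
    log-normal.  Deterministic given the seed.
    """
    if base_rate < 0 or enrichment < 0:
        raise PreconditionError("rates must be non-negative")
    target = set(int(x) for x in target_loci)
    rng = np.random.default_rng(seed)
    intervals = []
    for b in bins:
        rate = base_rate * (enrichment if b.index in target else 1.0)
        for _ in range(rng.poisson(rate)):
            length = max(50, int(rng.exponential(site_length)))
            start = int(rng.integers(b.start, max(b.start + 1, b.end - length)))
            end = min(start + length, b.end)
            intensity = float(rng.lognormal(0.0, 1.0))
            intervals.append(FeatureInterval(b.chrom, start, end, intensity))
    return FeatureTrack(intervals, name)


def write_track_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(track.intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or f'site_{k}'}\t"
                f"{0 if iv.intensity is None else iv.intensity:.4f}\n"
            )
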