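"""Overlap and enrichment statistics for genomic feature tracks.

Clusters (or single loci) are compared against interval tracks
(ChIP peaks, LADs, chromatin-state segments, ...) with three summary
metrics — proportion of the cluster covered, mean signal intensity per
bp, and number of overlapping sites — and per-locus feature enrichment
is measured along the nestedness axis relative to each locus's top
enclave.  DNA loops (BEDPE anchor pairs) are scored by whether both
anchors land in the same enclave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, MissingFieldError, PreconditionError
from .tree import EnclaveLabels, NestednessMap, PartitionTree

# ---------------------------------------------------------------------------
# tracks


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int
    end: int
    intensity: float | None = None
    name: str | None = None


@dataclass
class FeatureTrack:
    """A list of (possibly mutually overlapping) genomic intervals."""

    intervals: list[FeatureInterval]
    name: str = "track"

    def on_chrom(self, chrom: str) -> "FeatureTrack":
        return FeatureTrack(
            [iv for iv in self.intervals if iv.chrom == chrom], self.name
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([iv.start for iv in self.intervals], dtype=np.int64)
        e = np.array([iv.end for iv in self.intervals], dtype=np.int64)
        return s, e

    def intensities(self) -> np.ndarray:
        if any(iv.intensity is None for iv in self.intervals):
            raise MissingFieldError(f"track '{self.name}' lacks intensity values")
        return np.array([iv.intensity for iv in self.intervals], dtype=float)


def read_bed_track(path, name: str | None = None) -> FeatureTrack:
    """Read BED / narrowPeak intervals.

    Columns 1-3 are required.  For narrowPeak (10 columns) the
    signalValue column is used as intensity; for plain BED with a
    numeric column 5 the score is used.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise DegenerateInputError("BED needs at least 3 columns")
    intensities = None
    if df.shape[1] >= 10:  # narrowPeak: signalValue is column 7 (0-based 6)
        intensities = pd.to_numeric(df[6], errors="coerce")
    elif df.shape[1] >= 5:
        intensities = pd.to_numeric(df[4], errors="coerce")
    names = df[3].astype(str) if df.shape[1] >= 4 else None
    ivs = []
    for i in range(len(df)):
        start, end = int(df.iloc[i, 1]), int(df.iloc[i, 2])
        if start >= end:
            raise DegenerateInputError(f"interval {i} has start >= end")
        ivs.append(
            FeatureInterval(
                str(df.iloc[i, 0]), start, end,
                None if intensities is None or pd.isna(intensities.iloc[i])
                else float(intensities.iloc[i]),
                None if names is None else names.iloc[i],
            )
        )
    return FeatureTrack(ivs, name or str(path))


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE loop anchors (6 required columns)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 6:
        raise DegenerateInputError("BEDPE needs at least 6 columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    return df


# ---------------------------------------------------------------------------
# interval arithmetic over a cluster's merged bin intervals


def merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-adjacent sorted-by-start intervals into disjoint ones."""
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms, dtype=np.int64), np.array(me, dtype=np.int64)


def cluster_intervals(loci, bins) -> tuple[np.ndarray, np.ndarray]:
    """Merged genomic intervals spanned by a set of bin indices."""
    by_index = {b.index: b for b in bins}
    starts = np.array([by_index[i].start for i in sorted(loci)], dtype=np.int64)
    ends = np.array([by_index[i].end for i in sorted(loci)], dtype=np.int64)
    return merge_intervals(starts, ends)


def overlap_lengths(
    ms: np.ndarray, me: np.ndarray, site_s: np.ndarray, site_e: np.ndarray
) -> np.ndarray:
    """bp of intersection of each site with a merged disjoint interval set.

    Uses the cumulative-coverage trick: with ``cum[k]`` the total merged
    length left of interval k, coverage in [0, p) is
    ``cum[idx] + clamp(p - ms[idx-...])`` — vectorized over sites via
    searchsorted, so it stays O((n+m) log m) rather than O(n*m).
    """
    if ms.size == 0:
        return np.zeros(site_s.shape, dtype=np.int64)
    lengths = me - ms
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def coverage_before(p: np.ndarray) -> np.ndarray:
        # total merged bp in [0, p)
        idx = np.searchsorted(ms, p, side="right")  # intervals starting before p
        full = cum[np.maximum(idx - 1, 0)]
        partial = np.clip(p - ms[np.maximum(idx - 1, 0)], 0, lengths[np.maximum(idx - 1, 0)])
        return np.where(idx > 0, full + partial, 0)

    return coverage_before(np.asarray(site_e)) - coverage_before(np.asarray(site_s))


# ---------------------------------------------------------------------------
# overlap summaries


@dataclass(frozen=True)
class OverlapSummary:
    cluster_id: str
    bp_cl: int
    metric: str
    value: float


METRICS = ("size", "intensity", "count")


def overlap_summary(
    loci, bins, track: FeatureTrack, metric: str, cluster_id: str = "cluster"
) -> OverlapSummary:
    """One of the three overlap statistics between a cluster and a track.

    * ``size``: sum over sites of the bp overlapped, divided by the
      cluster's bp size — the proportion of the cluster covered (can
      exceed 1 if track intervals overlap one another; sites are summed
      independently, never merged).
    * ``intensity``: same sum with each site's overlap weighted by its
      intensity, per cluster bp.
    * ``count``: number of sites with non-empty intersection.
    """
    if metric not in METRICS:
        raise PreconditionError(f"unknown metric '{metric}'")
    ms, me = cluster_intervals(loci, bins)
    bp_cl = int((me - ms).sum())
    site_s, site_e = track.arrays()
    ov = overlap_lengths(ms, me, site_s, site_e)
    if metric == "size":
        value = float(ov.sum()) / bp_cl
    elif metric == "intensity":
        value = float((ov * track.intensities()).sum()) / bp_cl
    else:
        value = float(np.count_nonzero(ov))
    return OverlapSummary(cluster_id, bp_cl, metric, value)


# ---------------------------------------------------------------------------
# feature enrichment along nestedness


@dataclass(frozen=True)
class EnrichmentResult:
    locus: int
    ns: float
    overlap: float
    fe: float | None  # None when the top-enclave mean overlap is zero
    top_enclave: str | None


def _locus_top_enclave(tree: PartitionTree, labels: EnclaveLabels) -> dict[int, str]:
    mapping: dict[int, str] = {}
    for nid in sorted(labels.top_enclaves):
        for locus in tree.nodes[nid].loci:
            mapping[locus] = nid
    return mapping


def feature_enrichment(
    tree: PartitionTree,
    labels: EnclaveLabels,
    ns_map: NestednessMap,
    track: FeatureTrack,
    metric: str = "count",
) -> list[EnrichmentResult]:
    """Per-locus feature enrichment FE = x_i / mean(x over the locus's
    top enclave).

    Each locus is treated as a one-bin cluster; its overlap statistic is
    normalized by the average over all loci of the same top enclave, so
    trends along nestedness are comparable across enclaves and
    chromosomes.  Loci outside every top enclave, or in a top enclave
    whose mean overlap is zero, are reported with ``fe=None`` and should
    be excluded from trend statistics.
    """
    top_of = _locus_top_enclave(tree, labels)
    track = track.on_chrom(tree.chrom)
    per_locus: dict[int, float] = {}
    for locus in sorted(tree.universe):
        per_locus[locus] = overlap_summary(
            [locus], tree.bins, track, metric, f"locus_{locus}"
        ).value
    means: dict[str, float] = {}
    for nid in labels.top_enclaves:
        vals = [per_locus[l] for l in tree.nodes[nid].loci]
        means[nid] = float(np.mean(vals)) if vals else 0.0
    results = []
    for locus in sorted(tree.universe):
        top = top_of.get(locus)
        fe = None
        if top is not None and means[top] > 0:
            fe = per_locus[locus] / means[top]
        results.append(
            EnrichmentResult(locus, ns_map.locus_ns[locus], per_locus[locus], fe, top)
        )
    return results


# ---------------------------------------------------------------------------
# Poisson ratio test


@dataclass(frozen=True)
class PoissonRatioResult:
    rate_ratio: float
    p_value: float


def poisson_ratio_test(
    observed: int, observed_exposure: float, expected_rate: float
) -> PoissonRatioResult:
    """Exact two-sided test of an observed count against a Poisson rate.

    The null mean is ``expected_rate * observed_exposure``; the two-sided
    P-value sums the probability of all outcomes no more likely than the
    observed one (the minimum-likelihood convention, with the customary
    (1 + 1e-7) slack on the observed probability).
    """
    if observed_exposure <= 0:
        raise PreconditionError("exposure must be positive")
    if expected_rate < 0:
        raise PreconditionError("expected rate must be non-negative")
    mu = expected_rate * observed_exposure
    if mu == 0:
        # degenerate null: any positive count is infinitely surprising
        return PoissonRatioResult(np.inf if observed > 0 else 1.0,
                                  0.0 if observed > 0 else 1.0)
    ratio = observed / mu
    kmax = int(max(observed, mu + 20 * np.sqrt(mu) + 20)) + 1
    k = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(k, mu)
    d = stats.poisson.pmf(observed, mu) * (1 + 1e-7)
    p = float(pmf[pmf <= d].sum()) + float(stats.poisson.sf(kmax, mu))
    return PoissonRatioResult(float(ratio), min(1.0, p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def ns_bin_poisson_tests(
    enrichment: list[EnrichmentResult],
    bin_bp: int,
    track: FeatureTrack,
    genome_bp: int,
    n_ns_bins: int = 5,
) -> pd.DataFrame:
    """Poisson ratio tests of overlap counts within nestedness bins.

    Loci are grouped into ``n_ns_bins`` equal-width nestedness bins; in
    each, the summed overlap count is tested against the genome-wide
    site rate (sites per bp times the bin group's total bp).  P-values
    are BH-adjusted across bins.
    """
    rate = len(track.intervals) / genome_bp  # genome-wide sites per bp
    edges = np.linspace(0, 1, n_ns_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [
            e for e in enrichment
            if (e.ns >= lo and (e.ns < hi or hi == 1.0 and e.ns <= 1.0))
        ]
        if not members:
            continue
        observed = int(sum(e.overlap for e in members))
        exposure = bin_bp * len(members)
        res = poisson_ratio_test(observed, exposure, rate)
        rows.append(
            {"ns_lo": lo, "ns_hi": hi, "n_loci": len(members),
             "observed": observed, "rate_ratio": res.rate_ratio,
             "p_value": res.p_value}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# FE significance threshold


def fe_significance_threshold(null_fe) -> float:
    """Significance cutoff for enrichment values: 75th percentile of the
    null distribution plus twice its interquartile range.  Values
    strictly above the returned threshold are called significant."""
    null_fe = np.asarray(list(null_fe), dtype=float)
    if null_fe.size == 0:
        raise PreconditionError("empty null sample")
    if null_fe.size < 20:
        import warnings

        warnings.warn("fewer than 20 null values; threshold is unstable")
    q25, q75 = np.percentile(null_fe, [25, 75])
    return float(q75 + 2.0 * (q75 - q25))


# ---------------------------------------------------------------------------
# DNA loop integration


def _assign_anchor(start, end, enclave_ivs) -> str | None:
    """Enclave with the largest bp overlap with the anchor; ties go to
    the enclave whose intervals start earlier; None when no overlap."""
    best, best_ov, best_start = None, 0, None
    for nid in sorted(enclave_ivs):
        ms, me = enclave_ivs[nid]
        ov = int(
            overlap_lengths(ms, me, np.array([start]), np.array([end]))[0]
        )
        if ov > best_ov or (
            ov == best_ov and ov > 0 and best_start is not None and ms[0] < best_start
        ):
            best, best_ov, best_start = nid, ov, int(ms[0])
    return best


def loop_integration(
    loops: pd.DataFrame,
    tree: PartitionTree,
    labels: EnclaveLabels,
    level: str = "bottom",
) -> tuple[float, pd.DataFrame]:
    """Percentage of DNA loops with both anchors in the same enclave.

    Each anchor is assigned to the enclave its interval overlaps most
    (in bp); a loop is integrated when both anchors are assigned to the
    same single enclave.  Returns the percentage and the per-loop table.
    """
    chosen = {"bottom": labels.bottom_enclaves, "top": labels.top_enclaves}[level]
    enclave_ivs = {
        nid: cluster_intervals(tree.nodes[nid].loci, tree.bins) for nid in chosen
    }
    rows = []
    for _, row in loops.iterrows():
        e1 = _assign_anchor(row.start1, row.end1, enclave_ivs) \
            if row.chrom1 == tree.chrom else None
        e2 = _assign_anchor(row.start2, row.end2, enclave_ivs) \
            if row.chrom2 == tree.chrom else None
        integrated = e1 is not None and e1 == e2
        rows.append(
            {"start1": row.start1, "end1": row.end1, "enclave1": e1,
             "start2": row.start2, "end2": row.end2, "enclave2": e2,
             "integrated": integrated}
        )
    table = pd.DataFrame(rows)
    pct = 100.0 * table.integrated.mean() if len(table) else float("nan")
    return float(pct), table
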