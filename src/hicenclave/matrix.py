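"""Contact-matrix I/O and normalization.

A per-chromosome Hi-C contact map is held as a dense symmetric matrix over
equally sized genomic bins.  The module reads the sparse triple ("dump")
dialect emitted by common Hi-C extraction tools, drops unmappable bins
(zero total signal), and provides the two normalization stages applied
before spectral clustering: Knight–Ruiz-style matrix balancing and a
per-chromosome Box–Cox variance-stabilizing transform.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    FormatError,
    ParseError,
    PreconditionError,
)

STAGE_RAW = "raw"
STAGE_KR = "kr_normalized"
STAGE_BOXCOX = "boxcox_scaled"

DEFAULT_LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)


@dataclass(frozen=True)
class GenomicBin:
    """One equally sized genomic bin (0-based, half-open coordinates)."""

    chrom: str
    start: int
    end: int
    index: int


@dataclass
class ContactMatrix:
    """Symmetric non-negative interaction matrix over retained bins.

    ``weights[i, j]`` is the interaction weight between bins ``i`` and
    ``j`` (dense ``float64``).  ``stage`` records which normalization
    steps have been applied.  ``dropped_starts`` lists genomic start
    coordinates of bins removed as unmappable.
    """

    bins: list[GenomicBin]
    weights: np.ndarray
    resolution: int
    chrom: str
    stage: str = STAGE_RAW
    dropped_starts: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.bins)

    def bin_starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bins], dtype=np.int64)

    def validate(self) -> None:
        w = self.weights
        if w.shape != (self.n, self.n):
            raise FormatError("weights shape does not match number of bins")
        if self.n < 2:
            raise DegenerateInputError("fewer than 2 retained bins")
        if not np.allclose(w, w.T):
            raise FormatError("weights matrix is not symmetric")
        if np.any(w < 0):
            raise FormatError("weights matrix has negative entries")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def read_sparse_triples(path, resolution: int, chrom: str) -> ContactMatrix:
    """Read a sparse triple dump ``(pos_i, pos_j, value)`` into a matrix.

    Positions are genomic bin start coordinates and must be multiples of
    ``resolution``.  Upper-triangular and full dumps are both accepted;
    duplicate (i, j)/(j, i) entries are summed into a single symmetric
    entry.  Bins whose total weight (diagonal included) is zero are
    treated as unmappable and removed; their start coordinates are kept
    in ``dropped_starts``.
    """
    if resolution <= 0:
        raise FormatError("resolution must be positive")
    entries: dict[tuple[int, int], float] = {}
    max_bin = -1
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"expected 3 fields, got {len(parts)}", lineno)
            try:
                pi, pj = int(float(parts[0])), int(float(parts[1]))
                value = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", lineno) from None
            if pi % resolution or pj % resolution:
                raise FormatError(
                    f"line {lineno}: position not a multiple of "
                    f"resolution {resolution}: ({pi}, {pj})"
                )
            if pi < 0 or pj < 0:
                raise FormatError(f"line {lineno}: negative position")
            if not np.isfinite(value) or value < 0:
                raise FormatError(f"line {lineno}: invalid weight {value}")
            bi, bj = pi // resolution, pj // resolution
            key = (bi, bj) if bi <= bj else (bj, bi)
            entries[key] = entries.get(key, 0.0) + value
            max_bin = max(max_bin, bi, bj)
    if max_bin < 0:
        raise DegenerateInputError("no triples found in input")

    n_full = max_bin + 1
    w = np.zeros((n_full, n_full), dtype=np.float64)
    for (bi, bj), value in entries.items():
        w[bi, bj] += value
        if bi != bj:
            w[bj, bi] += value

    keep = w.sum(axis=1) > 0
    dropped = [int(i) * resolution for i in np.nonzero(~keep)[0]]
    if keep.sum() < 2:
        raise DegenerateInputError(
            f"only {int(keep.sum())} retained bins after dropping unmapped bins"
        )
    w = w[np.ix_(keep, keep)]
    bins = [
        GenomicBin(chrom, int(i) * resolution, (int(i) + 1) * resolution, k)
        for k, i in enumerate(np.nonzero(keep)[0])
    ]
    m = ContactMatrix(bins, w, resolution, chrom, STAGE_RAW, dropped)
    m.validate()
    return m


def write_sparse_triples(m: ContactMatrix, path) -> None:
    """Write the upper triangle (diagonal included) as sparse triples."""
    starts = m.bin_starts()
    path = str(path)
    opener = gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")
    with opener as fh:
        iu, ju = np.nonzero(np.triu(m.weights))
        for i, j in zip(iu, ju):
            fh.write(f"{starts[i]}\t{starts[j]}\t{m.weights[i, j]:.10g}\n")


def write_bins_bed(m: ContactMatrix, path) -> None:
    """Write the retained-bin table as BED (chrom, start, end, index)."""
    with open(path, "w") as fh:
        for b in m.bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.index}\n")


def kr_balance(
    m: ContactMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> ContactMatrix:
    """Balance the matrix so every row sum is equal.

    Symmetric diagonal scaling ``diag(x) W diag(x)`` found by fixed-point
    iteration (Sinkhorn–Knopp style), correcting locus-specific coverage
    bias.  Convergence is declared when the relative spread of row sums
    falls below ``tol``.  The overall scale is chosen so total weight is
    preserved.
    """
    if m.stage != STAGE_RAW:
        raise PreconditionError(f"kr_balance expects stage '{STAGE_RAW}', got '{m.stage}'")
    w = m.weights
    rowsums = w.sum(axis=1)
    if np.any(rowsums <= 0):
        bad = int(np.nonzero(rowsums <= 0)[0][0])
        raise PreconditionError(f"zero-weight row at bin index {bad}; drop unmapped bins first")

    x = np.ones(m.n)
    target = rowsums.mean()
    residual = np.inf
    for _ in range(max_iter):
        s = x * (w @ x)  # row sums of diag(x) W diag(x)
        residual = float(np.max(np.abs(s - s.mean())) / s.mean())
        if residual < tol:
            break
        x *= np.sqrt(target / s)
    else:
        raise ConvergenceError(
            f"balancing did not converge in {max_iter} iterations", residual
        )
    balanced = (w * x[:, None]) * x[None, :]
    balanced *= w.sum() / balanced.sum()  # preserve total weight
    balanced = 0.5 * (balanced + balanced.T)
    return replace(m, weights=balanced, stage=STAGE_KR)


@dataclass(frozen=True)
class BoxCoxFit:
    """Chromosome-specific Box–Cox fit: selected lambda and its profile."""

    lambda_: float
    log_likelihood_profile: list[tuple[float, float]]


def boxcox_scale(
    m: ContactMatrix, lambda_grid=DEFAULT_LAMBDA_GRID
) -> tuple[ContactMatrix, BoxCoxFit]:
    """Box–Cox-scale the positive entries toward normality.

    The scaling exponent lambda is chosen by maximizing the Box–Cox
    profile log-likelihood over ``lambda_grid``, fitted on the strictly
    positive upper-triangle entries (each symmetric pair counted once).
    Structural zeros — absent contacts — are left at zero.  If the
    transform produces negative values (possible for lambda <= 0) all
    transformed entries are shifted to be strictly positive, preserving
    order, so downstream graph weights stay non-negative.
    """
    if m.stage != STAGE_KR:
        raise PreconditionError(
            f"boxcox_scale expects stage '{STAGE_KR}', got '{m.stage}'"
        )
    grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    w = m.weights
    triu_i, triu_j = np.triu_indices(m.n)
    vals = w[triu_i, triu_j]
    pos = vals[vals > 0]
    if pos.size == 0:
        raise DegenerateInputError("matrix has no positive entries to scale")

    profile = [(float(l), float(stats.boxcox_llf(l, pos))) for l in grid]
    lam = float(max(profile, key=lambda p: p[1])[0])

    out = np.zeros_like(w)
    mask = w > 0
    out[mask] = special.boxcox(w[mask], lam)
    mn = out[mask].min() if mask.any() else 0.0
    if mn < 0:
        eps = np.sqrt(np.finfo(float).eps) * max(1.0, -mn)
        out[mask] += -mn + eps
    out = 0.5 * (out + out.T)
    return replace(m, weights=out, stage=STAGE_BOXCOX), BoxCoxFit(lam, profile)
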