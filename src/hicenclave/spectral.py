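"""Spectral bisection of a weighted loci graph.

One step of the recursive decomposition: build the random-walk
normalized Laplacian L = I - D^{-1} W of the (sub)graph, extract the
eigenvector of the second-smallest eigenvalue (the Fiedler vector), and
split the loci with a consensus 1-D 2-means over several seedings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans

from .errors import DegenerateSplitError, PreconditionError

# below this size a dense solve is faster and more robust than shift-invert
_DENSE_CUTOFF = 500
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class Bisection:
    """Result of one spectral bisection.

    ``part_a`` holds the loci on the low-coordinate side of the Fiedler
    vector, ``part_b`` the rest; indices are local to the matrix that was
    bisected.
    """

    part_a: frozenset[int]
    part_b: frozenset[int]
    fiedler_value: float
    fiedler_vector: np.ndarray


def _degrees(w: np.ndarray) -> np.ndarray:
    # degree includes the diagonal (self-interaction) weight
    d = np.asarray(w, dtype=float).sum(axis=1)
    if np.any(d <= 0):
        bad = int(np.nonzero(d <= 0)[0][0])
        raise PreconditionError(f"locus {bad} has zero degree")
    return d


def random_walk_laplacian(w: np.ndarray) -> np.ndarray:
    """Return L = I - D^{-1} W for a symmetric non-negative weight matrix."""
    w = np.asarray(w, dtype=float)
    d = _degrees(w)
    return np.eye(w.shape[0]) - w / d[:, None]


def fiedler_pair(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Second-smallest eigenvalue of L = I - D^{-1}W and its eigenvector.

    Computed through the symmetric normalized Laplacian
    S = I - D^{-1/2} W D^{-1/2}, which is similar to L: if S u = lam u
    then L (D^{-1/2} u) = lam (D^{-1/2} u).  Dense solve below
    ``_DENSE_CUTOFF`` loci, sparse shift-invert above.  The eigenvector
    sign is canonicalized so its first nonzero coordinate is positive.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise PreconditionError("need at least 2 loci to bisect")
    d = _degrees(w)
    inv_sqrt = 1.0 / np.sqrt(d)
    s = np.eye(n) - (w * inv_sqrt[:, None]) * inv_sqrt[None, :]
    s = 0.5 * (s + s.T)
    if n < _DENSE_CUTOFF:
        vals, vecs = eigh(s, subset_by_index=(0, 1))
    else:
        try:
            vals, vecs = eigsh(csr_matrix(s), k=2, sigma=-1e-6, which="LM", tol=_EIG_TOL)
        except Exception:  # pragma: no cover - rare solver breakdown
            warnings.warn("sparse eigensolver failed; falling back to dense solve")
            vals, vecs = eigh(s, subset_by_index=(0, 1))
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    if abs(vals[1] - vals[0]) < 1e-12 and vals[1] > 1e-12:
        warnings.warn("second eigenvalue has near-multiplicity; split may be arbitrary")
    lam = float(vals[1])
    vec = inv_sqrt * vecs[:, 1]
    nz = np.nonzero(np.abs(vec) > 1e-14)[0]
    if nz.size and vec[nz[0]] < 0:
        vec = -vec
    return lam, vec


def derive_kmeans_seeds(master_seed: int, n_seedings: int) -> list[int]:
    """Derive ``n_seedings`` distinct 2-means seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_seedings)
    return [int(s % (2**31 - 1)) for s in state]


def fiedler_bisect(
    w: np.ndarray, n_seedings: int = 5, master_seed: int = 1234
) -> Bisection:
    """Bisect loci by consensus 2-means on the Fiedler vector.

    2-means is run ``n_seedings`` times with distinct seeds derived from
    ``master_seed``; run labels are aligned by centroid order (lower
    Fiedler coordinate -> part_a) and each locus takes its majority
    label, ties going to the side with the nearer average centroid.
    """
    lam, vec = fiedler_pair(w)
    if float(np.ptp(vec)) < 1e-12:
        raise DegenerateSplitError("all Fiedler coordinates identical")
    coords = vec.reshape(-1, 1)
    votes = np.zeros(len(vec), dtype=int)
    centers = []
    for seed in derive_kmeans_seeds(master_seed, n_seedings):
        km = KMeans(n_clusters=2, n_init=1, random_state=seed).fit(coords)
        c = km.cluster_centers_.ravel()
        labels = km.labels_ if c[0] < c[1] else 1 - km.labels_
        centers.append(np.sort(c))
        votes += labels
    mean_centers = np.mean(centers, axis=0)
    label = votes * 2 > n_seedings
    tied = votes * 2 == n_seedings
    if np.any(tied):
        label[tied] = np.abs(vec[tied] - mean_centers[1]) < np.abs(
            vec[tied] - mean_centers[0]
        )
    part_a = frozenset(int(i) for i in np.nonzero(~label)[0])
    part_b = frozenset(int(i) for i in np.nonzero(label)[0])
    if not part_a or not part_b:  # pragma: no cover - 1-D 2-means guards this
        raise DegenerateSplitError("consensus produced an empty part")
    return Bisection(part_a, part_b, lam, vec)
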