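"""Ordination of distance matrices: classical and nonmetric MDS, UPGMA trees.

Classical (Torgerson) MDS double-centers the squared-distance matrix and
embeds via its top eigenvectors; it is exact for Euclidean-embeddable inputs
and serves as the deterministic initialisation of the nonmetric solver.

Nonmetric MDS minimises Kruskal's stress-1,

    stress-1 = sqrt( Σ (d̂_ij − d_ij)² / Σ d_ij² ),

by alternating a monotone (isotonic) regression of configuration distances on
dissimilarity ranks with a Guttman-transform update (SMACOF).  Stress is
reported ×100, the percent-style convention.

Agglomerative clustering (UPGMA by default) wraps scipy's linkage; the
resulting dendrogram exports Newick with branch lengths from merge heights
and supports cutting into k clusters.  Negative entries (possible for R_ST)
are floored at 0 before ordination, with a log note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression

from .distance_amova import DistanceMatrix

logger = logging.getLogger(__name__)


def floor_negative(D: DistanceMatrix) -> DistanceMatrix:
    """Clamp negative entries to 0 (distances must be non-negative)."""
    v = D.values
    if (v < 0).any():
        logger.info("flooring %d negative distance entries at 0", int((v < 0).sum()))
        v = np.where(v < 0, 0.0, v)
    return DistanceMatrix(D.labels, v)


@dataclass(frozen=True)
class MDSResult:
    coordinates: pd.DataFrame  # labels × k
    stress: float  # stress-1 × 100
    k: int
    converged: bool
    iterations: int
    eigenvalues: np.ndarray | None = None


def _stress1(dhat: np.ndarray, d: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def _config_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _fix_signs(X: np.ndarray) -> np.ndarray:
    # deterministic sign convention: first nonzero coordinate of each axis > 0
    for j in range(X.shape[1]):
        col = X[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            X[:, j] = -col
    return X


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Torgerson double-centering MDS.

    Coordinates come from the top-k non-negative eigenvalues of −½ J D² J; if
    fewer than k are positive the dimension is reduced with a warning.
    """
    Dm = floor_negative(D)
    n = len(Dm.labels)
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < number of labels")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm.values**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > max(1e-12, 1e-12 * abs(w[0]) if w.size else 0)
    k_eff = min(k, int(pos.sum()))
    if k_eff < k:
        logger.warning("only %d positive eigenvalues; reducing k from %d", k_eff, k)
    if k_eff == 0:
        X = np.zeros((n, 1))
        k_eff = 1
    else:
        X = V[:, :k_eff] * np.sqrt(w[:k_eff])
    X = X - X.mean(axis=0)
    X = _fix_signs(X)
    d = _config_distances(X)
    iu = np.triu_indices(n, k=1)
    stress = _stress1(d[iu], Dm.values[iu]) * 100.0
    coords = pd.DataFrame(X, index=Dm.labels,
                          columns=[f"dim{i+1}" for i in range(k_eff)])
    return MDSResult(coords, stress, k_eff, converged=True, iterations=0,
                     eigenvalues=w)


def nonmetric_mds(
    D: DistanceMatrix,
    k: int = 2,
    init: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> MDSResult:
    """Kruskal nonmetric MDS (SMACOF with isotonic disparities).

    Default init is the classical solution (deterministic); pass ``seed`` for
    a random start instead.  Returns stress-1 × 100; ``converged=False`` if
    the iteration cap is hit first.
    """
    Dm = floor_negative(D)
    n = len(Dm.labels)
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < number of labels")
    iu = np.triu_indices(n, k=1)
    diss = Dm.values[iu]
    if init is not None:
        X = np.asarray(init, dtype=float)[:, :k].copy()
    elif seed is not None:
        X = np.random.default_rng(seed).normal(size=(n, k))
    else:
        c = classical_mds(Dm, k)
        X = np.zeros((n, k))
        X[:, : c.k] = c.coordinates.to_numpy()
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    stress_prev = np.inf
    stress = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d = _config_distances(X)[iu]
        # monotone regression of distances on dissimilarity ranks
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(d.size), d[order])
        # scale disparities to Σd̂² = Σd² (removes the trivial shrink direction)
        ssd = (d**2).sum()
        if (dhat**2).sum() > 0:
            dhat = dhat * np.sqrt(ssd / (dhat**2).sum())
        stress = _stress1(dhat, d)
        if stress_prev - stress < tol:
            converged = True
            break
        stress_prev = stress
        # Guttman transform toward the disparities
        W = np.zeros((n, n))
        ratio = np.where(d > 1e-12, dhat / np.maximum(d, 1e-12), 0.0)
        W[iu] = ratio
        W = W + W.T
        B = -W
        np.fill_diagonal(B, W.sum(axis=1))
        X = B @ X / n
        X = X - X.mean(axis=0)
    X = _fix_signs(X - X.mean(axis=0))
    coords = pd.DataFrame(X, index=Dm.labels,
                          columns=[f"dim{i+1}" for i in range(k)])
    return MDSResult(coords, stress * 100.0, k, converged, it)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree over labels, backed by a scipy linkage matrix."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment at exactly k clusters."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def newick(self) -> str:
        """Newick string; branch lengths are differences of node heights.

        For UPGMA the node height is half the merge distance (ultrametric).
        """
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: f"{self.labels[i]}" for i in range(n)}
        for idx, (a, b, dist, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            h = dist / 2.0
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            new = n + idx
            node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[new] = h
        return node[n + len(self.linkage) - 1] + ";"


def upgma(D: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering (average = UPGMA by default; also complete,
    ward).  Ties are resolved deterministically by scipy's ordering."""
    if linkage not in {"average", "complete", "ward", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    Dm = floor_negative(D)
    Z = hierarchy.linkage(squareform(Dm.values, checks=False), method=linkage)
    return Dendrogram(Dm.labels, Z, linkage)
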