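"""Structural connectome construction and Laplacian eigendecomposition.

The structural connectome is an undirected, weighted graph ``C = {c_lm}`` of
white-matter connection strengths between brain regions.  The model's spatial
basis is the eigensystem of the coupling-scaled Laplacian

    L(alpha) = I - alpha * C,

whose eigenvectors are those of ``C`` itself (alpha-invariant) while the
eigenvalues transform affinely, ``lambda_k(alpha) = 1 - alpha * mu_k`` for the
connectome eigenvalues ``mu_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StructuralConnectome",
    "LaplacianEigens",
    "normalize_connectome",
    "augment_homologous",
    "build_laplacian",
    "eigendecompose",
    "scale_to_critical_coupling",
]

_SYM_TOL = 1e-10


@dataclass
class StructuralConnectome:
    """Symmetric, nonnegative, sum-normalized region-by-region weight matrix.

    Parameters
    ----------
    weights
        Square symmetric matrix with zero diagonal whose entries sum to one
        (arbitrary units after normalization).
    region_labels
        Ordered region identifiers, one per row of ``weights``.
    homolog_map
        Optional pairs of laterally homologous (left, right) region indices.
    adjacency_map
        Optional pairs of spatially adjacent region indices.
    """

    weights: np.ndarray
    region_labels: list = field(default_factory=list)
    homolog_map: list | None = None
    adjacency_map: list | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.region_labels:
            self.region_labels = [f"region_{i}" for i in range(self.n_regions)]
        if len(self.region_labels) != self.n_regions:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.n_regions} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class LaplacianEigens:
    """Eigensystem of ``L(alpha) = I - alpha C``.

    Eigenvalues are sorted ascending; columns of ``eigenvectors`` are the
    orthonormal eigenmodes in matching order.  ``connectome_eigenvalues`` are
    the eigenvalues ``mu_k`` of ``C`` so ``lambda_k = 1 - alpha * mu_k``.
    """

    alpha: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    connectome_eigenvalues: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.eigenvectors.shape[0]

    def with_alpha(self, alpha: float) -> "LaplacianEigens":
        """Re-evaluate the eigenvalues at a new coupling constant.

        The eigenvectors do not depend on ``alpha``; only the eigenvalues do.
        """
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        return replace(
            self,
            alpha=float(alpha),
            eigenvalues=1.0 - alpha * self.connectome_eigenvalues,
        )

    def laplacian(self) -> np.ndarray:
        lam = self.eigenvalues
        return (self.eigenvectors * lam) @ self.eigenvectors.T


def _check_connected(weights: np.ndarray, labels=None) -> None:
    n_comp, membership = connected_components(weights != 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(membership)
        small = int(np.argmin(sizes))
        idx = np.flatnonzero(membership == small)
        names = [labels[i] for i in idx] if labels else idx.tolist()
        raise ValueError(
            f"connectome graph is disconnected: isolated component {names}"
        )


def normalize_connectome(
    raw_weights: np.ndarray,
    region_labels: list | None = None,
    homolog_map: list | None = None,
    adjacency_map: list | None = None,
) -> StructuralConnectome:
    """Symmetrize, zero the diagonal, and normalize by the sum of all entries.

    The raw matrix is replaced by ``(A + A.T) / 2``, the diagonal is removed,
    and the result is scaled so that all entries sum to one, giving every
    subject's connectome the same total weight in arbitrary units.

    Raises
    ------
    ValueError
        If the matrix is not square, contains negative or non-finite entries,
        is all-zero, or its nonzero graph is disconnected (the error names the
        isolated component).
    """
    w = np.asarray(raw_weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome matrix must be square, got shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError("connectome matrix contains non-finite entries")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("connectome weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("connectome has no positive connection weights")
    _check_connected(w, region_labels)
    return StructuralConnectome(
        weights=w / total,
        region_labels=list(region_labels) if region_labels else [],
        homolog_map=list(homolog_map) if homolog_map is not None else None,
        adjacency_map=list(adjacency_map) if adjacency_map is not None else None,
    )


def augment_homologous(
    sc: StructuralConnectome,
    fraction: float = 0.05,
    include_adjacency: bool = False,
) -> StructuralConnectome:
    """Add weak interhemispheric edges between laterally homologous regions.

    Tractography systematically under-reconstructs interhemispheric fibers, so
    each homologous pair receives an extra ``fraction`` of the typical
    connection weight (the mean of nonzero entries).  With
    ``include_adjacency``, spatially adjacent pairs are augmented identically.
    The result is re-normalized to sum one.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if sc.homolog_map is None:
        raise ValueError("augment_homologous requires a homolog_map")
    if fraction == 0:
        return sc
    w = sc.weights.copy()
    n = sc.n_regions
    nonzero = w[w > 0]
    bump = fraction * nonzero.mean()
    pairs = list(sc.homolog_map)
    if include_adjacency:
        if sc.adjacency_map is None:
            raise ValueError("include_adjacency requires an adjacency_map")
        pairs = pairs + list(sc.adjacency_map)
    for l, m in pairs:
        if not (0 <= l < n and 0 <= m < n) or l == m:
            raise ValueError(f"invalid region pair ({l}, {m})")
        w[l, m] += bump
        w[m, l] += bump
    return normalize_connectome(
        w, sc.region_labels, sc.homolog_map, sc.adjacency_map
    )


def scale_to_critical_coupling(sc: StructuralConnectome) -> StructuralConnectome:
    """Rescale the weights so the connectome's largest eigenvalue is 1.

    Under this convention the coupling constant measures the fraction of the
    critical coupling: ``L(alpha) = I - alpha C`` loses positive definiteness
    exactly at ``alpha = 1``.  Sum-normalization alone leaves the spectral
    radius at O(1/N), where the coupling term is negligible at any plausible
    ``alpha``; all model-facing workflows therefore apply this scaling before
    eigendecomposition.  Idempotent.
    """
    mu_max = float(np.linalg.eigvalsh(sc.weights).max())
    if mu_max <= 0:
        raise ValueError("connectome has no positive eigenvalue")
    return replace(sc, weights=sc.weights / mu_max)


def build_laplacian(sc: StructuralConnectome | np.ndarray, alpha: float) -> np.ndarray:
    """Return ``L(alpha) = I - alpha C``."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    c = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc, float)
    return np.eye(c.shape[0]) - alpha * c


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (sign convention)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


def eigendecompose(
    sc: StructuralConnectome | np.ndarray, alpha: float
) -> LaplacianEigens:
    """Hermitian eigendecomposition of ``L(alpha)`` via the connectome.

    ``C`` is decomposed once; ``lambda_k(alpha) = 1 - alpha mu_k`` is reported
    sorted ascending (stable in the original index on ties) with eigenvector
    columns re-ordered consistently and signs fixed so the largest-magnitude
    entry of each column is positive.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    c = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc, float)
    if not np.all(np.isfinite(c)):
        raise ValueError("cannot eigendecompose: non-finite entries")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("connectome must be symmetric")
    mu, u = np.linalg.eigh(0.5 * (c + c.T))
    # descending mu <=> ascending lambda for any alpha > 0; the same order is
    # kept at alpha = 0 so the basis never depends on alpha
    order = np.argsort(-mu, kind="stable")
    mu = mu[order]
    u = _fix_signs(u[:, order])
    return LaplacianEigens(
        alpha=float(alpha),
        eigenvalues=1.0 - alpha * mu,
        eigenvectors=u,
        connectome_eigenvalues=mu,
    )
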