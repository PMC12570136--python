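"""Conformational ensemble analysis: clustering, essential dynamics, DCCM.

GROMOS clustering is the greedy neighbor-count algorithm of Daura et al.:
on a pairwise-RMSD matrix, the conformation with the most neighbors
within the cutoff seeds a cluster, the cluster is removed, and the
process repeats.  PCA (essential dynamics) diagonalizes the covariance
of superposed Cartesian coordinates; the dynamical cross-correlation
matrix (DCCM) normalizes displacement-vector covariances into [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose, _analysis_window, _fitted_coordinates
from .selection import Selection
from .trajectory import Trajectory

__all__ = [
    "ClusterAssignment",
    "PCAModel",
    "DensityGrid",
    "CorrelationMatrix",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "pca_fit",
    "pca_project",
    "hexbin_density",
    "dccm",
]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: np.ndarray        # per-conformation cluster id, 1-based
    centroid_ids: np.ndarray  # conformation index per cluster
    sizes: np.ndarray         # per-cluster member counts, non-increasing

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray               # flattened (3N,) mean coordinates, nm
    eigenvalues: np.ndarray        # non-negative, non-increasing, nm^2
    eigenvectors: np.ndarray       # orthonormal rows, (n_modes, 3N)
    variance_fractions: np.ndarray
    reference: np.ndarray          # fitting reference (N, 3)
    weights: np.ndarray            # fitting weights (masses)


@dataclass(frozen=True)
class DensityGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    densities: np.ndarray  # normalized to max 1


@dataclass(frozen=True)
class CorrelationMatrix:
    matrix: np.ndarray
    labels: np.ndarray  # residue indices of the selected atoms


def pairwise_rmsd_matrix(
    conformations: list[np.ndarray] | np.ndarray,
    selection: Selection | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Symmetric matrix of (optionally superposed) pairwise RMSDs."""
    confs = [np.asarray(c, dtype=float) for c in conformations]
    if len(confs) < 2:
        raise ValueError("need at least 2 conformations")
    shape = confs[0].shape
    if any(c.shape != shape for c in confs):
        raise ValueError("all conformations must share one atom count")
    if selection is not None:
        confs = [c[selection.indices] for c in confs]
    n = len(confs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fit:
                r = kabsch_superpose(confs[j], confs[i]).rmsd
            else:
                r = float(np.sqrt(np.mean(np.sum((confs[j] - confs[i]) ** 2, axis=1))))
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(rmsd_matrix: np.ndarray, cutoff: float) -> ClusterAssignment:
    """Greedy neighbor-count clustering on a pairwise distance matrix.

    Neighborhood uses a strict `< cutoff` test.  Ties in neighbor count are
    broken toward the lowest conformation index.  Cluster ids are 1-based
    and ordered by decreasing size (extraction order breaks size ties).
    """
    mat = np.asarray(rmsd_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("rmsd matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("rmsd matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = mat.shape[0]
    remaining = np.ones(n, dtype=bool)
    adj = mat < cutoff
    np.fill_diagonal(adj, False)

    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = np.where(remaining, (adj & remaining[None, :]).sum(axis=1), -1)
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(remaining & (adj[centroid] | (np.arange(n) == centroid)))[0]
        clusters.append((centroid, members))
        remaining[members] = False

    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k][1]), k))
    labels = np.zeros(n, dtype=int)
    centroid_ids = np.empty(len(clusters), dtype=int)
    sizes = np.empty(len(clusters), dtype=int)
    for rank, k in enumerate(order, start=1):
        centroid, members = clusters[k]
        labels[members] = rank
        centroid_ids[rank - 1] = centroid
        sizes[rank - 1] = len(members)
    return ClusterAssignment(labels=labels, centroid_ids=centroid_ids, sizes=sizes)


def _superposed_window(
    trajectory: Trajectory,
    selection: Selection,
    discard,
    fit: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = selection.indices
    if len(idx) < 1:
        raise ValueError("selection must contain at least 1 atom")
    window = _analysis_window(trajectory.n_frames, discard)
    coords = trajectory.coordinate_array()[window][:, idx, :]
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 analyzed frames")
    masses = trajectory.topology.masses[idx]
    if fit and len(idx) >= 3:
        coords = _fitted_coordinates(coords, coords[0], masses)
    labels = np.array(
        [trajectory.topology.atoms[i].residue_index for i in idx], dtype=int
    )
    return coords, masses, labels


def pca_fit(
    trajectory: Trajectory,
    selection: Selection,
    discard: int | tuple[int, int] | None = None,
    fit: bool = True,
) -> PCAModel:
    """Essential dynamics: diagonalize the positional covariance matrix.

    Frames are superposed onto the first analyzed frame; the covariance of
    the flattened coordinates about their mean is diagonalized and the
    eigenpairs are sorted by decreasing eigenvalue.
    """
    coords, masses, _ = _superposed_window(trajectory, selection, discard, fit)
    nf = coords.shape[0]
    flat = coords.reshape(nf, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / nf
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    trace = evals.sum()
    fractions = evals / trace if trace > 0 else np.zeros_like(evals)
    return PCAModel(
        mean=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fractions=fractions,
        reference=coords[0],
        weights=masses,
    )


def pca_project(
    model: PCAModel,
    trajectory: Trajectory,
    selection: Selection,
    components: int = 2,
    discard: int | tuple[int, int] | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Project (superposed, centered) frames onto the first k eigenvectors."""
    if components > model.eigenvectors.shape[0]:
        raise ValueError(
            f"{components} components requested, model stores "
            f"{model.eigenvectors.shape[0]}"
        )
    idx = selection.indices
    window = _analysis_window(trajectory.n_frames, discard)
    coords = trajectory.coordinate_array()[window][:, idx, :]
    if coords.reshape(coords.shape[0], -1).shape[1] != model.mean.shape[0]:
        raise ValueError("selection incompatible with the fitted model")
    if fit and len(idx) >= 3:
        coords = _fitted_coordinates(coords, model.reference, model.weights)
    centered = coords.reshape(coords.shape[0], -1) - model.mean
    return centered @ model.eigenvectors[:components].T


def hexbin_density(projections: np.ndarray, bins: int = 40) -> DensityGrid:
    """2D histogram of PC1/PC2 projections, normalized to max density 1.

    Rectangular bins are used for computation; hexagonal binning is a
    presentation choice applied only at plot time.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2 or pts.shape[0] < 1:
        raise ValueError("projections must be a non-empty (n, >=2) array")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins)
    peak = counts.max()
    densities = counts / peak if peak > 0 else counts
    return DensityGrid(x_edges=xe, y_edges=ye, densities=densities)


def dccm(
    trajectory: Trajectory,
    selection: Selection,
    discard: int | tuple[int, int] | None = None,
    fit: bool = True,
) -> CorrelationMatrix:
    """Dynamical cross-correlation matrix of atomic displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the
    displacement from the mean position after superposition.  Atoms with
    zero variance get zeroed rows/columns (diagonal kept at 1) and a
    warning.
    """
    coords, _, labels = _superposed_window(trajectory, selection, discard, fit)
    mean = coords.mean(axis=0)
    disp = coords - mean                        # (nf, na, 3)
    inner = np.einsum("tia,tja->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    zero = var < 1e-18  # nm^2; numerically indistinguishable from a static atom
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance atom(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    mat = inner / norm
    mat[zero, :] = 0.0
    mat[:, zero] = 0.0
    np.fill_diagonal(mat, 1.0)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(matrix=mat, labels=labels)
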