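"""Fisher-z functional connectomes and canonical edge vectors.

Edge order is fixed as the row-major upper triangle:
(0,1), (0,2), ..., (0,K-1), (1,2), ..., (K-2,K-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .maskparc import Parcellation
from .preprocess import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "edge_index_pairs",
    "n_edges_for",
    "node_timeseries",
    "connectivity_matrix",
    "fisher_z",
    "vectorize_edges",
    "devectorize_edges",
]

_R_CLAMP = 1.0 - 1e-7


def n_edges_for(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_index_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index pairs (i, j), i < j, in canonical edge order."""
    return np.triu_indices(n_nodes, k=1)


@dataclass
class Connectome:
    """Symmetric Fisher-z matrix with zero diagonal and its edge-vector view."""

    z_matrix: np.ndarray
    n_frames_used: int = 0

    def __post_init__(self) -> None:
        self.z_matrix = np.asarray(self.z_matrix, dtype=float)
        k = self.z_matrix.shape[0]
        if self.z_matrix.shape != (k, k):
            raise ValueError("z_matrix must be square")
        if not np.allclose(self.z_matrix, self.z_matrix.T, atol=1e-10):
            raise ValueError("z_matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.z_matrix.shape[0]

    @property
    def edge_vector(self) -> np.ndarray:
        return vectorize_edges(self.z_matrix)

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.z_matrix, delimiter="\t")


def node_timeseries(ts: TimeSeries, parc: Parcellation) -> TimeSeries:
    """Average voxel channels into node signals, per retained frame.

    Channel ``c`` of ``ts`` is the voxel at position ``c`` of the
    parcellation's in-mask voxel ordering (``np.argwhere`` order over the
    label volume's nonzero voxels).
    """
    lab = parc.labels.values
    voxel_labels = lab[lab > 0]  # argwhere / C order
    if len(voxel_labels) != ts.n_channels:
        raise ValueError(
            f"time series has {ts.n_channels} channels but parcellation has "
            f"{len(voxel_labels)} in-mask voxels"
        )
    k = parc.n_nodes
    out = np.empty((ts.n_frames, k))
    for node in range(1, k + 1):
        members = voxel_labels == node
        if not members.any():
            raise ValueError(f"node {node} has no voxels")
        out[:, node - 1] = ts.values[:, members].mean(axis=1)
    return TimeSeries(values=out, tr_seconds=ts.tr_seconds,
                      frame_retained=ts.frame_retained.copy())


def connectivity_matrix(node_ts: TimeSeries) -> np.ndarray:
    """Pearson correlation matrix over retained frames only."""
    values = node_ts.retained_values()
    if values.shape[0] < 3:
        raise ValueError("need at least 3 retained frames for correlation")
    variances = values.var(axis=0)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {dead.tolist()}")
    return np.corrcoef(values, rowvar=False)


def fisher_z(r_matrix: np.ndarray, n_frames_used: int = 0) -> Connectome:
    """Elementwise arctanh with zero diagonal; |r| = 1 clamped with a warning."""
    r = np.asarray(r_matrix, dtype=float).copy()
    np.fill_diagonal(r, 0.0)
    if (np.abs(r) >= 1.0).any():
        logger.warning("correlations at |r| >= 1 clamped to %.7f", _R_CLAMP)
        r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return Connectome(z_matrix=z, n_frames_used=n_frames_used)


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle (row-major) edge vector of a symmetric matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu, ju = edge_index_pairs(matrix.shape[0])
    return matrix[iu, ju]


def devectorize_edges(edge_vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; diagonal restored as zero."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    if len(edge_vector) != n_edges_for(n_nodes):
        raise ValueError(
            f"edge vector length {len(edge_vector)} does not match n_nodes={n_nodes}"
        )
    out = np.zeros((n_nodes, n_nodes))
    iu, ju = edge_index_pairs(n_nodes)
    out[iu, ju] = edge_vector
    out[ju, iu] = edge_vector
    return out
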