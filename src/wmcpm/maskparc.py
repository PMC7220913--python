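"""Group mask construction and equal-size spatial parcellation.

Thresholds are inclusive (>=).  The parcellation is a spatially constrained,
size-balanced k-means on voxel coordinates with a contiguity repair pass;
it is deterministic given its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Volume3D",
    "Parcellation",
    "individual_wm_mask",
    "group_wm_mask",
    "remove_labeled_regions",
    "parcellate",
    "assign_networks",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class Volume3D:
    """A 3-D grid of values with a grid-to-world transform."""

    values: np.ndarray
    affine: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("Volume3D expects a 3-D array")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "Volume3D") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine),
                 str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume3D":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(values=np.asarray(img.dataobj), affine=img.affine)


@dataclass
class Parcellation:
    """Integer label volume (0 background, 1..K nodes) with network assignments."""

    labels: Volume3D
    network_of_node: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.labels.values
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_nodes(self) -> int:
        return int(self.labels.values.max())

    @property
    def node_sizes(self) -> np.ndarray:
        """Voxel count per node, index 0 = node 1."""
        return np.bincount(self.labels.values.ravel(), minlength=self.n_nodes + 1)[1:]

    def node_voxels(self, node: int) -> np.ndarray:
        return np.argwhere(self.labels.values == node)

    def summary_csv(self, path: str | Path) -> None:
        import pandas as pd

        sizes = self.node_sizes
        pd.DataFrame(
            {
                "node": np.arange(1, self.n_nodes + 1),
                "size": sizes,
                "network": [self.network_of_node.get(k, 0) for k in range(1, self.n_nodes + 1)],
            }
        ).to_csv(path, index=False)


def _check_probability(vol: Volume3D) -> None:
    if vol.values.min() < 0 or vol.values.max() > 1:
        raise ValueError("probability volume must lie in [0, 1]")


def individual_wm_mask(prob: Volume3D, threshold: float = 0.90) -> Volume3D:
    """Binary mask of voxels with tissue probability >= threshold (inclusive)."""
    _check_probability(prob)
    return Volume3D(values=(prob.values >= threshold).astype(np.uint8), affine=prob.affine)


def group_wm_mask(masks: list[Volume3D], coverage: float = 0.80) -> Volume3D:
    """Voxels present in at least ``ceil(coverage * n)`` of the individual masks."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    for m in masks[1:]:
        if not m.same_grid(first):
            raise ValueError("mask grids do not match")
    counts = np.sum([m.values.astype(bool) for m in masks], axis=0)
    needed = math.ceil(coverage * len(masks))
    return Volume3D(values=(counts >= needed).astype(np.uint8), affine=first.affine)


def remove_labeled_regions(mask: Volume3D, region_prob: Volume3D,
                           threshold: float = 0.25) -> Volume3D:
    """Remove voxels whose region probability reaches threshold (e.g. subcortex)."""
    if not mask.same_grid(region_prob):
        raise ValueError("mask and region-probability grids do not match")
    _check_probability(region_prob)
    keep = mask.values.astype(bool) & (region_prob.values < threshold)
    return Volume3D(values=keep.astype(np.uint8), affine=mask.affine)


def _farthest_point_init(coords: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    chosen = [int(rng.integers(len(coords)))]
    dist = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[chosen].astype(float)


def _balanced_assign(coords: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Greedy capacity-limited assignment: every cluster gets at most ceil(N/K)."""
    n, k = len(coords), len(centroids)
    cap = math.ceil(n / k)
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=None, kind="stable")
    assignment = np.full(n, -1, dtype=int)
    load = np.zeros(k, dtype=int)
    assigned = 0
    for flat in order:
        voxel, cluster = divmod(int(flat), k)
        if assignment[voxel] >= 0 or load[cluster] >= cap:
            continue
        assignment[voxel] = cluster
        load[cluster] += 1
        assigned += 1
        if assigned == n:
            break
    return assignment


def _repair_contiguity(label_vol: np.ndarray, k: int, max_passes: int = 10) -> np.ndarray:
    """Reassign disconnected fragments of each node to an adjacent node."""
    lab = label_vol.copy()
    for _ in range(max_passes):
        changed = False
        for node in range(1, k + 1):
            comp, n_comp = ndimage.label(lab == node, structure=_FACE_STRUCT)
            if n_comp <= 1:
                continue
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, n_comp + 1):
                if c == keep:
                    continue
                frag = comp == c
                border = ndimage.binary_dilation(frag, structure=_FACE_STRUCT) & ~frag
                neighbor_labels = lab[border]
                neighbor_labels = neighbor_labels[(neighbor_labels > 0)
                                                  & (neighbor_labels != node)]
                if neighbor_labels.size == 0:
                    continue  # isolated fragment stays (disconnected mask)
                target = int(np.bincount(neighbor_labels).argmax())
                lab[frag] = target
                changed = True
        if not changed:
            break
    return lab


def parcellate(mask: Volume3D, K: int = 128, seed: int = 0, n_iter: int = 15) -> Parcellation:
    """Partition a binary mask into K contiguous, roughly equal-size nodes."""
    mask_arr = mask.values.astype(bool)
    coords = np.argwhere(mask_arr)
    n = len(coords)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds mask voxel count {n}")
    rng = np.random.default_rng(seed)
    coords_f = coords.astype(float)
    centroids = _farthest_point_init(coords_f, K, rng)
    assignment = _balanced_assign(coords_f, centroids)
    for _ in range(n_iter):
        new_centroids = np.array(
            [coords_f[assignment == c].mean(axis=0) for c in range(K)]
        )
        if np.allclose(new_centroids, centroids):
            break
        centroids = new_centroids
        assignment = _balanced_assign(coords_f, centroids)

    lab = np.zeros(mask.shape, dtype=int)
    lab[tuple(coords.T)] = assignment + 1
    lab = _repair_contiguity(lab, K)
    return Parcellation(labels=Volume3D(values=lab, affine=mask.affine))


def assign_networks(parc: Parcellation, network_label_volume: Volume3D) -> Parcellation:
    """Assign each node the majority network label among its voxels.

    Ties break to the lowest label id (logged).  A node with no overlapping
    labels is an error.
    """
    if not parc.labels.same_grid(network_label_volume):
        raise ValueError("parcellation and network label grids do not match")
    net = np.asarray(network_label_volume.values).astype(int)
    mapping: dict[int, int] = {}
    for node in range(1, parc.n_nodes + 1):
        labels = net[parc.labels.values == node]
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValueError(f"node {node} overlaps no network labels")
        counts = np.bincount(labels)
        winners = np.flatnonzero(counts == counts.max())
        if len(winners) > 1:
            logger.info("node %d network tie among %s; taking lowest", node, winners.tolist())
        mapping[node] = int(winners[0])
    return Parcellation(labels=parc.labels, network_of_node=mapping)
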