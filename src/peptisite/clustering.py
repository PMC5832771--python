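"""Hierarchical clustering of bound peptide poses.

Poses are compared by all-atom ligand RMSD *without* re-superposition of the
ligand: the frames are assumed to live in the receptor frame already, so
positional differences between binding locations and orientations are the
signal the clustering is meant to separate.

Merge heights are reported as δ(c1, c2) — the square root of the increase
in total within-cluster sum of squares caused by the fusion — so that
merging two singleton poses at configuration distance D gives δ = D/√2.
The common SciPy Ward linkage height h relates to it as δ = h/√2 (h² equals
twice the variance increase); conversion happens internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures import StructuralEnsemble, receptor_calpha_selection

_SQRT2 = np.sqrt(2.0)


def pairwise_ligand_rmsd(bound: StructuralEnsemble,
                         superposition_tolerance: float = 0.75) -> np.ndarray:
    """Symmetric matrix of all-atom ligand RMSDs between frame pairs.

    No further superposition is applied; a rigid translation of the pose by
    d Å therefore yields an RMSD of exactly d. Emits a warning when the
    receptor Cα atoms move more than ``superposition_tolerance`` Å RMSD
    between frames, which indicates the input was never superposed.
    """
    topo = bound.topology
    lig_idx = topo.ligand_indices()
    if lig_idx.size == 0:
        raise ValueError("ensemble has no ligand chain")
    rec_ca = receptor_calpha_selection(topo).resolve(topo)
    if rec_ca.size >= 3 and bound.n_frames > 1:
        ca = bound.frames[:, rec_ca, :]
        drift = np.sqrt(np.mean(np.sum((ca - ca[0]) ** 2, axis=2), axis=1))
        if np.max(drift) > superposition_tolerance:
            warnings.warn(
                f"receptor Cα RMSD between frames reaches {np.max(drift):.2f} Å; "
                "superpose the ensemble onto a common reference before "
                "clustering poses")
    lig = bound.frames[:, lig_idx, :]
    t, n, _ = lig.shape
    d2 = np.empty((t, t))
    # row-wise direct differences: exact even at large absolute coordinates
    for s in range(t):
        d2[s] = np.mean(np.sum((lig - lig[s]) ** 2, axis=2), axis=1)
    d2 = 0.5 * (d2 + d2.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class LinkageTree:
    """Ward merge history on the δ = sqrt(ΔSS) scale.

    ``merges[k] = (u, v, delta, size)`` merges clusters ``u`` and ``v``
    (SciPy numbering: leaves 0..n-1, merge k creates cluster n+k) at height
    ``delta`` into a cluster of ``size`` leaves.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_count: int
    _scipy_linkage: np.ndarray
    _distances: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


def ward_linkage(distances: np.ndarray) -> LinkageTree:
    """Agglomerative Ward linkage of a symmetric distance matrix.

    Heights are δ(c1, c2) = sqrt(increase in total within-cluster sum of
    squares), so two singletons at distance D merge at δ = D/√2.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(~np.isfinite(distances)) or np.any(distances < 0):
        raise ValueError("distances must be finite and non-negative")
    if not np.allclose(distances, distances.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(distances)) > 1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(distances, checks=False)
    z = linkage(condensed, method="ward")
    merges = [(int(u), int(v), float(h) / _SQRT2, int(size))
              for u, v, h, size in z]
    return LinkageTree(merges=merges, leaf_count=distances.shape[0],
                       _scipy_linkage=z, _distances=distances)


@dataclass
class ClusterAssignment:
    """Flat clustering from cutting a :class:`LinkageTree`.

    Cluster ids are contiguous from 1, ordered by decreasing size (ties by
    smallest member leaf index); ``centroid_leaf[cid]`` is the medoid frame
    of cluster ``cid`` (the member minimising the summed squared RMSD to all
    other members — an actual conformation, not an average).
    """

    labels: np.ndarray
    threshold: float
    n_clusters: int
    centroid_leaf: dict[int, int]

    def members(self, cluster_id: int) -> np.ndarray:
        return np.where(self.labels == cluster_id)[0]


def cut_tree(tree: LinkageTree, threshold: float) -> ClusterAssignment:
    """Cut the dendrogram at δ = ``threshold``: clusters are the connected
    components after removing all merges with δ > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    raw = fcluster(tree._scipy_linkage, t=threshold * _SQRT2,
                   criterion="distance")
    ids = np.unique(raw)
    keyed = sorted(ids, key=lambda cid: (-np.sum(raw == cid),
                                         int(np.min(np.where(raw == cid)[0]))))
    labels = np.empty_like(raw)
    centroid = {}
    d2 = tree._distances ** 2
    for new_id, cid in enumerate(keyed, start=1):
        members = np.where(raw == cid)[0]
        labels[members] = new_id
        centroid[new_id] = int(members[np.argmin(d2[np.ix_(members, members)]
                                                 .sum(axis=1))])
    return ClusterAssignment(labels=labels, threshold=threshold,
                             n_clusters=len(keyed), centroid_leaf=centroid)


def merge_clusters(assignment: ClusterAssignment, keep_ids: list[int],
                   bound: StructuralEnsemble) -> StructuralEnsemble:
    """Concatenate the frames of the kept clusters (original frame order)."""
    if not keep_ids:
        raise ValueError("keep_ids is empty")
    valid = set(range(1, assignment.n_clusters + 1))
    bad = [k for k in keep_ids if k not in valid]
    if bad:
        raise ValueError(f"unknown cluster ids {bad}; valid ids are 1..")
    mask = np.isin(assignment.labels, list(keep_ids))
    idx = np.where(mask)[0]
    frames = bound.frames[idx]
    spacing = float(bound.times[1] - bound.times[0]) if bound.n_frames > 1 else 1.0
    return StructuralEnsemble(bound.topology, frames,
                              spacing * np.arange(idx.size))
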