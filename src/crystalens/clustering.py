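"""Pairwise-RMSD conformational clustering and convergence diagnostics.

Two clusterings of the same pairwise Cα-RMSD matrix are provided:

* GROMOS clustering — iterative max-neighbour peeling under a distance
  cutoff (default 5 Å); used for windowed convergence diagnostics.
* Network clustering — a graph with an edge wherever RMSD < cutoff
  (default 3.5 Å, or the mean of the pairwise distribution in ``auto``
  mode); clusters are the connected components, ordered by size.

Both report populations, centroid (medoid) frames, and the cluster
entropy −Σ P_j ln P_j whose stability over 20 ns windows is the
convergence signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_superpose
from .io import Ensemble

__all__ = [
    "PairwiseRMSDMatrix",
    "ClusterAssignment",
    "ConvergenceReport",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "network_cluster",
    "centroid_structure",
    "cluster_entropy",
    "convergence_windows",
    "network_layout",
    "GROMOS_CUTOFF",
    "NETWORK_CUTOFF",
]

GROMOS_CUTOFF = 5.0    # Å
NETWORK_CUTOFF = 3.5   # Å


@dataclass
class PairwiseRMSDMatrix:
    """Symmetric matrix of Kabsch-minimised Cα RMSDs between frames."""

    values: np.ndarray
    frame_ids: list[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if v.shape[0] != len(self.frame_ids):
            raise ValueError("frame_ids length must match matrix size")
        if np.abs(v - v.T).max() > 1e-8:
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-8):
            raise ValueError("RMSD matrix must have a zero diagonal")
        if v.min() < 0:
            raise ValueError("RMSD entries must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.frame_ids)


@dataclass
class ClusterAssignment:
    """Frame → cluster labels (1-based, by decreasing cluster size)."""

    labels: np.ndarray
    populations: np.ndarray        # % per cluster, index 0 ↔ cluster 1
    centroid_frames: list[int]     # frame ids, one per cluster
    method: str
    cutoff: float
    edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster: int) -> np.ndarray:
        """Positional indices of the frames in a (1-based) cluster."""
        return np.flatnonzero(self.labels == cluster)

    def probabilities(self) -> np.ndarray:
        return self.populations / 100.0


@dataclass
class ConvergenceReport:
    """Per-window cluster counts and entropies over the analysed span."""

    window_starts_ns: np.ndarray
    n_clusters_per_window: np.ndarray
    entropy_per_window: np.ndarray
    window_ns: float
    cutoff: float


def pairwise_rmsd_matrix(
    ensemble: Ensemble, selection: list[int]
) -> PairwiseRMSDMatrix:
    """All-against-all Kabsch-minimised RMSD over the selected atoms."""
    n = ensemble.n_frames
    if n < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    coords = ensemble.coords(selection)
    centred = coords - coords.mean(axis=1, keepdims=True)

    # Batched Kabsch: for each row i, SVD all cross-covariances at once and
    # evaluate residuals directly (numerically stable near zero).
    values = np.zeros((n, n))
    for i in range(n):
        mobiles = centred[i + 1 :]
        if mobiles.size == 0:
            break
        h = np.einsum("ka,jkb->jab", centred[i], mobiles)  # = (X_j^T X_i)^T
        u, s, vt = np.linalg.svd(h)
        # exclude reflections: flip the smallest singular direction
        det = np.linalg.det(u) * np.linalg.det(vt)
        u[det < 0, :, -1] *= -1.0
        # rotation taking mobile X_j onto reference X_i: X_j @ R ≈ X_i
        rot = np.einsum("jba,jcb->jac", vt, u)  # vt^T @ u^T per pair
        residual = np.einsum("jka,jab->jkb", mobiles, rot) - centred[i]
        values[i, i + 1 :] = np.sqrt(
            np.mean(np.sum(residual**2, axis=2), axis=1)
        )
    values = values + values.T
    return PairwiseRMSDMatrix(values, list(range(n)))


def _ordered_assignment(
    raw_groups: list[list[int]],
    matrix: PairwiseRMSDMatrix,
    method: str,
    cutoff: float,
    centroids: list[int] | None = None,
    edges: list[tuple[int, int]] | None = None,
) -> ClusterAssignment:
    """Relabel raw frame groups by decreasing size (ties: lowest frame id)."""
    order = sorted(
        range(len(raw_groups)), key=lambda g: (-len(raw_groups[g]), min(raw_groups[g]))
    )
    n = len(matrix)
    labels = np.zeros(n, dtype=int)
    populations = []
    centroid_frames = []
    for rank, g in enumerate(order, start=1):
        members = raw_groups[g]
        labels[members] = rank
        populations.append(100.0 * len(members) / n)
        if centroids is not None:
            centroid_frames.append(matrix.frame_ids[centroids[g]])
        else:
            centroid_frames.append(
                matrix.frame_ids[centroid_structure(matrix, members)]
            )
    return ClusterAssignment(
        labels,
        np.array(populations),
        centroid_frames,
        method,
        cutoff,
        edges or [],
    )


def gromos_cluster(
    matrix: PairwiseRMSDMatrix, cutoff: float = GROMOS_CUTOFF
) -> ClusterAssignment:
    """Iterative max-neighbour peeling under a distance cutoff.

    Repeatedly takes the unassigned frame with the most unassigned
    neighbours (RMSD strictly below the cutoff) as a cluster centre,
    assigns it and its neighbours to a new cluster, and removes them from
    the pool.  Neighbour-count ties are broken by the lowest frame index.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = matrix.values
    n = len(matrix)
    adjacency = (v < cutoff) & ~np.eye(n, dtype=bool)
    remaining = np.ones(n, dtype=bool)
    raw_groups: list[list[int]] = []
    centroids: list[int] = []
    while remaining.any():
        counts = (adjacency & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.flatnonzero(remaining & (adjacency[centre] | (np.arange(n) == centre)))
        raw_groups.append(list(members))
        centroids.append(centre)
        remaining[members] = False
    return _ordered_assignment(raw_groups, matrix, "gromos", cutoff, centroids)


def network_cluster(
    matrix: PairwiseRMSDMatrix, cutoff: float | str = "auto"
) -> ClusterAssignment:
    """Connected components of the RMSD-cutoff graph.

    An edge joins two frames when their RMSD is strictly below the
    cutoff; ``auto`` sets the cutoff to the mean of the strictly-upper-
    triangle RMSD distribution.  The edge list is retained for layout
    export.
    """
    import networkx as nx

    v = matrix.values
    n = len(matrix)
    if cutoff == "auto":
        cutoff = float(v[np.triu_indices(n, k=1)].mean())
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    connected = v[iu, ju] < cutoff
    edges = [(int(i), int(j)) for i, j in zip(iu[connected], ju[connected])]
    graph.add_edges_from(edges)
    raw_groups = [sorted(c) for c in nx.connected_components(graph)]
    return _ordered_assignment(
        raw_groups, matrix, "network", float(cutoff), edges=edges
    )


def centroid_structure(
    matrix: PairwiseRMSDMatrix, member_frames: list[int]
) -> int:
    """Medoid: the member minimising mean RMSD to the other members.

    Ties are broken by the lowest frame index.  Returns a positional
    index into the matrix.
    """
    members = list(member_frames)
    if not members:
        raise ValueError("member set is empty")
    if len(members) == 1:
        return members[0]
    sub = matrix.values[np.ix_(members, members)]
    mean_d = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_d))]


def cluster_entropy(populations: np.ndarray | list[float]) -> float:
    """Shannon entropy −Σ p ln p (nats) of cluster occupation probabilities."""
    p = np.asarray(populations, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def convergence_windows(
    ensemble: Ensemble,
    selection: list[int],
    window_ns: float = 20.0,
    step_ns: float | None = None,
    cutoff: float = GROMOS_CUTOFF,
) -> ConvergenceReport:
    """GROMOS clustering in overlapping time windows.

    Defaults to 20 ns windows advancing by half a window.  Reports the
    cluster count and cluster entropy per window; a flat trend across
    windows indicates converged sampling (reported, not auto-judged).
    """
    span_ns = ensemble.n_frames * ensemble.frame_interval / 1000.0
    if window_ns > span_ns + 1e-9:
        raise ValueError(
            f"window of {window_ns} ns exceeds the {span_ns:g} ns span"
        )
    if step_ns is None:
        step_ns = window_ns / 2.0
    frames_per_window = max(2, int(round(window_ns * 1000.0 / ensemble.frame_interval)))
    step_frames = max(1, int(round(step_ns * 1000.0 / ensemble.frame_interval)))

    starts, counts, entropies = [], [], []
    start = 0
    while start + frames_per_window <= ensemble.n_frames:
        window = ensemble.subset(range(start, start + frames_per_window))
        matrix = pairwise_rmsd_matrix(window, selection)
        assignment = gromos_cluster(matrix, cutoff)
        starts.append(start * ensemble.frame_interval / 1000.0)
        counts.append(assignment.n_clusters)
        entropies.append(cluster_entropy(assignment.probabilities()))
        if start + frames_per_window == ensemble.n_frames:
            break
        start += step_frames
        # final (possibly shorter-step) window flush against the end
        if start + frames_per_window > ensemble.n_frames:
            start = ensemble.n_frames - frames_per_window
    return ConvergenceReport(
        np.array(starts), np.array(counts), np.array(entropies), window_ns, cutoff
    )


def network_layout(
    assignment: ClusterAssignment, seed: int = 0
) -> dict[int, tuple[float, float]]:
    """Force-directed 2-D coordinates for visualising the cutoff graph.

    Purely cosmetic — cluster membership is defined by connected
    components, not by the layout.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(len(assignment.labels)))
    graph.add_edges_from(assignment.edges)
    pos = nx.spring_layout(graph, seed=seed)
    return {node: (float(x), float(y)) for node, (x, y) in pos.items()}
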