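"""Density-based common-nearest-neighbors (CNN) clustering.

Two points a and b are density-connected iff they lie within radius
``r`` of each other AND their r-neighborhoods share at least ``n_c``
other points.  Clusters are the connected components of the resulting
graph; components smaller than ``min_members`` are noise (label -1).
The relation is symmetric by construction, the algorithm contains no
randomness, and labels are assigned deterministically: clusters are
numbered 0..K-1 by decreasing size, ties broken by smallest member
index.

Neighbor search is exact (KD-tree); there are no silent default
parameters, because sensible values of r and n_c depend entirely on the
projected space at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from phrelay.containers import FeatureTrajectory


@dataclass(frozen=True)
class CNNParams:
    """Clustering parameters: neighborhood radius, shared-neighbor count,
    minimum cluster size."""

    radius: float
    n_c: int
    min_members: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.n_c < 0:
            raise ValueError(f"n_c must be >= 0, got {self.n_c}")
        if self.min_members < 1:
            raise ValueError(f"min_members must be >= 1, got {self.min_members}")


@dataclass
class ClusterLabels:
    """Per-frame labels; -1 marks noise.  Labels are dense 0..K-1 by
    decreasing cluster size."""

    labels: np.ndarray
    params: CNNParams
    input_space: str = ""

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    @property
    def sizes(self) -> dict[int, int]:
        return {int(k): int((self.labels == k).sum())
                for k in range(self.n_clusters)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.labels)),
                             "label": self.labels})


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber components 0..K-1 by decreasing size, ties by first member."""
    out = np.full(raw.shape, -1, dtype=int)
    ids = [c for c in np.unique(raw) if c >= 0]
    keyed = sorted(ids, key=lambda c: (-(raw == c).sum(),
                                       int(np.argmax(raw == c))))
    for new, old in enumerate(keyed):
        out[raw == old] = new
    return out


def fit_commonnn(points: np.ndarray, params: CNNParams,
                 input_space: str = "") -> ClusterLabels:
    """Cluster points with the common-nearest-neighbors criterion.

    Works on any (n_points, n_dim) array with finite coordinates.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 1:
        raise ValueError("need at least one point")
    if not np.isfinite(x).all():
        raise ValueError("non-finite coordinates")
    n = x.shape[0]
    tree = cKDTree(x)
    neighbors = tree.query_ball_tree(tree, params.radius)
    neighbor_sets = [set(nb) - {i} for i, nb in enumerate(neighbors)]
    rows, cols = [], []
    for i, nb in enumerate(neighbor_sets):
        for j in nb:
            if j <= i:
                continue
            shared = len((neighbor_sets[i] & neighbor_sets[j]) - {i, j})
            if shared >= params.n_c:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, raw = connected_components(graph, directed=False)
    # singletons with no density-connected partner are noise unless a
    # cluster may consist of one point (min_members == 1 keeps them only
    # if they had at least one connection, matching the brute-force rule
    # that a cluster is a component of the connectivity graph)
    connected = np.zeros(n, dtype=bool)
    connected[rows] = True
    connected[cols] = True
    raw = raw.copy()
    raw[~connected] = -1
    labels = _canonical_labels(raw)
    # drop small components to noise
    for k, size in list(ClusterLabels(labels, params).sizes.items()):
        if size < params.min_members:
            labels[labels == k] = -1
    labels = _canonical_labels(labels)
    return ClusterLabels(labels, params, input_space)


def fit_commonnn_bruteforce(points: np.ndarray, params: CNNParams
                            ) -> ClusterLabels:
    """O(n^2) reference implementation used as an exactness oracle."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    within = d2 <= params.radius ** 2
    np.fill_diagonal(within, False)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        js = np.flatnonzero(within[i, i + 1:]) + i + 1
        if js.size == 0:
            continue
        # diagonal is False, so neither a nor b counts as a common neighbor
        shared = (within[i][None, :] & within[js]).sum(axis=1)
        ok = js[shared >= params.n_c]
        adj[i, ok] = adj[ok, i] = True
    n_comp, raw = connected_components(csr_matrix(adj), directed=False)
    raw = raw.copy()
    raw[~adj.any(axis=1)] = -1
    labels = _canonical_labels(raw)
    for k in range(labels.max() + 1 if (labels >= 0).any() else 0):
        if (labels == k).sum() < params.min_members:
            labels[labels == k] = -1
    labels = _canonical_labels(labels)
    return ClusterLabels(labels, params)


@dataclass
class CoreSets:
    """Core-set definitions handed to the Markov-model stage: for each
    non-noise cluster, the member frame indices into the pooled frame
    order of the trajectories that were clustered."""

    members: list[np.ndarray]
    traj_lengths: list[int]

    @property
    def n_cores(self) -> int:
        return len(self.members)


def select_cores(labels: ClusterLabels, projected: list[FeatureTrajectory]
                 ) -> CoreSets:
    """Turn every non-noise cluster into one core set.

    Noise frames stay unassigned; the MSM stage fills them by
    milestoning.  Raises if the labeling contains no cluster at all.
    """
    if labels.n_clusters == 0:
        raise ValueError("all frames are noise; relax r / n_c / min_members")
    lengths = [t.n_frames for t in projected]
    if sum(lengths) != len(labels.labels):
        raise ValueError(f"label count {len(labels.labels)} does not match "
                         f"total frames {sum(lengths)}")
    members = [np.flatnonzero(labels.labels == k)
               for k in range(labels.n_clusters)]
    return CoreSets(members, lengths)


def core_label_trajs(labels: ClusterLabels, projected: list[FeatureTrajectory]
                     ) -> list[np.ndarray]:
    """Split the pooled per-frame labels back into per-replica arrays."""
    lengths = [t.n_frames for t in projected]
    if sum(lengths) != len(labels.labels):
        raise ValueError("label/frame count mismatch")
    out, start = [], 0
    for ln in lengths:
        out.append(labels.labels[start:start + ln].copy())
        start += ln
    return out


def cluster_report(labels: ClusterLabels,
                   hbond_features: FeatureTrajectory | pd.DataFrame
                   ) -> pd.DataFrame:
    """Per-cluster and whole-ensemble hydrogen-bond occupancy table.

    ``hbond_features`` holds one 0/1 column per bond label with exactly
    one row per clustered frame.  The returned table has one row per
    (cluster, bond) plus ``ensemble`` rows, and the cluster weight
    (population fraction) per cluster.
    """
    df = hbond_features.data if isinstance(hbond_features, FeatureTrajectory) \
        else hbond_features
    if len(df) != len(labels.labels):
        raise ValueError(f"occupancy table has {len(df)} rows for "
                         f"{len(labels.labels)} labeled frames")
    rows = []
    n = len(df)
    for bond in df.columns:
        col = df[bond].to_numpy(dtype=float)
        rows.append({"cluster": "ensemble", "bond": bond,
                     "occupancy": float(col.mean()), "weight": 1.0})
        for k in range(labels.n_clusters):
            mask = labels.labels == k
            rows.append({"cluster": str(k), "bond": bond,
                         "occupancy": float(col[mask].mean()),
                         "weight": float(mask.mean())})
    return pd.DataFrame(rows)
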