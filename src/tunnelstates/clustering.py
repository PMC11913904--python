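"""Clustering of per-frame tunnel pathways into tunnel types.

Pathways from all frames are compared by a pairwise distance that considers
only the middle and end part of the path (the first ``start_fraction`` of the
arc length is ignored, since all tunnels share the region near the start
point), grouped by average-linkage hierarchical clustering cut at a fixed
threshold, and labelled by the reference exit direction they match best.
Bifurcating exits that share a trunk but diverge near the surface fall into
separate clusters and can therefore receive distinct labels (the Si/Sf
pattern of solvent tunnels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._geometry import unit
from .engine import TunnelPathway

UNASSIGNED = "unassigned"


@dataclass(eq=False)
class TunnelCluster:
    cluster_id: int
    members: list[TunnelPathway]
    type_label: str = ""
    exit_direction: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def size(self) -> int:
        return len(self.members)


def resample_to_count(pathway: TunnelPathway, n_samples: int) -> np.ndarray:
    """Arc-length resampling of the centerline to exactly n_samples points."""
    pts = pathway.centers
    if len(pts) == 1:
        return np.repeat(pts, n_samples, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.linspace(0.0, s[-1], n_samples)
    return np.column_stack([np.interp(grid, s, pts[:, k]) for k in range(3)])


def pathway_distance(p1: TunnelPathway, p2: TunnelPathway,
                     start_fraction: float = 1 / 3,
                     n_samples: int = 50) -> float:
    """Mean distance between corresponding centerline samples, skipping the
    initial ``start_fraction`` of the arc length."""
    a = resample_to_count(p1, n_samples)
    b = resample_to_count(p2, n_samples)
    first = int(np.ceil(start_fraction * (n_samples - 1)))
    d = np.linalg.norm(a[first:] - b[first:], axis=1)
    return float(d.mean())


def _distance_matrix(pathways: list[TunnelPathway], start_fraction: float,
                     n_samples: int) -> np.ndarray:
    first = int(np.ceil(start_fraction * (n_samples - 1)))
    coords = np.stack([resample_to_count(p, n_samples)[first:]
                       for p in pathways])      # (n, m, 3)
    diff = coords[:, None] - coords[None, :]
    return np.linalg.norm(diff, axis=3).mean(axis=2)


def cluster_pathways(pathways: list[TunnelPathway], threshold: float,
                     start_fraction: float = 1 / 3,
                     n_samples: int = 50) -> list[TunnelCluster]:
    """Average-linkage clustering of the pairwise pathway distances, cut at
    ``threshold`` Å.  Deterministic given input order; a zero threshold
    yields one cluster per pathway."""
    if len(pathways) == 0:
        raise ValueError("no pathways to cluster")
    if len(pathways) == 1 or threshold <= 0:
        assignments = np.arange(len(pathways))
    else:
        dm = _distance_matrix(pathways, start_fraction, n_samples)
        z = linkage(squareform(dm, checks=False), method="average")
        assignments = fcluster(z, t=threshold, criterion="distance") - 1
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(assignments):
        clusters.setdefault(int(c), []).append(i)
    # deterministic ids: order clusters by their lowest member index
    ordered = sorted(clusters.values(), key=lambda m: m[0])
    out = []
    for cid, members in enumerate(ordered):
        paths = [pathways[i] for i in members]
        mean_dir = np.mean([p.exit_direction for p in paths], axis=0)
        out.append(TunnelCluster(cluster_id=cid, members=paths,
                                 exit_direction=unit(mean_dir)))
    return out


def assign_types(clusters: list[TunnelCluster],
                 reference_exits: dict[str, np.ndarray],
                 similarity_floor: float = 0.7) -> list[TunnelCluster]:
    """Label each cluster with the reference exit direction of maximal cosine
    similarity; below ``similarity_floor`` the cluster stays unassigned.

    Several clusters may legitimately share a label (near-duplicate routes);
    distinct exits bifurcating from one trunk get distinct labels as long as
    distinct reference directions are supplied.
    """
    if not reference_exits:
        raise ValueError("reference_exits must not be empty")
    refs = {lab: unit(vec) for lab, vec in reference_exits.items()}
    for cl in clusters:
        sims = {lab: float(np.dot(cl.exit_direction, v))
                for lab, v in refs.items()}
        lab = max(sims, key=sims.get)
        cl.type_label = lab if sims[lab] >= similarity_floor else UNASSIGNED
    return clusters


@dataclass(eq=False)
class BottleneckSeries:
    """Per (tunnel type, trajectory) bottleneck radii, 0 where closed."""

    data: dict[tuple[str, str], np.ndarray]
    frame_counts: dict[str, int]

    @property
    def types(self) -> list[str]:
        return sorted({t for t, _ in self.data})

    @property
    def trajectories(self) -> list[str]:
        return list(self.frame_counts)

    def series(self, type_label: str, trajectory_id: str) -> np.ndarray:
        key = (type_label, trajectory_id)
        if key in self.data:
            return self.data[key]
        return np.zeros(self.frame_counts[trajectory_id])

    def concatenated(self, type_label: str) -> np.ndarray:
        """Series over all trajectories, concatenated in trajectory order."""
        return np.concatenate([self.series(type_label, t)
                               for t in self.frame_counts])

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for t in self.types:
            for traj in self.frame_counts:
                s = self.series(t, traj)
                for k, v in enumerate(s):
                    rows.append((k, traj, t, v))
        return pd.DataFrame(rows, columns=["frame", "trajectory", "type",
                                           "bottleneck_A"])


def bottleneck_series(clusters: list[TunnelCluster],
                      frame_counts: dict[str, int]) -> BottleneckSeries:
    """Per type and frame, the widest bottleneck among that type's pathways
    (a type may have near-duplicate pathways in one frame); 0 when absent."""
    data: dict[tuple[str, str], np.ndarray] = {}
    for cl in clusters:
        if not cl.type_label:
            raise ValueError("clusters must be labelled before series assembly")
        for p in cl.members:
            key = (cl.type_label, p.trajectory_id)
            if key not in data:
                if p.trajectory_id not in frame_counts:
                    raise KeyError(f"unknown trajectory '{p.trajectory_id}'")
                data[key] = np.zeros(frame_counts[p.trajectory_id])
            arr = data[key]
            arr[p.frame_index] = max(arr[p.frame_index], p.bottleneck_radius)
    return BottleneckSeries(data=data, frame_counts=dict(frame_counts))
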