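"""Partitioning SOM nodes into niche clusters and assigning genomes.

The trained codebooks are grouped by k-means (k = 8 by default); each genome
is then assigned to the cluster holding the plurality of its ensemble-member
BMUs, with the plurality fraction kept as an assignment-confidence
diagnostic. Stability across independently seeded SOM + k-means runs is
quantified with the adjusted Rand index against a random-label baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .classes import ORGANIC_CLASSES
from .errors import ValidationError
from .som import SOMGrid, TrainConfig, train_som

KMEANS_RESTARTS = 25
DEFAULT_K = 8


@dataclass
class ClusterModel:
    """k-means partition of SOM nodes plus genome-level assignments."""

    k: int
    node_assignment: np.ndarray  # node index → cluster id (0-based)
    centroids: np.ndarray  # (k, n_features)
    inertia: float
    genome_assignment: dict[str, int] = field(default_factory=dict)
    plurality_fraction: dict[str, float] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome_id": list(self.genome_assignment),
                "cluster": list(self.genome_assignment.values()),
                "plurality_fraction": [
                    self.plurality_fraction[g] for g in self.genome_assignment
                ],
                "ambiguous": [g in self.ambiguous for g in self.genome_assignment],
            }
        )


def cluster_nodes(grid: SOMGrid, k: int = DEFAULT_K, seed: int = 0) -> ClusterModel:
    """k-means on the codebook vectors, best of 25 seeded restarts."""
    if k < 1:
        raise ValidationError("k must be ≥ 1")
    if k > grid.n_nodes:
        raise ValidationError("k cannot exceed the number of nodes")
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(grid.codebooks)
    return ClusterModel(
        k=k,
        node_assignment=labels,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def intracluster_distance_curve(
    grid: SOMGrid, k_range: Sequence[int], seed: int = 0
) -> pd.DataFrame:
    """Mean within-cluster distance to centroid over a range of k.

    The elbow diagnostic for choosing k: the curve decreases monotonically in
    expectation and reaches 0 when every node is its own cluster.
    """
    rows = []
    for k in k_range:
        cm = cluster_nodes(grid, k, seed)
        dists = np.linalg.norm(
            grid.codebooks - cm.centroids[cm.node_assignment], axis=1
        )
        rows.append((k, float(dists.mean())))
    return pd.DataFrame(rows, columns=["k", "mean_intracluster_distance"])


def assign_genomes(
    model: ClusterModel,
    grid: SOMGrid,
    profiles: pd.DataFrame,
    feature_columns: Sequence[str] = ORGANIC_CLASSES,
) -> ClusterModel:
    """Assign each genome to the cluster with the plurality of its members.

    ``profiles`` holds one row per (genome, member). Ties go to the lowest
    cluster index and the genome is flagged ambiguous. Updates and returns
    ``model``.
    """
    bmus = grid.bmu(profiles[list(feature_columns)].to_numpy())
    clusters = model.node_assignment[bmus]
    frame = pd.DataFrame(
        {"genome_id": profiles["genome_id"].to_numpy(), "cluster": clusters}
    )
    for gid, grp in frame.groupby("genome_id", sort=True):
        counts = grp["cluster"].value_counts()
        top = int(counts.max())
        winners = sorted(counts.index[counts == top])
        model.genome_assignment[gid] = int(winners[0])
        model.plurality_fraction[gid] = top / len(grp)
        if len(winners) > 1:
            model.ambiguous.add(gid)
    return model


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected partition agreement in [−1, 1].

    Accepts two label sequences over the same elements (or two dicts keyed by
    element, which are aligned on their common sorted keys).
    """
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            raise ValidationError("mix of dict and sequence partitions")
        if set(a) != set(b):
            raise ValidationError("partitions cover different element sets")
        keys = sorted(a)
        a = [a[k] for k in keys]
        b = [b[k] for k in keys]
    if len(a) != len(b):
        raise ValidationError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))


def stability_analysis(
    profiles: pd.DataFrame,
    n_runs: int,
    config: TrainConfig,
    k: int = DEFAULT_K,
    width: int = 20,
    height: int = 20,
    feature_columns: Sequence[str] = ORGANIC_CLASSES,
) -> dict[str, np.ndarray]:
    """Pairwise ARI across independently seeded runs, with a random baseline.

    Each run trains a fresh SOM and k-means from a seed derived from
    ``config.seed`` and assigns genomes; the baseline shuffles k labels
    uniformly over the genomes. Returns the two pairwise-ARI distributions.
    """
    if n_runs < 2:
        raise ValidationError("need at least two runs")
    data = profiles[list(feature_columns)].to_numpy()
    seeds = np.random.SeedSequence(config.seed).generate_state(n_runs)
    assignments = []
    for s in seeds:
        cfg = TrainConfig(
            iterations=config.iterations,
            learning_rate_start=config.learning_rate_start,
            learning_rate_end=config.learning_rate_end,
            radius_start=config.radius_start,
            radius_end=config.radius_end,
            seed=int(s % (2**31)),
        )
        grid = train_som(data, cfg, width, height)
        cm = cluster_nodes(grid, k, seed=cfg.seed)
        assign_genomes(cm, grid, profiles, feature_columns)
        assignments.append(cm.genome_assignment)

    def pairwise(parts: list) -> np.ndarray:
        out = []
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                out.append(adjusted_rand_index(parts[i], parts[j]))
        return np.array(out)

    rng = np.random.default_rng(config.seed)
    genomes = sorted(assignments[0])
    random_parts = [
        dict(zip(genomes, rng.integers(0, k, size=len(genomes))))
        for _ in range(n_runs)
    ]
    return {
        "run_ari": pairwise(assignments),
        "baseline_ari": pairwise(random_parts),
    }
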