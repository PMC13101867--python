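"""Biogeographic analysis of cluster abundances.

Site × genome RPKM tables are aggregated to site × cluster relative
abundances, bootstrapped within region × cluster pools for regional means
with percentile confidence intervals, ordinated by NMDS on Bray-Curtis
dissimilarities, clustered hierarchically with McQuitty (WPGMA) linkage, and
partitioned into environmental ecotypes via k-means on an ordination of
standardized environmental variables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import ConvexHull
from scipy.spatial.distance import braycurtis, pdist, squareform
from sklearn.cluster import KMeans

from .errors import ValidationError
from .ordination import Ordination, ordinate

BOOT_N_ITER = 1000
BOOT_N_DRAW = 10_000
BOOT_SEED = 123

ENV_COLUMNS = (
    "temperature",
    "chlorophyll_a",
    "oxygen",
    "nitrate_nitrite",
    "phosphate",
    "silicate",
)


@dataclass
class AbundanceTable:
    """Non-negative site × genome abundance values plus site metadata.

    ``metadata`` is indexed by site and carries at least a ``region`` column;
    ``category`` and the environmental columns are optional.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("abundances must be non-negative")
        missing = set(self.values.index) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"sites without metadata: {sorted(missing)[:5]}")

    @property
    def sites(self) -> list[str]:
        return list(self.values.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, metadata_path) -> "AbundanceTable":
        return cls(
            pd.read_csv(values_path, sep="\t", index_col=0),
            pd.read_csv(metadata_path, sep="\t", index_col=0),
        )


@dataclass
class ClusterAbundance:
    """Site × cluster relative abundances and the per-cluster z-scores."""

    relative: pd.DataFrame
    z_scores: pd.DataFrame
    excluded_sites: list[str] = field(default_factory=list)


def cluster_relative_abundance(
    table: AbundanceTable, assignment: Mapping[str, int]
) -> ClusterAbundance:
    """Sum genome abundances by cluster and normalize per site.

    Sites with zero total abundance are flagged and excluded (a row of
    relative abundances must sum to 1). Each cluster column is additionally
    z-score-normalized across sites for map-style comparisons; constant
    columns get z = 0.
    """
    missing = set(table.genomes) - set(assignment)
    if missing:
        raise ValidationError(f"genomes without cluster: {sorted(missing)[:5]}")
    clusters = pd.Series({g: assignment[g] for g in table.genomes})
    sums = table.values.T.groupby(clusters).sum().T  # site × cluster
    totals = sums.sum(axis=1)
    excluded = list(sums.index[totals == 0])
    kept = sums.loc[totals > 0]
    relative = kept.div(kept.sum(axis=1), axis=0)
    sd = relative.std(ddof=0)
    z = (relative - relative.mean()).div(sd.replace(0.0, np.nan)).fillna(0.0)
    return ClusterAbundance(relative, z, excluded)


def bootstrap_recruitment(
    table: AbundanceTable,
    assignment: Mapping[str, int],
    n_iter: int = BOOT_N_ITER,
    n_draw: int = BOOT_N_DRAW,
    seed: int = BOOT_SEED,
    group_column: str = "region",
) -> pd.DataFrame:
    """Bootstrapped regional mean relative abundances with 95% CIs.

    Per region and cluster, the pool is every (site, genome) RPKM value of
    the cluster's genomes at the region's sites. Each iteration draws
    ``n_draw`` values with replacement independently from each cluster pool,
    sums them, and converts the cumulative RPKMs to relative abundances; the
    mean and the 2.5/97.5 percentile interval over iterations are reported.
    Regions with an empty cluster pool are skipped with a warning column.
    """
    if group_column not in table.metadata.columns:
        raise ValidationError(f"metadata lacks column {group_column!r}")
    clusters = sorted(set(assignment.values()))
    genome_by_cluster = {
        c: [g for g in table.genomes if assignment[g] == c] for c in clusters
    }
    rng = np.random.default_rng(seed)
    rows = []
    for region in sorted(table.metadata[group_column].unique()):
        sites = table.metadata.index[table.metadata[group_column] == region]
        block = table.values.loc[table.values.index.intersection(sites)]
        pools = {
            c: block[genome_by_cluster[c]].to_numpy().ravel() for c in clusters
        }
        if any(len(p) == 0 for p in pools.values()):
            continue
        sums = np.empty((n_iter, len(clusters)))
        for j, c in enumerate(clusters):
            pool = pools[c]
            idx = rng.integers(0, len(pool), size=(n_iter, n_draw))
            sums[:, j] = pool[idx].sum(axis=1)
        shares = sums / sums.sum(axis=1, keepdims=True)
        mean = shares.mean(axis=0)
        lo = np.percentile(shares, 2.5, axis=0)
        hi = np.percentile(shares, 97.5, axis=0)
        for j, c in enumerate(clusters):
            rows.append((region, c, mean[j], lo[j], hi[j]))
    return pd.DataFrame(
        rows, columns=[group_column, "cluster", "mean", "ci_low", "ci_high"]
    )


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: 1 − 2·Σ min(u, v) / (Σu + Σv)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValidationError("abundance vectors must be non-negative")
    if u.sum() + v.sum() == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(u, v))


def ordinate_sites(
    relative: pd.DataFrame, dims: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, Ordination]:
    """NMDS of sites on Bray-Curtis dissimilarity of relative abundances."""
    D = squareform(pdist(relative.to_numpy(), metric="braycurtis"))
    result = ordinate(D, dims=dims, seed=seed)
    coords = pd.DataFrame(
        result.embedding,
        index=relative.index,
        columns=[f"NMDS{i+1}" for i in range(dims)],
    )
    return coords, result


def ecotype_partition(
    env: pd.DataFrame, k: int = 3, seed: int = 0
) -> tuple[pd.Series, dict[int, np.ndarray], pd.DataFrame]:
    """Environmental ecotypes from NMDS + k-means with convex hulls.

    Environmental variables are standardized (their units are
    incommensurable), sites are ordinated by NMDS on Euclidean distances,
    k-means (default k = 3) labels the embedding, and each ecotype's 2-D
    convex hull vertices are returned. Sites with missing metadata are
    labeled ``Other`` and left out of the ordination.
    """
    complete = env.dropna()
    if complete.empty:
        raise ValidationError("no sites with complete environmental metadata")
    scaled = (complete - complete.mean()) / complete.std(ddof=0).replace(0.0, 1.0)
    D = squareform(pdist(scaled.to_numpy()))
    result = ordinate(D, dims=2, seed=seed)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    labels = km.fit_predict(result.embedding)
    ecotypes = pd.Series("Other", index=env.index, name="ecotype", dtype=object)
    ecotypes.loc[complete.index] = labels
    hulls: dict[int, np.ndarray] = {}
    for c in range(k):
        pts = result.embedding[labels == c]
        if len(pts) >= 3 and np.ptp(pts, axis=0).min() > 0:
            hulls[c] = pts[ConvexHull(pts).vertices]
        else:
            hulls[c] = pts
    coords = pd.DataFrame(
        result.embedding, index=complete.index, columns=["NMDS1", "NMDS2"]
    )
    return ecotypes, hulls, coords


def hierarchical_regions(relative: pd.DataFrame) -> np.ndarray:
    """WPGMA (McQuitty) linkage on Bray-Curtis distances between sites."""
    if len(relative) < 2:
        raise ValidationError("need at least two sites")
    dvec = pdist(relative.to_numpy(), metric="braycurtis")
    return hierarchy.linkage(dvec, method="weighted")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
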