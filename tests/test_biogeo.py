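"""Biogeography: relative abundances, bootstrap recruitment, ordination."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from metaniche.biogeo import (
    AbundanceTable,
    bootstrap_recruitment,
    bray_curtis,
    cluster_relative_abundance,
    ecotype_partition,
    hierarchical_regions,
    linkage_to_newick,
    ordinate_sites,
)
from metaniche.errors import ValidationError
from metaniche.ordination import ordinate


def _table(values, regions=None):
    values = pd.DataFrame(values)
    values.index = [f"site{i}" for i in range(len(values))]
    values.columns = [f"g{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame(
        {"region": regions or ["R"] * len(values)}, index=values.index
    )
    return AbundanceTable(values, meta)


class TestClusterRelativeAbundance:
    def test_two_cluster_split(self):
        table = _table([[30.0, 10.0]])
        ca = cluster_relative_abundance(table, {"g0": 1, "g1": 2})
        assert ca.relative.loc["site0", 1] == pytest.approx(0.75)
        assert ca.relative.loc["site0", 2] == pytest.approx(0.25)

    def test_single_cluster_all_one(self):
        table = _table([[5.0, 3.0], [1.0, 9.0]])
        ca = cluster_relative_abundance(table, {"g0": 1, "g1": 1})
        assert np.allclose(ca.relative[1], 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        table = _table(rng.random((6, 10)))
        assignment = {f"g{j}": j % 3 for j in range(10)}
        ca = cluster_relative_abundance(table, assignment)
        assert np.allclose(ca.relative.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_site_excluded(self):
        table = _table([[1.0, 1.0], [0.0, 0.0]])
        ca = cluster_relative_abundance(table, {"g0": 1, "g1": 2})
        assert ca.excluded_sites == ["site1"]
        assert "site1" not in ca.relative.index

    def test_constant_cluster_column_zero_z(self):
        table = _table([[3.0, 1.0], [3.0, 1.0]])
        ca = cluster_relative_abundance(table, {"g0": 1, "g1": 2})
        assert np.allclose(ca.z_scores.to_numpy(), 0.0)

    def test_unassigned_genome_raises(self):
        with pytest.raises(ValidationError):
            cluster_relative_abundance(_table([[1.0, 1.0]]), {"g0": 1})


class TestBootstrapRecruitment:
    def test_symmetric_pools_equal_shares(self):
        rng = np.random.default_rng(1)
        # 8 genomes, one per cluster, every pool a permutation of the same
        # values — the cluster pools are exactly exchangeable
        base = rng.lognormal(0, 0.2, size=12)
        values = np.column_stack([rng.permutation(base) for _ in range(8)])
        table = _table(values)
        assignment = {f"g{j}": j for j in range(8)}
        out = bootstrap_recruitment(table, assignment, n_iter=300, n_draw=2000, seed=123)
        assert np.allclose(out["mean"], 1 / 8, atol=0.01)
        assert ((out["ci_low"] <= 1 / 8) & (1 / 8 <= out["ci_high"])).all()

    def test_doubled_pool_gets_two_ninths(self):
        rng = np.random.default_rng(2)
        values = np.abs(rng.normal(10, 0.1, size=(10, 9)))
        values[:, 0] *= 2  # cluster 0's pool doubled in value
        table = _table(values)
        assignment = {f"g{j}": j for j in range(9)}
        out = bootstrap_recruitment(table, assignment, n_iter=300, n_draw=2000, seed=5)
        share0 = out.loc[out["cluster"] == 0, "mean"].iloc[0]
        assert share0 == pytest.approx(2 / 10, abs=0.01)

    def test_fixed_seed_bitwise_reproducible(self):
        rng = np.random.default_rng(3)
        table = _table(rng.random((6, 4)), regions=["A", "A", "A", "B", "B", "B"])
        assignment = {f"g{j}": j % 2 for j in range(4)}
        a = bootstrap_recruitment(table, assignment, n_iter=50, n_draw=500, seed=123)
        b = bootstrap_recruitment(table, assignment, n_iter=50, n_draw=500, seed=123)
        assert a.equals(b)


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_disjoint_support(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == 1.0

    def test_hand_formula(self):
        assert bray_curtis([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_all_zero_raises(self):
        with pytest.raises(ValidationError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            u, v = rng.random(5), rng.random(5)
            d = bray_curtis(u, v)
            assert d == pytest.approx(bray_curtis(v, u))
            assert 0.0 <= d <= 1.0


class TestNMDS:
    def test_euclidean_embeddable_triangle_near_zero_stress(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        D = squareform(pdist(pts))
        result = ordinate(D, dims=2, seed=0)
        assert result.stress < 1e-3

    def test_identical_points_coincide(self):
        D = np.zeros((4, 4))
        result = ordinate(D, dims=2, seed=0)
        spread = result.embedding.std(axis=0)
        assert np.allclose(spread, 0.0, atol=1e-6)

    def test_stress_monotone_over_iterations(self):
        rng = np.random.default_rng(5)
        pts = rng.random((10, 6))
        D = squareform(pdist(pts))
        result = ordinate(D, dims=2, seed=1)
        path = result.stress_path
        assert path[-1] <= path[0] + 1e-12
        assert all(path[i + 1] <= path[i] + 1e-9 for i in range(len(path) - 1))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            ordinate(D)

    def test_ordinate_sites_wrapper(self):
        rng = np.random.default_rng(6)
        table = _table(rng.random((5, 6)))
        ca = cluster_relative_abundance(table, {f"g{j}": j % 2 for j in range(6)})
        coords, result = ordinate_sites(ca.relative, seed=0)
        assert list(coords.columns) == ["NMDS1", "NMDS2"]
        assert len(coords) == 5
        assert result.stress >= 0


class TestEcotypes:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(7)
        blobs = [
            rng.normal(center, 0.05, size=(10, 3))
            for center in ([0, 0, 0], [5, 5, 5], [-5, 5, 0])
        ]
        env = pd.DataFrame(
            np.vstack(blobs),
            columns=["temperature", "chlorophyll_a", "oxygen"],
            index=[f"s{i}" for i in range(30)],
        )
        labels, hulls, coords = ecotype_partition(env, k=3, seed=0)
        truth = np.repeat([0, 1, 2], 10)
        from metaniche.clustering import adjusted_rand_index

        assert adjusted_rand_index(truth, labels.to_numpy()) == 1.0
        assert len(hulls) == 3

    def test_missing_metadata_routes_to_other(self):
        env = pd.DataFrame(
            {"temperature": [1.0, 2.0, np.nan, 10.0], "oxygen": [1.0, 2.0, 3.0, 10.0]},
            index=["a", "b", "c", "d"],
        )
        labels, _, coords = ecotype_partition(env, k=2, seed=0)
        assert labels["c"] == "Other"
        assert "c" not in coords.index


class TestHierarchicalRegions:
    def test_identical_sites_merge_at_zero(self):
        rel = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"])
        Z = hierarchical_regions(rel)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_hand_wpgma_merge_heights(self):
        # BC(s1,s2)=0.5, BC(s1,s3)=1, BC(s2,s3)=1
        # WPGMA: merge s1,s2 at 0.5; distance to s3 = (1+1)/2 = 1
        rel = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]],
            index=["s1", "s2", "s3"],
        )
        Z = hierarchical_regions(rel)
        assert Z[0, 2] == pytest.approx(0.5)
        assert Z[1, 2] == pytest.approx(1.0)

    def test_newick_output_parses(self):
        rel = pd.DataFrame(
            [[1.0, 0.0], [0.8, 0.2], [0.0, 1.0]], index=["x", "y", "z"]
        )
        Z = hierarchical_regions(rel)
        newick = linkage_to_newick(Z, list(rel.index))
        assert newick.endswith(";")
        for name in ("x", "y", "z"):
            assert name in newick
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        assert tree.count_terminals() == 3
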