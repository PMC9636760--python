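"""Species x group matrix, Euclidean distances and hierarchical classification."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chemotax import (
    MetaboliteCluster,
    RelationTable,
    SpeciesGroupMatrix,
    SyntheticSpec,
    build_matrix,
    clade_report,
    cut_tree,
    distance_matrix,
    dpcluso_cluster,
    euclidean_distance,
    generate_dataset,
    build_network,
    hierarchical_cluster,
)


def two_group_clusters():
    return [
        MetaboliteCluster(1, frozenset({"c1", "c1b"}), 1),
        MetaboliteCluster(2, frozenset({"c2", "c2b"}), 1),
    ]


class TestBuildMatrix:
    def test_member_mode_marks_single_compound(self):
        rel = RelationTable.from_pairs([("sp", "c1"), ("sp", "c2")])
        mat = build_matrix(rel, two_group_clusters(), mode="member")
        assert mat.to_frame().loc["sp"].tolist() == [1, 1]

    def test_pair_mode_requires_two_compounds_per_group(self):
        rel = RelationTable.from_pairs([("sp", "c1"), ("sp", "c2")])
        # one compound per group -> all-zero row -> species dropped -> empty matrix
        with pytest.raises(ValueError):
            build_matrix(rel, two_group_clusters(), mode="pair")

    def test_pair_mode_with_two_group_members(self):
        rel = RelationTable.from_pairs([("sp", "c1"), ("sp", "c1b"), ("sp", "c2")])
        mat = build_matrix(rel, two_group_clusters(), mode="pair")
        assert mat.to_frame().loc["sp"].tolist() == [1, 0]

    def test_singleton_columns_included_by_default(self):
        rel = RelationTable.from_pairs([("sp", "c1"), ("sp", "lone")])
        mat = build_matrix(rel, two_group_clusters(), singletons=["lone"])
        assert "singleton_lone" in mat.group_ids
        assert mat.to_frame().loc["sp", "singleton_lone"] == 1

    def test_clusters_only_column_universe(self):
        rel = RelationTable.from_pairs([("sp", "c1"), ("sp", "lone")])
        mat = build_matrix(rel, two_group_clusters(), singletons=["lone"], columns="clusters")
        assert mat.group_ids == ["cluster_1", "cluster_2"]

    def test_synthetic_dimensions_match_ground_truth(self, small_dataset):
        fps, rel, truth = small_dataset
        clusters, singles = dpcluso_cluster(build_network(fps, 0.85))
        mat = build_matrix(rel, clusters, singles)
        assert mat.shape == (len(rel.species_ids), len(clusters) + len(singles))


class TestEuclideanDistance:
    def test_identical_rows_zero(self):
        mat = SpeciesGroupMatrix(["a", "b"], ["g1", "g2"], np.array([[1, 0], [1, 0]]))
        assert euclidean_distance(mat, 0, 1) == 0.0

    def test_four_differing_positions_gives_two(self):
        mat = SpeciesGroupMatrix(
            ["a", "b"], [f"g{i}" for i in range(5)],
            np.array([[1, 1, 1, 1, 0], [0, 0, 0, 0, 0]]),
        )
        assert euclidean_distance(mat, 0, 1) == 2.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        M = rng.integers(0, 2, size=(10, 6))
        mat = SpeciesGroupMatrix([f"s{i}" for i in range(10)], [f"g{j}" for j in range(6)], M)
        D = distance_matrix(mat).to_numpy()
        for i, j in itertools.product(range(10), range(10)):
            expected = np.sqrt(sum((M[i, k] - M[j, k]) ** 2 for k in range(6)))
            assert D[i, j] == pytest.approx(expected, abs=1e-12)

    def test_metric_axioms_on_random_binary_matrices(self):
        rng = np.random.default_rng(8)
        M = rng.integers(0, 2, size=(8, 5))
        mat = SpeciesGroupMatrix([f"s{i}" for i in range(8)], [f"g{j}" for j in range(5)], M)
        D = distance_matrix(mat).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for i, j, k in itertools.product(range(8), repeat=3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


class TestHierarchy:
    def test_two_species_merge_at_their_distance(self):
        mat = SpeciesGroupMatrix(["a", "b"], ["g1", "g2"], np.array([[1, 0], [0, 1]]))
        tax = hierarchical_cluster(mat)
        assert tax.linkage_matrix[0, 2] == pytest.approx(np.sqrt(2))

    def test_zero_distance_pair_merges_first(self):
        M = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        mat = SpeciesGroupMatrix(["a", "b", "c"], ["g1", "g2", "g3"], M)
        tax = hierarchical_cluster(mat)
        assert tax.linkage_matrix[0, 2] == 0.0
        assert set(tax.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_non_decreasing(self, small_dataset):
        fps, rel, _ = small_dataset
        clusters, singles = dpcluso_cluster(build_network(fps, 0.85))
        tax = hierarchical_cluster(build_matrix(rel, clusters, singles))
        heights = tax.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_planted_two_clades_recovered_exactly(self):
        fps, rel, truth = generate_dataset(SyntheticSpec(noise_rate=0.0, seed=2))
        clusters, singles = dpcluso_cluster(build_network(fps, 0.85))
        tax = hierarchical_cluster(build_matrix(rel, clusters, singles))
        cut = cut_tree(tax, 2)
        ari = adjusted_rand_score(
            [truth.species_clade[s] for s in tax.species_ids],
            [cut[s] for s in tax.species_ids],
        )
        assert ari == 1.0

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        M = rng.integers(0, 2, size=(12, 4))
        ids = [f"s{i:02d}" for i in range(12)]
        mat = SpeciesGroupMatrix(ids, ["g1", "g2", "g3", "g4"], M)
        perm = rng.permutation(12)
        mat_shuffled = SpeciesGroupMatrix([ids[i] for i in perm], mat.group_ids, M[perm])
        a1 = cut_tree(hierarchical_cluster(mat), 4)
        a2 = cut_tree(hierarchical_cluster(mat_shuffled), 4)
        groups1 = {frozenset(s for s, c in a1.items() if c == k) for k in set(a1.values())}
        groups2 = {frozenset(s for s, c in a2.items() if c == k) for k in set(a2.values())}
        assert groups1 == groups2

    @pytest.mark.parametrize("linkage", ["average", "complete", "ward"])
    def test_all_linkages_supported(self, linkage):
        rng = np.random.default_rng(2)
        M = rng.integers(0, 2, size=(6, 4))
        tax = hierarchical_cluster(
            SpeciesGroupMatrix([f"s{i}" for i in range(6)], list("wxyz"), M), linkage
        )
        assert len(cut_tree(tax, 3)) == 6


class TestCutTree:
    def _tax(self, n=7, seed=0):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 2, size=(n, 5))
        return hierarchical_cluster(
            SpeciesGroupMatrix([f"s{i}" for i in range(n)], [f"g{j}" for j in range(5)], M)
        )

    def test_k_equals_n_every_species_alone(self):
        tax = self._tax()
        cut = cut_tree(tax, 7)
        assert len(set(cut.values())) == 7

    def test_k_one_single_cluster(self):
        cut = cut_tree(self._tax(), 1)
        assert set(cut.values()) == {1}

    @pytest.mark.parametrize("k", [0, 8, -1])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            cut_tree(self._tax(), k)

    def test_cuts_are_nested(self):
        tax = self._tax(n=10, seed=3)
        for k in range(2, 10):
            fine = cut_tree(tax, k)
            coarse = cut_tree(tax, k - 1)
            # every fine cluster maps into exactly one coarse cluster
            for kf in set(fine.values()):
                members = [s for s, c in fine.items() if c == kf]
                assert len({coarse[s] for s in members}) == 1

    def test_exactly_k_nonempty_clusters(self):
        tax = self._tax(n=10, seed=1)
        for k in (2, 4, 9):
            assert len(set(cut_tree(tax, k).values())) == k


class TestCladeReport:
    def test_all_eudicot_input_no_monocots(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 2, size=(6, 4))
        tax = hierarchical_cluster(
            SpeciesGroupMatrix([f"s{i}" for i in range(6)], list("abcd"), M)
        )
        report = clade_report(tax, {f"s{i}": "D" for i in range(6)}, n_clades=2)
        assert (report["n_monocot"] == 0).all()
        assert report["n_eudicot"].sum() == 6

    def test_species_counts_conserved(self, small_dataset):
        fps, rel, _ = small_dataset
        clusters, singles = dpcluso_cluster(build_network(fps, 0.85))
        tax = hierarchical_cluster(build_matrix(rel, clusters, singles))
        report = clade_report(tax, {}, n_clades=3)
        assert report["n_species"].sum() == len(tax.species_ids)
        assert (report["n_na"] == report["n_species"]).all()

    def test_pure_monocot_clade_reported(self):
        fps, rel, truth = generate_dataset(SyntheticSpec(noise_rate=0.0, seed=6))
        clusters, singles = dpcluso_cluster(build_network(fps, 0.85))
        tax = hierarchical_cluster(build_matrix(rel, clusters, singles))
        annotation = {
            sp: ("M" if truth.species_clade[sp] == 1 else "D") for sp in tax.species_ids
        }
        report = clade_report(tax, annotation, n_clades=2)
        pure_m = report[(report["n_monocot"] > 0) & (report["n_eudicot"] == 0)]
        assert len(pure_m) == 1
        assert pure_m.iloc[0]["n_monocot"] == 20
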