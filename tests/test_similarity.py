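"""Tanimoto computation, species filtering and network construction."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st
from rdkit import Chem

from chemotax import (
    CompoundRecord,
    Fingerprint,
    RelationTable,
    build_network,
    degree_distribution,
    filter_species,
    fingerprint_from_structure,
    tanimoto,
)

feature_sets = st.frozensets(st.integers(min_value=0, max_value=200), min_size=1, max_size=40)


def fp(cid, feats):
    return Fingerprint(cid, frozenset(feats))


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),          # identical sets: highest similarity
            ({1, 2}, {3, 4}, 0.0),                # disjoint sets: no similarity
            ({1, 2, 3}, {2, 3, 4}, 0.5),          # 2 shared / 4 in union
            ({1}, {1, 2, 3, 4}, 0.25),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert tanimoto(fp("a", a), fp("b", b)) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(fp("a", {1}), Fingerprint("b", frozenset()))

    @given(feature_sets, feature_sets)
    def test_symmetric_and_bounded(self, a, b):
        t1 = tanimoto(fp("a", a), fp("b", b))
        t2 = tanimoto(fp("b", b), fp("a", a))
        assert t1 == t2
        assert 0.0 <= t1 <= 1.0

    @given(feature_sets)
    def test_self_similarity_is_one(self, a):
        assert tanimoto(fp("a", a), fp("a", a)) == 1.0


class TestFilterSpecies:
    def _table(self, counts):
        pairs = []
        for i, c in enumerate(counts):
            for j in range(c):
                pairs.append((f"sp{i}", f"c{i}_{j}"))
        return RelationTable.from_pairs(pairs)

    def test_counts_1_1_2_3_5_1_leaves_three_species(self):
        out = filter_species(self._table([1, 1, 2, 3, 5, 1]))
        assert len(out.species_ids) == 3

    def test_boundary_two_compounds_retained(self):
        out = filter_species(self._table([2]))
        assert out.species_ids == ["sp0"]

    def test_single_compound_species_removed(self):
        out = filter_species(self._table([1, 3]))
        assert out.species_ids == ["sp1"]

    def test_empty_result_fatal(self):
        with pytest.raises(ValueError):
            filter_species(self._table([1, 1]))


class TestStructureFingerprints:
    def test_identical_structures_identical_fingerprints(self):
        a = CompoundRecord("a", Chem.MolFromSmiles("CCS"))
        b = CompoundRecord("b", Chem.MolFromSmiles("CCS"))
        assert fingerprint_from_structure(a).features == fingerprint_from_structure(b).features

    def test_ethanethiol_and_ethanol_differ(self):
        thiol = CompoundRecord("thiol", Chem.MolFromSmiles("CCS"))
        alcohol = CompoundRecord("alcohol", Chem.MolFromSmiles("CCO"))
        assert (
            fingerprint_from_structure(thiol).features
            != fingerprint_from_structure(alcohol).features
        )

    def test_single_atom_rejected(self):
        rec = CompoundRecord("na", Chem.MolFromSmiles("[Na]"))
        with pytest.raises(ValueError):
            fingerprint_from_structure(rec)

    def test_missing_structure_rejected(self):
        with pytest.raises(ValueError):
            fingerprint_from_structure(CompoundRecord("x"))


class TestBuildNetwork:
    def brute_force_edges(self, fps, threshold):
        out = set()
        for a, b in itertools.combinations(fps, 2):
            inter = len(a.features & b.features)
            union = len(a.features | b.features)
            if inter / union > threshold:
                out.add(tuple(sorted((a.compound_id, b.compound_id))))
        return out

    def _random_fps(self, n, seed=0):
        import numpy as np

        rng = np.random.default_rng(seed)
        return [
            fp(f"c{i:02d}", {int(x) for x in rng.choice(60, size=rng.integers(5, 25), replace=False)})
            for i in range(n)
        ]

    @pytest.mark.parametrize("threshold", [0.2, 0.5, 0.85])
    def test_matches_brute_force_double_loop(self, threshold):
        fps = self._random_fps(20, seed=3)
        net = build_network(fps, threshold)
        got = {(e.id_a, e.id_b) for e in net.edges}
        assert got == self.brute_force_edges(fps, threshold)

    def test_threshold_is_strict(self):
        # 17/20 = 0.85 exactly: must be excluded at threshold 0.85
        a = fp("a", set(range(20)))
        b = fp("b", set(range(17)))  # subset: 17 shared, union 20
        assert tanimoto(a, b) == pytest.approx(0.85)
        assert build_network([a, b], 0.85).edges == []
        assert len(build_network([a, b], 0.849).edges) == 1

    def test_edge_count_monotone_in_threshold(self):
        fps = self._random_fps(25, seed=7)
        counts = [len(build_network(fps, t).edges) for t in (0.0, 0.3, 0.6, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_isolated_nodes_kept(self):
        fps = [fp("a", {1, 2}), fp("b", {1, 2}), fp("c", {50})]
        net = build_network(fps, 0.85)
        assert net.nodes == {"a", "b", "c"}
        assert net.n_isolated == 1

    def test_feature_relabeling_invariance(self):
        fps = self._random_fps(15, seed=11)
        # apply a bijection on feature IDs: Tanimoto values cannot change
        mapping = {i: 1000 - i for i in range(61)}
        relabeled = [fp(f.compound_id, {mapping[x] for x in f.features}) for f in fps]
        e1 = {(e.id_a, e.id_b, round(e.tanimoto, 12)) for e in build_network(fps, 0.5).edges}
        e2 = {(e.id_a, e.id_b, round(e.tanimoto, 12)) for e in build_network(relabeled, 0.5).edges}
        assert e1 == e2

    def test_too_few_fingerprints_rejected(self):
        with pytest.raises(ValueError):
            build_network([fp("a", {1})])


class TestDegreeDistribution:
    def test_triangle_all_degree_two(self):
        fps = [fp("a", {1, 2}), fp("b", {1, 2}), fp("c", {1, 2})]
        table, _ = degree_distribution(build_network(fps, 0.5))
        assert dict(zip(table["degree"], table["count"])) == {2: 3}

    def test_star_histogram(self):
        hub = fp("hub", set(range(10)))
        leaves = [fp(f"leaf{i}", set(range(10)) | {100 + i, 200 + i, 300 + i, 400 + i}) for i in range(4)]
        net = build_network([hub] + leaves, 0.65)
        # hub-leaf: 10/14 > 0.65; leaf-leaf: 10/18 < 0.65
        table, _ = degree_distribution(net)
        assert dict(zip(table["degree"], table["count"])) == {1: 4, 4: 1}

    def test_histogram_sums_to_node_count(self, small_dataset):
        fps, _, _ = small_dataset
        net = build_network(fps, 0.85)
        table, _ = degree_distribution(net)
        assert table["count"].sum() == len(net.nodes)

    def test_no_edges_slope_absent(self):
        net = build_network([fp("a", {1}), fp("b", {2})], 0.85)
        table, slope = degree_distribution(net)
        assert slope is None
        assert dict(zip(table["degree"], table["count"])) == {0: 2}
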