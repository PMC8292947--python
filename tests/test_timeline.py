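"""Tree-derived ages, GO leveling, and f-versus-age timelines."""

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from molvocab import (AgeTable, Clock, OccurrenceMatrix, TimelineError,
                      VennPartition, ages_from_tree, assign_levels,
                      build_ontology, f_trajectory, first_loss_age,
                      group_age_stats, terminal_terms, to_gy)


def tree_from(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=False)


class TestAgesFromTree:
    def test_caterpillar_node_ages(self):
        # pectinate 4-leaf tree, unit branches: node depths 0..3
        t = tree_from("(a:1,(b:1,(c:1,d:1)n2:1)n1:1)root:0;")
        ages = ages_from_tree(t)
        assert ages["root"] == 0.0
        assert ages["a"] == pytest.approx(1 / 3)
        assert ages["n1"] == pytest.approx(1 / 3)
        assert ages["b"] == pytest.approx(2 / 3)
        assert ages["n2"] == pytest.approx(2 / 3)
        assert ages["c"] == 1.0 and ages["d"] == 1.0
        distinct = np.unique(np.round(list(ages.ages.values()), 9))
        assert np.allclose(distinct, [0.0, 1 / 3, 2 / 3, 1.0])

    def test_invariant_under_branch_scaling(self):
        t1 = tree_from("((a:1,b:2):1,c:3);")
        t2 = tree_from("((a:10,b:20):10,c:30);")
        a1, a2 = ages_from_tree(t1), ages_from_tree(t2)
        for leaf in "abc":
            assert a1[leaf] == pytest.approx(a2[leaf])

    def test_zero_depth_rejected(self):
        with pytest.raises(TimelineError):
            ages_from_tree(tree_from("(a:0,b:0);"))


class TestClock:
    def test_boundaries_and_midpoint(self):
        clock = Clock(origin_gy=3.8)
        assert clock.gy(0.0) == pytest.approx(3.8)
        assert clock.gy(1.0) == 0.0
        assert clock.gy(0.5) == pytest.approx(1.9)

    def test_roundtrip_identity(self):
        clock = Clock(origin_gy=4.2)
        for nd in np.linspace(0, 1, 11):
            assert clock.nd(clock.gy(nd)) == pytest.approx(nd)

    def test_age_table_conversion(self):
        ages = AgeTable({"x": 0.0, "y": 0.5})
        gy = to_gy(ages, Clock(3.8))
        assert gy == {"x": pytest.approx(3.8), "y": pytest.approx(1.9)}

    def test_out_of_range_age_rejected(self):
        with pytest.raises(TimelineError):
            Clock(3.8).gy(1.2)
        with pytest.raises(TimelineError):
            AgeTable({"x": -0.1})


def chain_ontology():
    return build_ontology(
        terms=[("root", "molecular_function", "mf"), ("a", "a", "mf"),
               ("b", "b", "mf")],
        edges=[("a", "root", "is_a"), ("b", "a", "is_a")])


def diamond_ontology():
    return build_ontology(
        terms=[("root", "molecular_function", "mf"), ("a", "a", "mf"),
               ("b", "b", "mf"), ("c", "c", "mf")],
        edges=[("a", "root", "is_a"), ("b", "root", "is_a"),
               ("c", "a", "is_a"), ("c", "b", "is_a")])


class TestTerminalTerms:
    def test_linear_chain(self):
        assert terminal_terms(chain_ontology(), "mf") == {"b"}

    def test_diamond(self):
        assert terminal_terms(diamond_ontology(), "mf") == {"c"}

    def test_unknown_namespace_rejected(self):
        with pytest.raises(TimelineError):
            terminal_terms(chain_ontology(), "xx")


class TestAssignLevels:
    def test_root_children_at_level_one(self):
        ont = build_ontology(
            terms=[("r", "r", "mf")] + [(f"c{i}", f"c{i}", "mf") for i in range(3)],
            edges=[(f"c{i}", "r", "is_a") for i in range(3)])
        lev = assign_levels(ont, "mf")
        assert all(lev.levels[f"c{i}"] == 1 for i in range(3))
        assert lev.levels["r"] == 0

    def test_multi_depth_term_collapsed_once(self):
        # c reachable at depth 1 (via root) and depth 2 (via a)
        ont = build_ontology(
            terms=[("r", "r", "mf"), ("a", "a", "mf"), ("c", "c", "mf")],
            edges=[("a", "r", "is_a"), ("c", "r", "is_a"), ("c", "a", "is_a")])
        assert assign_levels(ont, "mf", collapse="min").levels["c"] == 1
        assert assign_levels(ont, "mf", collapse="max").levels["c"] == 2

    def test_part_of_only_terms_excluded(self):
        ont = build_ontology(
            terms=[("r", "r", "mf"), ("a", "a", "mf"), ("p", "p", "mf")],
            edges=[("a", "r", "is_a"), ("p", "r", "part_of")])
        lev = assign_levels(ont, "mf")
        assert lev.excluded == ["p"]
        assert "p" not in lev.levels

    def test_matches_bfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            terms = [("r", "r", "mf")] + [(f"t{i}", f"t{i}", "mf")
                                          for i in range(n)]
            edges = []
            ids = ["r"] + [f"t{i}" for i in range(n)]
            for i in range(1, n + 1):  # parents strictly earlier: acyclic
                for p in rng.choice(i, size=min(i, 2), replace=False):
                    edges.append((ids[i], ids[int(p)], "is_a"))
            ont = build_ontology(terms, edges)
            lev = assign_levels(ont, "mf", collapse="min")
            # oracle: BFS shortest-path depth from the root over is_a edges
            g = nx.DiGraph((c, p) for c, p, _ in edges)
            oracle = nx.single_source_shortest_path_length(g.reverse(), "r")
            assert lev.levels == oracle

    def test_cyclic_input_rejected(self):
        with pytest.raises(TimelineError):
            build_ontology(
                terms=[("a", "a", "mf"), ("b", "b", "mf")],
                edges=[("a", "b", "is_a"), ("b", "a", "is_a")])


class TestTrajectories:
    def _matrix(self, rows, genomes, labels):
        counts = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))],
                              columns=genomes, dtype=int)
        return OccurrenceMatrix(counts=counts, superkingdoms=labels)

    def test_first_loss_age_enumeration(self):
        m = self._matrix([[1, 1], [0, 0], [0, 0]], ["a1", "a2"],
                         {"a1": "A", "a2": "A"})
        ages = AgeTable({"t0": 0.1, "t1": 0.2, "t2": 0.3})
        tl = f_trajectory(m, ages, taxa=["A"])
        assert first_loss_age(tl, "A") == pytest.approx(0.2)

    def test_no_loss_returns_none(self):
        m = self._matrix([[1, 1]], ["a1", "a2"], {"a1": "A", "a2": "A"})
        tl = f_trajectory(m, AgeTable({"t0": 0.5}), taxa=["A"])
        assert first_loss_age(tl, "A") is None

    def test_adding_presence_never_decreases_first_loss(self):
        rng = np.random.default_rng(17)
        genomes = [f"a{i}" for i in range(4)]
        labels = {g: "A" for g in genomes}
        rows = (rng.random((12, 4)) < 0.4).astype(int)
        ages = AgeTable({f"t{i}": round(float(rng.random()), 2)
                         for i in range(12)})
        m1 = self._matrix(rows, genomes, labels)
        before = first_loss_age(f_trajectory(m1, ages, taxa=["A"]), "A")
        rows2 = rows.copy()
        zero = np.argwhere(rows2 == 0)
        i, j = zero[0]
        rows2[i, j] = 1
        after = first_loss_age(f_trajectory(self._matrix(rows2, genomes, labels),
                                            ages, taxa=["A"]), "A")
        if before is None:
            assert after is None
        else:
            assert after is None or after >= before

    def test_missing_ages_listed(self):
        m = self._matrix([[1, 1]], ["a1", "a2"], {"a1": "A", "a2": "A"})
        with pytest.raises(TimelineError, match="t0"):
            f_trajectory(m, AgeTable({}), taxa=["A"])


class TestGroupAgeStats:
    def test_median_and_no_outlier(self):
        part = VennPartition(members={"ABE": ["x", "y", "z"]})
        ages = AgeTable({"x": 0.1, "y": 0.2, "z": 0.9})
        stats = group_age_stats(ages, part)
        assert stats.medians["ABE"] == pytest.approx(0.2)
        assert stats.outliers["ABE"] == []

    def test_single_member_group(self):
        part = VennPartition(members={"AE": ["solo"]})
        stats = group_age_stats(AgeTable({"solo": 0.7}), part)
        assert stats.medians["AE"] == pytest.approx(0.7)
        assert stats.medians["ABE"] is None

    def test_constructed_ranking_abe_first_ae_last(self):
        members = {"ABE": ["t0", "t1"], "BE": ["t2", "t3"], "AB": ["t4"],
                   "B": ["t5"], "E": ["t6"], "A": ["t7"], "AE": ["t8"]}
        ages = AgeTable({"t0": 0.0, "t1": 0.1, "t2": 0.2, "t3": 0.25,
                         "t4": 0.3, "t5": 0.4, "t6": 0.5, "t7": 0.6,
                         "t8": 0.9})
        stats = group_age_stats(ages, VennPartition(members=members))
        assert stats.ranking[0] == "ABE"
        assert stats.ranking[-1] == "AE"

    def test_outlier_by_iqr_rule(self):
        part = VennPartition(members={"AB": [f"t{i}" for i in range(9)]})
        ages = AgeTable({f"t{i}": 0.5 + 0.01 * i for i in range(8)} | {"t8": 0.05})
        stats = group_age_stats(ages, part)
        assert stats.outliers["AB"] == ["t8"]
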