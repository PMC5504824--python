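"""Dendrogram serialization, branch supports and rendering."""

from __future__ import annotations

import itertools
import random

import pandas as pd
import pytest

import oracles
from isips import (
    ComplexDefinition,
    PPINetwork,
    agglomerate,
    branch_support,
    parse_linear_format,
    pairwise_similarity,
    render_dendrogram,
    to_linear_format,
    to_newick,
    trace_to_tree,
)
from isips.tree import DendrogramNode


def leaf(label, pos=0):
    return DendrogramNode(members=frozenset({label}), formed_at=(0, pos))


def cherry(a, b, dist, step=1):
    la, lb = leaf(a, 0), leaf(b, 1)
    return DendrogramNode(
        members=la.members | lb.members, children=(la, lb),
        merge_distance=dist, formed_at=(step, 0),
    )


class TestTraceToTree:
    def test_fig2_topology_and_distance(self, fig2):
        _, complex_def, net = fig2
        tree = trace_to_tree(agglomerate(net, complex_def))
        assert set(tree.leaves()) == set(complex_def.subunits)
        first_child = tree.children[0]
        # earliest-formed cluster leads: the (A,B) cherry at 4/7
        assert first_child.members == frozenset({"A", "B"})
        assert first_child.merge_distance == pytest.approx(4 / 7, abs=1e-12)

    def test_two_leaf_trace(self):
        from isips import build_network

        cd = ComplexDefinition(("S1", "S2"))
        net = build_network([("S1", "P1"), ("S2", "P1")], cd)
        tree = trace_to_tree(agglomerate(net, cd))
        assert not tree.is_leaf
        assert all(c.is_leaf for c in tree.children)

    def test_random_traces_cover_all_leaves(self):
        rng = random.Random(8)
        for _ in range(10):
            graph, subunits = oracles.random_ppi_graph(rng, max_subunits=6, max_externals=12)
            net = PPINetwork(graph=graph, subunits=tuple(subunits))
            tree = trace_to_tree(agglomerate(net, ComplexDefinition(tuple(subunits))))
            assert sorted(tree.leaves()) == sorted(subunits)


class TestLinearFormat:
    def test_cherry_format(self):
        assert to_linear_format(cherry("A", "B", 4 / 7)) == "(A,B):0.571429"

    def test_single_leaf_is_bare_label(self):
        assert to_linear_format(leaf("Elp1")) == "Elp1"

    def test_roundtrip_random_trees(self, fig2):
        _, complex_def, net = fig2
        tree = trace_to_tree(agglomerate(net, complex_def))
        text = to_linear_format(tree)
        parsed = parse_linear_format(text)
        assert to_linear_format(parsed) == text
        assert parsed.members == tree.members

    def test_nested_format_places_distance_after_group(self):
        inner = cherry("A", "B", 4 / 7, step=1)
        outer = DendrogramNode(
            members=inner.members | {"C"}, children=(inner, leaf("C", 2)),
            merge_distance=0.8, formed_at=(2, 0),
        )
        assert to_linear_format(outer) == "((A,B):0.571429,C):0.800000"


class TestNewick:
    def test_cherry_merge_distance_mode(self):
        nwk = to_newick(cherry("A", "B", 4 / 7))
        assert nwk == "(A:0.000000,B:0.000000):0.571429;"

    def test_parsed_by_dendropy(self, fig2):
        import dendropy

        _, complex_def, net = fig2
        tree = trace_to_tree(agglomerate(net, complex_def))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(complex_def.subunits)

    def test_reserved_characters_are_quoted(self):
        nwk = to_newick(cherry("A B", "C:1", 0.5))
        assert "'A B'" in nwk and "'C:1'" in nwk

    def test_both_encodings_share_topology(self, fig2):
        import dendropy

        _, complex_def, net = fig2
        tree = trace_to_tree(agglomerate(net, complex_def))
        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=to_newick(tree), schema="newick",
                               taxon_namespace=taxa)
        linear = parse_linear_format(to_linear_format(tree))
        t2 = dendropy.Tree.get(data=to_newick(linear), schema="newick",
                               taxon_namespace=taxa)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert {b.split_bitmask for b in t1.bipartition_encoding} == {
            b.split_bitmask for b in t2.bipartition_encoding
        }


def sim_frame(labels, values):
    frame = pd.DataFrame(1.0, index=list(labels), columns=list(labels))
    for (i, j), v in values.items():
        frame.loc[i, j] = frame.loc[j, i] = v
    return frame


class TestBranchSupport:
    def three_leaf_tree(self):
        inner = cherry("b1", "b2", 0.2, step=1)
        return DendrogramNode(
            members=inner.members | {"a"}, children=(inner, leaf("a", 2)),
            merge_distance=0.9, formed_at=(2, 0),
        )

    def test_single_triple_well_designed(self):
        tree = self.three_leaf_tree()
        sim = sim_frame(["a", "b1", "b2"],
                        {("b1", "b2"): 0.9, ("a", "b1"): 0.1, ("a", "b2"): 0.1})
        branch_support(tree, sim)
        # the root joins {b1,b2} with {a}: its single triple is well designed
        assert tree.support == pytest.approx(1.0)

    def test_single_triple_failing(self):
        tree = self.three_leaf_tree()
        sim = sim_frame(["a", "b1", "b2"],
                        {("b1", "b2"): 0.1, ("a", "b1"): 0.9, ("a", "b2"): 0.1})
        branch_support(tree, sim)
        assert tree.support == pytest.approx(0.0)

    def test_leaves_carry_no_support(self):
        tree = self.three_leaf_tree()
        branch_support(tree, sim_frame(["a", "b1", "b2"], {}))
        assert tree.support is not None
        assert all(n.support is None for n in tree.walk() if n.is_leaf)

    def test_degenerate_denominator_convention(self):
        """A cherry joins two singletons: no admissible triple, support 1."""
        tree = cherry("A", "B", 0.5)
        branch_support(tree, sim_frame(["A", "B"], {("A", "B"): 0.3}))
        assert tree.support == 1.0

    def test_missing_leaf_is_fatal(self):
        tree = self.three_leaf_tree()
        with pytest.raises(KeyError, match="b2"):
            branch_support(tree, sim_frame(["a", "b1"], {}))

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = random.Random(77)
        for _ in range(10):
            graph, subunits = oracles.random_ppi_graph(rng, max_subunits=6, max_externals=15)
            if len(subunits) < 4:
                continue
            cd = ComplexDefinition(tuple(subunits))
            net = PPINetwork(graph=graph, subunits=tuple(subunits))
            tree = trace_to_tree(agglomerate(net, cd))
            sim = pairwise_similarity(net, cd)
            branch_support(tree, sim)
            for node in tree.walk():
                if node.is_leaf:
                    continue
                left, right = node.children
                expected = oracles.oracle_branch_support(
                    sim, sorted(left.members), sorted(right.members)
                )
                assert node.support == pytest.approx(expected, abs=1e-12)
                assert 0.0 <= node.support <= 1.0

    def test_tree_compatible_similarity_gives_full_support(self):
        """On a similarity matrix perfectly nested with the topology every
        internal branch is fully supported."""
        leaves = ["L1", "L2", "L3", "L4", "L5", "L6"]
        # ((L1,L2),L3) vs ((L4,L5),L6): similarity decays with tree depth
        sim = sim_frame(leaves, {(i, j): 0.05 for i, j in itertools.combinations(leaves, 2)})
        for i, j, v in [("L1", "L2", 0.9), ("L1", "L3", 0.6), ("L2", "L3", 0.6),
                        ("L4", "L5", 0.9), ("L4", "L6", 0.6), ("L5", "L6", 0.6)]:
            sim.loc[i, j] = sim.loc[j, i] = v
        c1 = cherry("L1", "L2", 0.1, step=1)
        n1 = DendrogramNode(members=c1.members | {"L3"}, children=(c1, leaf("L3", 2)),
                            merge_distance=0.4, formed_at=(2, 0))
        c2 = cherry("L4", "L5", 0.1, step=3)
        n2 = DendrogramNode(members=c2.members | {"L6"}, children=(c2, leaf("L6", 5)),
                            merge_distance=0.4, formed_at=(4, 0))
        root = DendrogramNode(members=n1.members | n2.members, children=(n1, n2),
                              merge_distance=0.95, formed_at=(5, 0))
        branch_support(root, sim)
        for node in root.walk():
            if node.is_leaf:
                continue
            assert node.support == pytest.approx(1.0), sorted(node.members)

    def test_relabeling_invariance(self, fig2):
        _, complex_def, net = fig2
        cd = complex_def
        tree = trace_to_tree(agglomerate(net, cd))
        sim = pairwise_similarity(net, cd)
        branch_support(tree, sim)
        supports = {frozenset(n.members): n.support for n in tree.walk()}

        mapping = {s: f"Q{i}" for i, s in enumerate(cd.subunits)}
        import networkx as nx

        net2 = PPINetwork(
            graph=nx.relabel_nodes(net.graph, mapping),
            subunits=tuple(mapping[s] for s in cd.subunits),
        )
        cd2 = ComplexDefinition(net2.subunits)
        tree2 = trace_to_tree(agglomerate(net2, cd2))
        branch_support(tree2, pairwise_similarity(net2, cd2))
        supports2 = {
            frozenset(mapping_inv(n.members, mapping)): n.support
            for n in tree2.walk()
        }
        assert supports == supports2


def mapping_inv(members, mapping):
    inverse = {v: k for k, v in mapping.items()}
    return {inverse[m] for m in members}


class TestRender:
    def test_svg_written(self, fig2, tmp_path):
        _, complex_def, net = fig2
        tree = trace_to_tree(agglomerate(net, complex_def))
        out = render_dendrogram(tree, tmp_path / "tree.svg")
        content = out.read_text()
        assert content.lstrip().startswith("<?xml") and "<svg" in content

    def test_single_leaf_tree(self, tmp_path):
        out = render_dendrogram(leaf("A"), tmp_path / "one.svg")
        assert out.stat().st_size > 0
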