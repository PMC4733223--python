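"""Super-network merging: deduplication, provenance, roles, degrees."""

import itertools

import pytest

from pathweave import (
    Entry,
    GeneList,
    MetabolicReaction,
    PathwayGraph,
    SignalRelation,
    annotate_fold_changes,
    degree_map,
    generate_fixture_set,
    merge,
)

from conftest import gene_list


def metabolic_graph(pid, reactions):
    g = PathwayGraph(pathway_id=pid, title=pid, organism="syn")
    g.reactions = list(reactions)
    return g


def signaling_graph(pid, relations):
    g = PathwayGraph(pathway_id=pid, title=pid, organism="syn")
    g.relations = list(relations)
    return g


def rxn(rid, subs, prods, mods=(), reversible=False):
    return MetabolicReaction(
        reaction_id=rid, substrates=tuple(subs), products=tuple(prods),
        modifiers=tuple(mods), reversible=reversible,
    )


class TestMergeMetabolic:
    def test_self_merge_idempotent(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"], ["syn:G1"])])
        assert merge([g, g], "metabolic") == merge([g], "metabolic")

    def test_shared_compound_is_single_species(self):
        g1 = metabolic_graph("p1", [rxn("r1", ["cpd:C00031"], ["cpd:B"])])
        g2 = metabolic_graph("p2", [rxn("r2", ["cpd:C00031"], ["cpd:C"])])
        net = merge([g1, g2], "metabolic")
        assert sorted(net.species) == ["cpd:B", "cpd:C", "cpd:C00031"]
        assert len(net.interactions) == 2

    def test_shared_reaction_carries_both_provenances(self):
        shared = rxn("r9", ["cpd:S"], ["cpd:P"], ["syn:G1"])
        g1 = metabolic_graph(
            "p1", [shared, rxn("r1", ["cpd:A"], ["cpd:B"]),
                   rxn("r2", ["cpd:B"], ["cpd:C"])]
        )
        g2 = metabolic_graph(
            "p2", [shared, rxn("r3", ["cpd:X"], ["cpd:Y"]),
                   rxn("r4", ["cpd:Y"], ["cpd:Z"])]
        )
        net = merge([g1, g2], "metabolic")
        assert len(net.interactions) == 5  # 3 + 3 with one duplicate collapsed
        shared_merged = [
            i for i in net.interactions if i.substrates == ("cpd:S",)
        ]
        assert len(shared_merged) == 1
        assert shared_merged[0].provenance == ("p1", "p2")

    def test_reversible_direction_ignored_in_identity(self):
        g1 = metabolic_graph("p1", [rxn("r1", ["cpd:B"], ["cpd:A"], reversible=True)])
        g2 = metabolic_graph("p2", [rxn("r2", ["cpd:A"], ["cpd:B"], reversible=True)])
        net = merge([g1, g2], "metabolic")
        assert len(net.interactions) == 1
        assert net.interactions[0].provenance == ("p1", "p2")

    def test_map_links_excluded(self):
        g = metabolic_graph(
            "p1", [rxn("r1", ["cpd:A"], ["cpd:B"], ["path:syn00999"])]
        )
        net = merge([g], "metabolic")
        assert "path:syn00999" not in net.species
        assert net.interactions[0].modifiers == ()

    def test_empty_graph_list(self):
        net = merge([], "metabolic")
        assert net.species == {} and net.interactions == []


class TestMergeSignaling:
    def test_duplicate_relation_collapsed(self):
        r = SignalRelation("syn:A", "syn:B", "PPrel", ("activation",))
        net = merge(
            [signaling_graph("p1", [r]), signaling_graph("p2", [r])], "signaling"
        )
        assert len(net.interactions) == 1
        assert net.interactions[0].provenance == ("p1", "p2")

    def test_different_subtypes_not_duplicates(self):
        net = merge(
            [
                signaling_graph(
                    "p1",
                    [
                        SignalRelation("syn:A", "syn:B", "PPrel", ("activation",)),
                        SignalRelation("syn:A", "syn:B", "PPrel", ("inhibition",)),
                    ],
                )
            ],
            "signaling",
        )
        assert len(net.interactions) == 2

    def test_mixed_graph_routes_each_side(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"])])
        g.relations = [SignalRelation("syn:X", "syn:Y", "PPrel", ("activation",))]
        met = merge([g], "metabolic")
        sig = merge([g], "signaling")
        assert {i.kind for i in met.interactions} == {"metabolic"}
        assert {i.kind for i in sig.interactions} == {"signaling"}
        assert "syn:X" not in met.species and "cpd:A" not in sig.species


class TestMergeAlgebra:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_order_insensitive(self, seed):
        fs = generate_fixture_set(seed, n_pathways=6, n_genes=40)
        for kind in ("metabolic", "signaling"):
            graphs = [g for g in fs.graphs if g.kind == kind]
            ref = merge(graphs, kind)
            for perm in itertools.islice(itertools.permutations(graphs), 6):
                assert merge(list(perm), kind) == ref

    @pytest.mark.parametrize("seed", [0, 3])
    def test_idempotent_and_conserves_species(self, seed):
        fs = generate_fixture_set(seed, n_pathways=6, n_genes=40)
        for kind in ("metabolic", "signaling"):
            graphs = [g for g in fs.graphs if g.kind == kind]
            once = merge(graphs, kind)
            assert merge(graphs + graphs, kind) == once
            assert len(once.species) == fs.manifest["expected_species"][kind]
            n_inputs = sum(
                len(g.reactions) if kind == "metabolic" else len(g.relations)
                for g in graphs
            )
            assert len(once.interactions) <= n_inputs

    def test_no_duplicate_keys_in_output(self):
        fs = generate_fixture_set(5, n_pathways=8, n_genes=50)
        for kind in ("metabolic", "signaling"):
            net = merge([g for g in fs.graphs if g.kind == kind], kind)
            keys = [i.key for i in net.interactions]
            assert len(keys) == len(set(keys))


class TestRolesAndFoldChanges:
    def test_role_classes(self):
        g = metabolic_graph(
            "p1",
            [
                rxn("r1", ["cpd:A"], ["cpd:B"], ["syn:G1"]),
                rxn("r2", ["cpd:B"], ["cpd:C"]),
            ],
        )
        net = merge([g], "metabolic")
        roles = {gid: sp.role_class for gid, sp in net.species.items()}
        assert roles == {
            "cpd:A": "reactant-only",
            "cpd:B": "reactant-and-product",
            "cpd:C": "product-only",
            "syn:G1": "modifier",
        }

    def test_annotate_fold_changes(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"], ["syn:G1"])])
        net = merge([g], "metabolic")
        out = annotate_fold_changes(net, gene_list(["syn:G1"], {"syn:G1": 2.5}))
        assert out.species["syn:G1"].fold_change == 2.5
        assert out.species["cpd:A"].fold_change is None
        # original untouched
        assert net.species["syn:G1"].fold_change is None

    def test_annotate_empty_list_is_identity(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"])])
        net = merge([g], "metabolic")
        assert annotate_fold_changes(net, GeneList([])) == net

    def test_annotate_ignores_absent_genes(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"])])
        net = merge([g], "metabolic")
        out = annotate_fold_changes(net, gene_list(["syn:ZZ"], {"syn:ZZ": 3.0}))
        assert out == net


class TestDegreeMap:
    def test_reaction_participants_form_clique(self):
        g = metabolic_graph("p1", [rxn("r1", ["cpd:A"], ["cpd:B"], ["syn:G"])])
        assert degree_map(merge([g], "metabolic")) == {
            "cpd:A": 2, "cpd:B": 2, "syn:G": 2
        }

    def test_star_hub_degree(self):
        k = 5
        rels = [
            SignalRelation("syn:H", f"syn:S{i}", "PPrel", ("activation",))
            for i in range(k)
        ]
        net = merge([signaling_graph("p1", rels)], "signaling")
        degrees = degree_map(net)
        assert degrees["syn:H"] == k
        assert all(degrees[f"syn:S{i}"] == 1 for i in range(k))

    def test_brute_force_adjacency_on_random_fixture(self):
        fs = generate_fixture_set(11, n_pathways=6, n_genes=40)
        for kind in ("metabolic", "signaling"):
            net = merge([g for g in fs.graphs if g.kind == kind], kind)
            adj = {gid: set() for gid in net.species}
            for i in net.interactions:
                parts = list(dict.fromkeys(i.substrates + i.products + i.modifiers))
                for a in parts:
                    for b in parts:
                        if a != b:
                            adj[a].add(b)
            assert degree_map(net) == {g: len(s) for g, s in adj.items()}
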