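from collections import Counter

import networkx as nx
import numpy as np
import pytest

from phylofam import (
    mcl_cluster,
    reconcile,
    simulate_gene_family,
    simulate_species_tree,
    synthesize_annotations,
    synthesize_hit_table,
)
from phylofam.clustering import ClusterSet, build_similarity_graph
from phylofam.simulate import planted_families
from phylofam.stats import ssp_filter
from phylofam.trees import split_gene_label, to_newick


class TestSpeciesTreeSimulation:
    def test_two_species_forced_topology(self):
        st = simulate_species_tree(2, 1.0, seed=99)
        assert st.n_leaves == 2
        assert len(st) == 3

    def test_eight_species_has_seven_internals_positive_lengths(self):
        st = simulate_species_tree(8, 1.0, seed=1)
        internals = [n for n in st.nodes if not n.is_leaf]
        assert len(internals) == 7
        for node in st.nodes:
            if node is not st.root:
                assert node.length > 0

    def test_determinism_byte_identical_newick(self):
        a = simulate_species_tree(6, 0.7, seed=42).to_newick()
        b = simulate_species_tree(6, 0.7, seed=42).to_newick()
        assert a == b

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_species_tree(4, 0.0, seed=0)


class TestGeneFamilySimulation:
    def test_no_events_gives_congruent_single_copy_tree(self, stree8):
        fam = simulate_gene_family(stree8, 0.0, 0.0, seed=5)
        assert not fam.truth.events
        assert all(v == 1 for v in fam.truth.copy_number.values())
        rec = reconcile(fam.tree, stree8)
        assert rec.n_duplications == 0 and rec.n_losses == 0

    @pytest.mark.parametrize("seed", [0, 7, 13])
    def test_lossless_copy_number_conservation(self, stree8, seed):
        """Without losses, leaf counts equal 1 + duplications on the lineage."""
        fam = simulate_gene_family(stree8, 0.6, 0.0, seed=seed)
        assert not fam.truth.extinct
        leaf_counts = Counter(
            split_gene_label(l.label)[0] for l in fam.tree.leaves()
        )
        assert dict(leaf_counts) == {
            sp: c for sp, c in fam.truth.copy_number.items() if c
        }
        # every true event is a duplication
        assert fam.truth.n_losses == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_leaf_multiset_always_matches_truth(self, stree8, seed):
        fam = simulate_gene_family(stree8, 0.5, 0.3, seed=seed)
        if fam.truth.extinct:
            assert fam.tree is None
            assert all(v == 0 for v in fam.truth.copy_number.values())
        else:
            counts = Counter(
                split_gene_label(l.label)[0] for l in fam.tree.leaves()
            )
            for sp, c in fam.truth.copy_number.items():
                assert counts.get(sp, 0) == c

    def test_replay_determinism(self, stree8):
        a = simulate_gene_family(stree8, 0.5, 0.2, seed=7)
        b = simulate_gene_family(stree8, 0.5, 0.2, seed=7)
        assert a.truth.events == b.truth.events
        assert a.truth.copy_number == b.truth.copy_number
        if a.tree is not None:
            assert to_newick(a.tree) == to_newick(b.tree)

    def test_event_stream_matches_manual_replay(self, stree8):
        """The recorded event count equals a replay of the same random stream."""
        fam = simulate_gene_family(stree8, 0.5, 0.2, seed=7)
        rng = np.random.default_rng(7)
        total = 0.7
        # replay: consume the identical exponential/uniform stream and count
        node_len = {}
        for node in stree8.root.preorder():
            node_len[stree8.label_to_index[node.label]] = node.length or 0.0

        events = []

        def evolve(snode, remaining):
            while True:
                dt = rng.exponential(1.0 / total)
                if dt >= remaining:
                    for child in stree8.children_of(snode):
                        evolve(child, node_len[child])
                    return
                remaining -= dt
                if rng.random() < 0.5 / total:
                    events.append("duplication")
                    evolve(snode, remaining)
                    # second copy continues in this frame
                else:
                    events.append("loss")
                    return

        for child in stree8.children_of(stree8.root_index):
            evolve(child, node_len[child])
        assert len(events) == len(fam.truth.events)
        assert Counter(events) == Counter(e.kind for e in fam.truth.events)

    def test_rate_validation(self, stree8):
        with pytest.raises(ValueError):
            simulate_gene_family(stree8, -0.1, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_gene_family(stree8, 0.1, 0.1, root_copies=0, seed=0)


class TestHitTableSynthesis:
    def test_no_noise_components_are_families(self, stree8):
        fams = planted_families(n_families=4, n_proteins=40, n_species=8)
        hits, _ = synthesize_hit_table(fams, noise_prob=0.0, seed=11)
        graph = build_similarity_graph(hits, evalue_cutoff=10.0)
        comps = list(nx.connected_components(graph))
        expected = [
            {f"{sp}|{p}" for sp, ps in fam.proteins.items() for p in ps}
            for fam in fams
        ]
        assert sorted(map(sorted, comps)) == sorted(map(sorted, expected))

    def test_format_contract(self, stree8):
        fams = planted_families(n_families=3, n_proteins=18, n_species=6)
        hits, _ = synthesize_hit_table(fams, noise_prob=0.2, seed=2)
        assert (hits.qstart <= hits.qend).all()
        assert (hits.sstart <= hits.send).all()
        assert (hits.bitscore > 0).all()
        assert (hits.qend <= hits.qlen).all()
        assert (hits.send <= hits.slen).all()

    def test_ordered_pair_count_includes_self_hits(self):
        fams = planted_families(n_families=2, n_proteins=5, n_species=3)
        # families of sizes 3 and 2 -> 9 + 4 = 13 ordered rows
        hits, _ = synthesize_hit_table(fams, noise_prob=0.0, seed=0)
        assert len(hits) == 13

    def test_evalue_monotone_in_bitscore(self):
        fams = planted_families(n_families=2, n_proteins=20, n_species=4)
        hits, _ = synthesize_hit_table(fams, noise_prob=0.3, seed=5)
        h = hits.sort_values("bitscore")
        assert (np.diff(h.evalue.to_numpy()) <= 1e-12).all()

    def test_noise_prob_validation(self):
        fams = planted_families(n_families=2, n_proteins=4, n_species=2)
        with pytest.raises(ValueError):
            synthesize_hit_table(fams, noise_prob=1.0, seed=0)


class TestAnnotationSynthesis:
    @pytest.fixture()
    def clusters(self):
        fams = planted_families(n_families=6, n_proteins=60, n_species=6)
        assignment = {
            f"{sp}|{p}": i
            for i, fam in enumerate(fams)
            for sp, ps in fam.proteins.items()
            for p in ps
        }
        return ClusterSet.from_assignment(assignment)

    def test_zero_background_confines_planted_term(self, clusters):
        annot = synthesize_annotations(
            clusters, "PLANT", {0, 1}, background_term_rate=0.0, seed=3
        )
        carriers = {
            pid for pid, terms in annot.term_map().items() if "PLANT" in terms
        }
        target = set(clusters.clusters[0]) | set(clusters.clusters[1])
        assert carriers == target

    def test_all_pass_ssp_filter_when_forced(self, clusters):
        annot = synthesize_annotations(
            clusters, "T", set(), sp_rate=1.0, length_range=(100, 200), seed=1
        )
        ids, fraction = ssp_filter(annot)
        assert ids == set(annot.proteins)
        assert fraction == 100.0

    def test_determinism(self, clusters):
        a = synthesize_annotations(clusters, "T", {2}, seed=9)
        b = synthesize_annotations(clusters, "T", {2}, seed=9)
        assert a.df.drop(columns="terms").equals(b.df.drop(columns="terms"))
        assert list(a.df.terms) == list(b.df.terms)

    def test_unknown_target_cluster_rejected(self, clusters):
        with pytest.raises(ValueError, match="unknown cluster"):
            synthesize_annotations(clusters, "T", {999}, seed=0)
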