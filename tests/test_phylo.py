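import dendropy
import numpy as np
import pytest

from paleozyme import phylo, seqsim
from paleozyme.mcmc import tree_splits
from paleozyme.msa import Alignment


def brute_force_loglik(tree_newick_lengths, aln, model):
    """Enumeration oracle for a fixed 4-taxon shape ((A,B)u,(C,D)v)root:
    sum over all root/internal state assignments, column by column."""
    tu, tv, ta, tb, tc, td = tree_newick_lengths
    pi = model.frequencies
    P = model.transition_matrix
    Pu, Pv, PA, PB, PC, PD = P(tu), P(tv), P(ta), P(tb), P(tc), P(td)
    enc = {k: model.encode(v) for k, v in aln.rows.items()}

    def leafp(Pm, state, obs):
        return 1.0 if obs < 0 else Pm[state, obs]

    total = 0.0
    for col in range(aln.ncols):
        s = 0.0
        for r in range(20):
            for u in range(20):
                for v in range(20):
                    s += (
                        pi[r] * Pu[r, u] * Pv[r, v]
                        * leafp(PA, u, enc["A"][col]) * leafp(PB, u, enc["B"][col])
                        * leafp(PC, v, enc["C"][col]) * leafp(PD, v, enc["D"][col])
                    )
        total += np.log(s)
    return total


class TestLikelihood:
    def test_matches_enumeration_oracle(self, jtt, four_taxon_tree, four_taxon_alignment):
        ll = phylo.tree_log_likelihood(four_taxon_tree, four_taxon_alignment, jtt)
        brute = brute_force_loglik(
            (0.15, 0.1, 0.1, 0.2, 0.3, 0.05), four_taxon_alignment, jtt
        )
        assert abs(ll - brute) < 1e-8

    def test_zero_length_two_leaf_column(self, jtt):
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        tree.is_rooted = True
        ll = phylo.tree_log_likelihood(tree, Alignment({"A": "A", "B": "A"}), jtt)
        assert ll == pytest.approx(np.log(jtt.frequencies[0]), abs=1e-10)

    def test_infinite_branch_independence_limit(self, jtt):
        tree = dendropy.Tree.get(data="(A:19.9,B:19.9);", schema="newick")
        tree.is_rooted = True
        aln = Alignment({"A": "KR", "B": "WD"})
        ll = phylo.tree_log_likelihood(tree, aln, jtt)
        expected = sum(
            np.log(jtt.frequencies[jtt.alphabet.index(c)]) for c in "KRWD"
        )
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_invariant_under_rerooting(self, jtt, four_taxon_tree, four_taxon_alignment):
        ll = phylo.tree_log_likelihood(four_taxon_tree, four_taxon_alignment, jtt)
        for label in ("A", "C"):
            clone = four_taxon_tree.clone(depth=1)
            leaf = [x for x in clone.leaf_node_iter() if x.taxon.label == label][0]
            half = leaf.edge.length / 2
            clone.reroot_at_edge(leaf.edge, length1=half, length2=half)
            clone.is_rooted = True
            assert phylo.tree_log_likelihood(clone, four_taxon_alignment, jtt) == (
                pytest.approx(ll, abs=1e-8)
            )

    def test_label_mismatch_raises(self, jtt, four_taxon_tree):
        with pytest.raises(ValueError):
            phylo.tree_log_likelihood(
                four_taxon_tree, Alignment({"A": "K", "B": "K"}), jtt
            )

    def test_gamma_changes_likelihood(self, four_taxon_tree, four_taxon_alignment):
        from paleozyme import models

        plain = phylo.tree_log_likelihood(
            four_taxon_tree, four_taxon_alignment, models.jtt()
        )
        gamma = phylo.tree_log_likelihood(
            four_taxon_tree, four_taxon_alignment, models.jtt(gamma_shape=0.5)
        )
        assert plain != gamma


class TestDistancesAndNJ:
    def test_additive_matrix_recovered_exactly(self):
        # hand-built additive distances on ((A,B),(C,D)) with internal edge 0.2
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.3, 0.7, 0.8],
                [0.3, 0.0, 0.8, 0.9],
                [0.7, 0.8, 0.0, 0.5],
                [0.8, 0.9, 0.5, 0.0],
            ]
        )
        tree = phylo.nj_tree(d, labels)
        splits = tree_splits(tree, labels)
        assert frozenset({"C", "D"}) in splits
        pdm = tree.phylogenetic_distance_matrix()
        tns = tree.taxon_namespace
        for i in range(4):
            for j in range(i + 1, 4):
                est = pdm.distance(
                    tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
                )
                assert est == pytest.approx(d[i, j], abs=1e-9)

    def test_identical_sequences_zero_distances(self, jtt):
        aln = Alignment({x: "MKVLDW" for x in "ABC"})
        d, _ = phylo.ml_distances(aln, jtt)
        assert np.allclose(d, 0.0)

    def test_nj_requires_three_taxa(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(np.zeros((2, 2)), ["A", "B"])

    def test_ml_distance_tracks_divergence(self, jtt):
        tree = seqsim.sample_yule_tree(2, 1.0, 1)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.25  # pairwise distance 0.5
        fam = seqsim.evolve_alignment(tree, 2000, jtt, seed=4)
        d, _ = phylo.ml_distances(fam.leaf_alignment, jtt)
        assert d[0, 1] == pytest.approx(0.5, rel=0.15)


class TestSearch:
    def test_true_topology_is_fixed_point(self, jtt):
        tree = seqsim.sample_yule_tree(5, 2.0, 9)
        fam = seqsim.evolve_alignment(tree, 400, jtt, seed=10)
        result, _ = phylo.nni_ml_search(tree.clone(depth=1), fam.leaf_alignment, jtt)
        labels = sorted(fam.leaf_alignment.rows)
        assert tree_splits(result, labels) == tree_splits(tree, labels)

    def test_likelihood_never_decreases(self, jtt, small_family):
        aln = small_family.leaf_alignment
        d, labels = phylo.ml_distances(aln, jtt)
        start = phylo.nj_tree(d, labels)
        start_binary = phylo.ensure_rooted_binary(start.clone(depth=1))
        ll_start = phylo.tree_log_likelihood(start_binary, aln, jtt)
        _, ll_end = phylo.nni_ml_search(start, aln, jtt)
        assert ll_end >= ll_start

    def test_branch_length_optimisation_improves(self, jtt, small_family):
        tree = small_family.tree.clone(depth=1)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.5  # deliberately wrong
        aln = small_family.leaf_alignment
        before = phylo.tree_log_likelihood(tree, aln, jtt)
        after = phylo.optimize_branch_lengths(tree, aln, jtt)
        assert after > before


class TestRooting:
    def test_root_on_central_branch(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        rooted = phylo.root_with_outgroup(tree, {"A", "B"})
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()} for c in children
        ]
        assert {"A", "B"} in sides

    def test_non_monophyletic_outgroup_names_offenders(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        with pytest.raises(ValueError, match="not monophyletic"):
            phylo.root_with_outgroup(tree, {"A", "C"})

    def test_single_leaf_outgroup(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:2):1);", schema="newick")
        rooted = phylo.root_with_outgroup(tree, {"D"})
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"D"} in sides

    def test_improper_outgroup_rejected(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        with pytest.raises(ValueError):
            phylo.root_with_outgroup(tree, {"A", "B", "C", "D"})
        with pytest.raises(ValueError):
            phylo.root_with_outgroup(tree, set())
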