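import dendropy
import numpy as np
import pytest
from scipy.stats import spearmanr

from paleozyme import asr, models, phylo, seqsim
from paleozyme.msa import Alignment, percent_identity


def enumerate_marginals(branch_lengths, alignment, model):
    """Enumeration oracle for ((A,B)N1,(C,D)N2)N0: exact per-node marginal
    posteriors by summing the joint over all internal-state assignments."""
    tu, tv, ta, tb, tc, td = branch_lengths
    pi = model.frequencies
    P = model.transition_matrix
    Pu, Pv, PA, PB, PC, PD = P(tu), P(tv), P(ta), P(tb), P(tc), P(td)
    enc = {k: model.encode(v) for k, v in alignment.rows.items()}
    k = model.n_states
    ncols = alignment.ncols
    out = {n: np.zeros((ncols, k)) for n in ("N0", "N1", "N2")}

    def leafp(Pm, state, obs):
        return 1.0 if obs < 0 else Pm[state, obs]

    for col in range(ncols):
        jr, ju, jv = np.zeros(k), np.zeros(k), np.zeros(k)
        for r in range(k):
            for u in range(k):
                for v in range(k):
                    w = (
                        pi[r] * Pu[r, u] * Pv[r, v]
                        * leafp(PA, u, enc["A"][col]) * leafp(PB, u, enc["B"][col])
                        * leafp(PC, v, enc["C"][col]) * leafp(PD, v, enc["D"][col])
                    )
                    jr[r] += w
                    ju[u] += w
                    jv[v] += w
        out["N0"][col] = jr / jr.sum()
        out["N1"][col] = ju / ju.sum()
        out["N2"][col] = jv / jv.sum()
    return out


class TestMarginalPosteriors:
    def test_matches_enumeration_oracle(self, jtt, four_taxon_tree, four_taxon_alignment):
        posts = asr.marginal_posteriors(four_taxon_tree, four_taxon_alignment, jtt)
        brute = enumerate_marginals(
            (0.15, 0.1, 0.1, 0.2, 0.3, 0.05), four_taxon_alignment, jtt
        )
        for node in ("N0", "N1", "N2"):
            assert np.abs(posts[node] - brute[node]).max() < 1e-8

    def test_zero_branches_certain_ancestor(self, jtt):
        tree = dendropy.Tree.get(
            data="((A:0,B:0)N1:0,(C:0,D:0)N2:0)N0;", schema="newick"
        )
        tree.is_rooted = True
        aln = Alignment({x: "K" for x in "ABCD"})
        posts = asr.marginal_posteriors(tree, aln, jtt)
        assert posts["N0"][0, jtt.alphabet.index("K")] == pytest.approx(1.0)

    def test_stationarity_limit(self, jtt):
        """A node cut off by effectively infinite branches carries no signal:
        its posterior is the equilibrium distribution."""
        tree = dendropy.Tree.get(
            data="((A:40,B:40)N1:40,(C:0.1,D:0.1)N2:0.1)N0;", schema="newick"
        )
        tree.is_rooted = True
        aln = Alignment({"A": "K", "B": "K", "C": "D", "D": "D"})
        posts = asr.marginal_posteriors(tree, aln, jtt)
        assert np.abs(posts["N1"][0] - jtt.frequencies).max() < 1e-4

    def test_posterior_mass_conserved(self, jtt, four_taxon_tree, four_taxon_alignment):
        posts = asr.marginal_posteriors(four_taxon_tree, four_taxon_alignment, jtt)
        for p in posts.values():
            assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-9

    def test_root_marginal_consistent_with_pruning(self, jtt, four_taxon_tree,
                                                   four_taxon_alignment):
        """Up/down passes agree: the root posterior equals the pi-weighted
        root partial of the plain pruning pass."""
        posts = asr.marginal_posteriors(four_taxon_tree, four_taxon_alignment, jtt)
        idx = phylo._TreeIndex(four_taxon_tree)
        data = phylo.encode_alignment(four_taxon_alignment, jtt)
        partials, _, _ = phylo._pruning_pass(idx, data, jtt, 1.0)
        direct = (jtt.frequencies[:, None] * partials[idx.root]).T
        direct /= direct.sum(axis=1, keepdims=True)
        assert np.abs(posts["N0"] - direct).max() < 1e-10

    def test_unrooted_tree_rejected(self, jtt):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        with pytest.raises(ValueError):
            asr.marginal_posteriors(tree, Alignment({x: "K" for x in "ABC"}), jtt)

    def test_gamma_posteriors_still_normalised(self, four_taxon_tree,
                                               four_taxon_alignment):
        m = models.jtt(gamma_shape=0.7)
        posts = asr.marginal_posteriors(four_taxon_tree, four_taxon_alignment, m)
        for p in posts.values():
            assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-9


class TestIndelReconstruction:
    def test_matches_two_state_enumeration(self):
        tree = dendropy.Tree.get(
            data="((A:0.3,B:0.2)N1:0.15,(C:0.3,D:0.1)N2:0.2)N0;", schema="newick"
        )
        tree.is_rooted = True
        aln = Alignment({"A": "K-", "B": "--", "C": "R-", "D": "--"})
        pres = asr.reconstruct_indels(aln, tree, gain_loss_rate=1.0)
        pa = models.presence_absence(1.0)
        brute = enumerate_marginals(
            (0.15, 0.2, 0.3, 0.2, 0.3, 0.1),
            Alignment({"A": "10", "B": "00", "C": "10", "D": "00"}),
            pa,
        )
        for node in ("N0", "N1", "N2"):
            assert np.abs(pres[node] - brute[node][:, 1]).max() < 1e-8

    def test_gap_free_column_fully_present(self):
        tree = dendropy.Tree.get(
            data="((A:0.5,B:0.5)N1:0.5,(C:0.5,D:0.5)N2:0.5)N0;", schema="newick"
        )
        tree.is_rooted = True
        pres = asr.reconstruct_indels(Alignment({x: "KR" for x in "ABCD"}), tree)
        for node in pres.values():
            assert np.all(node == 1.0)

    def test_all_gap_column_absent_everywhere(self):
        tree = dendropy.Tree.get(
            data="((A:0.3,B:0.3)N1:0.3,(C:0.3,D:0.3)N2:0.3)N0;", schema="newick"
        )
        tree.is_rooted = True
        pres = asr.reconstruct_indels(Alignment({x: "-" for x in "ABCD"}), tree)
        for node in pres.values():
            assert np.all(node < 0.5)


class TestMlSequence:
    def test_gap_emitted_when_presence_low(self, jtt):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.1)N1:0.1,(C:0.1,D:0.1)N2:0.1)N0;", schema="newick"
        )
        tree.is_rooted = True
        aln = Alignment({"A": "K-", "B": "K-", "C": "K-", "D": "K-"})
        recs = asr.reconstruct_ancestors(tree, aln, jtt)
        for rec in recs.values():
            assert rec.ml_sequence == "K-"
            assert 0.0 <= rec.mean_posterior <= 1.0

    def test_argmax_ties_break_alphabetically(self):
        rec = asr.AncestralReconstruction(
            node_id="x",
            residue_posteriors=np.zeros((1, 20)),
            presence_posterior=np.ones(1),
            ml_sequence="",
            mean_posterior=0.0,
        )
        # uniform posterior over all residues -> 'A' (alphabetically first)
        post = np.full((1, 20), 1 / 20)
        pres = np.ones(1)
        from paleozyme.models import AA_ALPHABET

        best = post[0].max()
        cands = [i for i in range(20) if post[0, i] >= best - 1e-12]
        assert min(cands, key=lambda i: AA_ALPHABET[i]) == AA_ALPHABET.index("A")
        del rec


class TestExtractAncestor:
    def test_full_clade_returns_root(self, jtt, small_family):
        aln = small_family.leaf_alignment
        recs = asr.reconstruct_ancestors(small_family.tree, aln, jtt)
        rec = asr.extract_ancestor(recs, small_family.tree, set(aln.rows))
        assert rec.node_id == "N0"

    def test_subtree_clade_matches_simulator_node(self, jtt, small_family):
        tree = small_family.tree
        child = [c for c in tree.seed_node.child_nodes() if not c.is_leaf()][0]
        clade = {lf.taxon.label for lf in child.leaf_iter()}
        recs = asr.reconstruct_ancestors(tree, small_family.leaf_alignment, jtt)
        rec = asr.extract_ancestor(recs, tree, clade)
        assert rec.node_id == child.label

    def test_singleton_clade_is_the_leaf(self, jtt, small_family):
        aln = small_family.leaf_alignment
        recs = asr.reconstruct_ancestors(small_family.tree, aln, jtt)
        label = sorted(aln.rows)[0]
        rec = asr.extract_ancestor(recs, small_family.tree, {label}, aln=aln)
        assert rec.node_id == label
        assert rec.ml_sequence == aln.rows[label]

    def test_empty_clade_rejected(self, jtt, small_family):
        with pytest.raises(ValueError):
            asr.extract_ancestor({}, small_family.tree, set())


def test_ancestor_identity_decreases_with_divergence(jtt):
    """Reconstruction accuracy is monotone in divergence (Spearman rho < 0)."""
    scales = [0.2, 0.6, 1.2, 2.0]
    mean_ids = []
    for scale in scales:
        ids = []
        for seed in range(3):
            tree = seqsim.sample_yule_tree(8, 1.0, 100 + seed)
            depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length *= scale / depth
            fam = seqsim.evolve_alignment(tree, 150, jtt, seed=200 + seed)
            recs = asr.reconstruct_ancestors(tree, fam.leaf_alignment, jtt)
            for node, rec in recs.items():
                ids.append(
                    percent_identity(rec.ml_sequence, fam.ancestor_rows[node])
                )
        mean_ids.append(np.mean(ids))
    rho, _ = spearmanr(scales, mean_ids)
    assert rho < 0
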