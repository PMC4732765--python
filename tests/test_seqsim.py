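import numpy as np
import pytest

from paleozyme import kinetics, operon, seqsim
from paleozyme.models import GAP


class TestYuleTree:
    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_shape(self, n):
        tree = seqsim.sample_yule_tree(n, 1.0, 42)
        assert len(tree.leaf_nodes()) == n
        assert len(tree.internal_nodes()) == n - 1
        edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
        assert len(edges) == 2 * n - 2
        assert all(e.length > 0 for e in edges)

    def test_deterministic(self):
        a = seqsim.sample_yule_tree(8, 1.0, 42).as_string(schema="newick")
        b = seqsim.sample_yule_tree(8, 1.0, 42).as_string(schema="newick")
        assert a == b

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            seqsim.sample_yule_tree(1, 1.0, 0)


class TestEvolveAlignment:
    def test_zero_divergence_copies_root(self, jtt):
        tree = seqsim.sample_yule_tree(4, 1.0, 5)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
        fam = seqsim.evolve_alignment(tree, 50, jtt, seed=9)
        root = fam.true_ancestors["N0"]
        assert all(row == root for row in fam.leaf_alignment.rows.values())

    def test_saturation_reaches_background_identity(self, jtt):
        """At branch length 10 the leaf-root identity approaches sum(pi^2)."""
        tree = seqsim.sample_yule_tree(2, 1.0, 1)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = 10.0
        fam = seqsim.evolve_alignment(tree, 1000, jtt, seed=2)
        root = fam.true_ancestors["N0"]
        idents = [
            np.mean([a == b for a, b in zip(row, root)])
            for row in fam.leaf_alignment.rows.values()
        ]
        background = float(np.sum(jtt.frequencies**2))  # ~0.058
        assert np.mean(idents) == pytest.approx(background, abs=0.02)

    def test_no_indels_no_gaps(self, jtt):
        tree = seqsim.sample_yule_tree(5, 1.0, 3)
        fam = seqsim.evolve_alignment(tree, 100, jtt, indel_rate=0.0, seed=4)
        assert all(GAP not in row for row in fam.leaf_alignment.rows.values())

    def test_substitution_count_concentrates(self, jtt):
        """Observed differences on a branch of length t stay within 3 SD of
        the model expectation n*(1 - sum pi_i P_ii(t))."""
        tree = seqsim.sample_yule_tree(2, 1.0, 7)
        t = 0.05
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = t
        n = 2000
        fam = seqsim.evolve_alignment(tree, n, jtt, seed=8)
        root = fam.true_ancestors["N0"]
        p = jtt.transition_matrix(t)
        p_diff = 1.0 - float(np.sum(jtt.frequencies * np.diag(p)))
        sd = np.sqrt(n * p_diff * (1 - p_diff))
        for row in fam.leaf_alignment.rows.values():
            observed = sum(a != b for a, b in zip(row, root))
            assert abs(observed - n * p_diff) <= 3 * sd

    def test_gap_bookkeeping(self, small_family):
        """Dropping all-gap columns never changes any ungapped sequence."""
        aln = small_family.leaf_alignment
        keep = [
            j for j in range(aln.ncols)
            if any(row[j] != GAP for row in aln.rows.values())
        ]
        for label, row in aln.rows.items():
            stripped = "".join(row[j] for j in keep).replace(GAP, "")
            assert stripped == aln.ungapped(label)

    def test_ancestors_recorded_for_all_internal_nodes(self, small_family):
        internal = [n.label for n in small_family.tree.preorder_internal_node_iter()]
        assert set(small_family.true_ancestors) == set(internal)

    def test_determinism(self, jtt):
        t1 = seqsim.sample_yule_tree(5, 1.0, 3)
        t2 = seqsim.sample_yule_tree(5, 1.0, 3)
        f1 = seqsim.evolve_alignment(t1, 80, jtt, indel_rate=0.05, seed=6)
        f2 = seqsim.evolve_alignment(t2, 80, jtt, indel_rate=0.05, seed=6)
        assert f1.leaf_alignment.rows == f2.leaf_alignment.rows
        assert f1.true_ancestors == f2.true_ancestors

    def test_negative_branch_rejected(self, jtt):
        tree = seqsim.sample_yule_tree(3, 1.0, 0)
        next(tree.leaf_node_iter()).edge.length = -0.1
        with pytest.raises(ValueError):
            seqsim.evolve_alignment(tree, 10, jtt, seed=0)


class TestGenomes:
    @staticmethod
    def _families(n):
        return {
            m: {f"sp{i:02d}": "M" + "A" * 20 for i in range(n)}
            for m in ("hisA", "hisF", "hisH")
        }

    @pytest.mark.parametrize("frac,expected", [(1.0, 10), (0.0, 0), (0.5, 5)])
    def test_neighbor_fraction_by_construction(self, frac, expected):
        genomes = seqsim.make_genomes(self._families(10), frac, decoy_genes=8, seed=1)
        passing = operon.scan_neighbor_triplets(genomes, max_intervening=0)
        assert len(passing) == expected

    def test_non_neighbor_genomes_fail_strict_scan(self):
        genomes = seqsim.make_genomes(self._families(12), 0.0, decoy_genes=8, seed=5)
        assert operon.scan_neighbor_triplets(genomes, max_intervening=0) == []
        # scattered markers keep >= 2 intervening genes, so even a relaxed
        # scan with one allowed intervening gene finds nothing
        assert operon.scan_neighbor_triplets(genomes, max_intervening=1) == []

    def test_missing_marker_raises(self):
        with pytest.raises(ValueError):
            seqsim.make_genomes({"hisA": {}, "hisF": {}}, 0.5)


class TestProgressCurves:
    def test_substrate_exhaustion(self):
        curves = seqsim.simulate_progress_curves(
            1.0, 10.0, 1.0, [50.0], noise_sd=0.0, dt=5.0, t_end=2000.0, seed=0
        )
        assert curves[0].product[-1] == pytest.approx(50.0, rel=1e-3)

    def test_matches_closed_form_everywhere(self):
        """Noise-free integration equals the Lambert-W closed form to 0.1%."""
        kcat, km = 0.9, 28.0
        curves = seqsim.simulate_progress_curves(
            kcat, km, 0.5, [100.0], noise_sd=0.0, dt=2.0, t_end=800.0, seed=0
        )
        c = curves[0]
        closed = kinetics.integrated_mm_product(c.times, kcat, km, c.E0, c.S0)
        mask = closed > 1e-6
        assert np.max(np.abs(c.product[mask] - closed[mask]) / closed[mask]) < 1e-3

    def test_first_order_limit(self):
        """S0 << KM: initial slope approaches (kcat/KM) * E0 * S0."""
        kcat, km, e0, s0 = 1.0, 100.0, 0.1, 0.5
        curves = seqsim.simulate_progress_curves(
            kcat, km, e0, [s0], noise_sd=0.0, dt=0.01, t_end=1.0, seed=0
        )
        c = curves[0]
        slope = (c.product[1] - c.product[0]) / (c.times[1] - c.times[0])
        assert slope == pytest.approx(kcat / km * e0 * s0, rel=0.02)

    def test_invalid_s0(self):
        with pytest.raises(ValueError):
            seqsim.simulate_progress_curves(1.0, 10.0, 1.0, [0.0])


class TestIdentityBlocks:
    def test_single_block_full_identity(self):
        seqs = seqsim.make_family_with_identity(5, 50, [(5, 1.0)], seed=0)
        assert len(set(seqs.values())) == 1

    def test_block_identity_hits_target(self):
        from itertools import combinations

        seqs = seqsim.make_family_with_identity(10, 300, [(10, 0.52)], seed=3)
        vals = list(seqs.values())
        idents = [
            100.0 * np.mean([a == b for a, b in zip(x, y)])
            for x, y in combinations(vals, 2)
        ]
        assert np.mean(idents) == pytest.approx(52.0, abs=5.0)

    def test_between_block_identity_near_background(self):
        seqs = seqsim.make_family_with_identity(10, 300, [(5, 0.9), (5, 0.9)], seed=1)
        a = seqs["B1_S001"]
        b = seqs["B2_S006"]
        ident = np.mean([x == y for x, y in zip(a, b)])
        assert ident < 0.15

    def test_unreachable_identity_rejected(self):
        with pytest.raises(ValueError):
            seqsim.make_family_with_identity(4, 100, [(4, 0.01)], seed=0)

    def test_block_sizes_must_sum(self):
        with pytest.raises(ValueError):
            seqsim.make_family_with_identity(5, 100, [(3, 0.9)], seed=0)
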