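"""Distances, neighbor joining and bootstrap."""

import math

import numpy as np
import pytest

import chlorotype as ct
from chlorotype.genome_io import CircularGenome
from chlorotype.phylo import (
    DistanceMatrix,
    alignment_matrix,
    bootstrap_support,
    distance_matrix,
    fit_tn93,
    neighbor_joining,
    tn93_distance,
)

from conftest import random_dna
from oracles import random_additive_tree, simulate_alignment_on_tree


class TestDistances:
    def test_p_distance_direct_count(self, rng):
        a = random_dna(rng, 1000)
        b = list(a)
        pos = rng.choice(1000, size=10, replace=False)
        for p in pos:
            b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
        D, _ = distance_matrix(["a", "b"], [a, "".join(b)], model="p_distance")
        assert D.d[0, 1] == pytest.approx(0.01)

    def test_identical_sequences_distance_zero(self, rng):
        a = random_dna(rng, 500)
        for model in ("p_distance", "tn93_mcl"):
            D, _ = distance_matrix(["a", "b"], [a, a], model=model)
            assert D.d[0, 1] == 0.0

    def test_tn93_hand_formula(self):
        """Check against the closed-form expression evaluated by hand."""
        rng = np.random.default_rng(77)
        a = random_dna(rng, 4000, gc=0.5)
        b = list(a)
        # plant known substitution counts: 12 A<->G, 8 C<->T, 6 transversions
        a_pos = [i for i, c in enumerate(a) if c == "A"]
        c_pos = [i for i, c in enumerate(a) if c == "C"]
        g_pos = [i for i, c in enumerate(a) if c == "G"]
        for i in a_pos[:12]:
            b[i] = "G"
        for i in c_pos[:8]:
            b[i] = "T"
        for i in g_pos[:6]:
            b[i] = "C"
        b = "".join(b)
        mat = alignment_matrix([a, b])
        model = fit_tn93(mat)
        got = tn93_distance(mat, 0, 1, model)
        n = len(a)
        P1, P2, Q = 12 / n, 8 / n, 6 / n
        g = model.freqs
        gR, gY = g["A"] + g["G"], g["C"] + g["T"]
        w1 = 1 - gR * P1 / (2 * g["A"] * g["G"]) - Q / (2 * gR)
        w2 = 1 - gY * P2 / (2 * g["T"] * g["C"]) - Q / (2 * gY)
        w3 = 1 - Q / (2 * gR * gY)
        expect = (
            -(2 * g["A"] * g["G"] / gR) * math.log(w1)
            - (2 * g["T"] * g["C"] / gY) * math.log(w2)
            - 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["T"] * g["C"] * gR / gY)
            * math.log(w3)
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_tn93_converges_to_p_at_low_divergence(self, rng):
        """|tn93 - p| < 1e-6 in the p < 1e-4 regime."""
        a = random_dna(rng, 50000)
        b = list(a)
        for p in rng.choice(len(a), size=4, replace=False):  # p = 8e-5
            b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
        rows = [a, "".join(b)]
        Dt, _ = distance_matrix(["a", "b"], rows, model="tn93_mcl")
        Dp, _ = distance_matrix(["a", "b"], rows, model="p_distance")
        assert Dp.d[0, 1] < 1e-4
        assert abs(Dt.d[0, 1] - Dp.d[0, 1]) < 1e-6

    def test_gap_columns_excluded_pairwise(self):
        rows = ["ACGTACGT--", "ACGTACGTAC", "ACGAACGTAC"]
        D, _ = distance_matrix(["a", "b", "c"], rows, model="p_distance")
        assert D.d[0, 1] == 0.0  # gaps not counted as differences
        assert D.d[0, 2] == pytest.approx(1 / 8)
        assert D.d[1, 2] == pytest.approx(1 / 10)

    def test_complete_deletion_mode(self):
        rows = ["ACGTACGT--", "ACGTACGTAC", "ACGAACGTAC"]
        D, _ = distance_matrix(
            ["a", "b", "c"], rows, model="p_distance", complete_deletion=True
        )
        assert D.d[1, 2] == pytest.approx(1 / 8)

    def test_zero_compared_sites_errors(self):
        with pytest.raises(ValueError, match="zero compared sites"):
            distance_matrix(["a", "b"], ["A---", "-CGT"], model="p_distance")

    def test_pairwise_distance_on_genomes(self, canonical_pair):
        cs, cn, truth = canonical_pair
        d = ct.pairwise_distance(cs, cn, model="p_distance")
        # planted SNPs are the only substitutions; InDel columns are excluded
        expected = len(truth.snps) / len(cn)
        assert d == pytest.approx(expected, rel=0.2)


class TestDistanceMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 1], [2, 0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            DistanceMatrix(
                taxa=["a", "b"], d=np.array([[0, np.nan], [np.nan, 0]])
            )


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            taxa=["x", "y", "z"],
            d=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = neighbor_joining(D)
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths["x"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["y"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["z"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        """NJ on an additive matrix returns the generating tree."""
        rng = np.random.default_rng(40 + n_taxa)
        taxa, D, true_splits, edges = random_additive_tree(n_taxa, rng)
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=D))
        assert tree.bipartitions() == true_splits
        # branch lengths: leaf-to-leaf path lengths through the tree must
        # reproduce the additive matrix
        dist = _tree_leaf_distances(tree)
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert dist[(a, b)] == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_scikit_bio(self):
        """Independent cross-check against an established NJ implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(99)
        taxa, D, true_splits, _ = random_additive_tree(7, rng)
        noise = rng.uniform(0, 0.01, size=D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        Dn = D + noise
        Dn = (Dn + Dn.T) / 2
        ours = neighbor_joining(DistanceMatrix(taxa=taxa, d=Dn))
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        sk_tree = nj(SkDM(Dn, ids=taxa))
        sk_splits = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                other = frozenset(taxa) - side
                sk_splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert ours.bipartitions() == sk_splits

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(taxa=["a", "b"], d=np.array([[0, 1.0], [1.0, 0]]))
            )

    def test_newick_parseable_by_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        taxa, D, _, _ = random_additive_tree(6, rng)
        tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=D))
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(taxa)


def _tree_leaf_distances(tree):
    dist = {}

    def walk(node, acc):
        if not node.children:
            return [(node.name, acc)]
        out = []
        for child, length in node.children:
            out.extend(walk(child, acc + length))
        return out

    # path lengths via the root (valid: root is an internal node of the
    # unrooted tree, all paths pass through tree edges once)
    def pairs(node):
        groups = [walk(child, length) for child, length in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a, da in groups[gi]:
                    for b, db in groups[gj]:
                        dist[tuple(sorted((a, b)))] = da + db
        for child, _ in node.children:
            if child.children:
                pairs(child)

    pairs(tree.root)
    return {(a, b): v for (a, b), v in dist.items()}


class TestBootstrap:
    def test_strong_signal_recovers_true_splits(self):
        """Simulated alignment on a known 6-taxon tree: every true split
        supported at >= 95%."""
        rng = np.random.default_rng(11)
        taxa, D, true_splits, edges = random_additive_tree(6, rng)
        edges = {e: 1.0 for e in edges}  # per-branch substitution prob 0.05
        seqs = simulate_alignment_on_tree(
            edges, taxa, n_sites=1000, sub_prob_per_unit=0.05, rng=rng
        )
        rows = [seqs[t] for t in taxa]
        res = bootstrap_support(taxa, rows, n_reps=100, seed=5, model="p_distance")
        tree_splits = res.tree.bipartitions()
        assert true_splits <= tree_splits
        for split in true_splits:
            assert res.supports[split] >= 95.0

    def test_identical_sequences_degenerate_full_support(self, rng):
        a = random_dna(rng, 200)
        res = bootstrap_support(["x", "y", "z", "w"], [a, a, a, a], n_reps=10, seed=1)
        assert res.degenerate

    def test_invariant_to_taxon_input_order(self):
        rng = np.random.default_rng(21)
        taxa, D, _, edges = random_additive_tree(5, rng)
        seqs = simulate_alignment_on_tree(
            edges, taxa, n_sites=400, sub_prob_per_unit=0.05, rng=rng
        )
        rows = [seqs[t] for t in taxa]
        res1 = bootstrap_support(taxa, rows, n_reps=50, seed=9, model="p_distance")
        perm = taxa[::-1]
        res2 = bootstrap_support(
            perm, [seqs[t] for t in perm], n_reps=50, seed=9, model="p_distance"
        )
        assert res1.supports == res2.supports

    def test_zero_reps_rejected(self, rng):
        a = random_dna(rng, 100)
        with pytest.raises(ValueError):
            bootstrap_support(["a", "b", "c"], [a, a, a], n_reps=0, seed=0)


class TestSpeciesSet:
    def test_planted_sisters_and_distances(self, demo_spec, genome_pair):
        from chlorotype.synth import generate_species_set

        s, n, _ = genome_pair
        taxa_map, truth = generate_species_set(demo_spec, (s, n))
        taxa, rows = ct.star_alignment(list(taxa_map.values()))
        D, _ = distance_matrix(taxa, rows)
        a, b = truth["zero_distance_pair"]
        assert D.value(a, b) == 0.0
        c, d = truth["one_snp_pair"]
        assert 0 < D.value(c, d) < 1e-4
        tree = neighbor_joining(D)
        splits = tree.bipartitions()
        for pair in truth["sister_pairs"]:
            assert frozenset(pair) in splits
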