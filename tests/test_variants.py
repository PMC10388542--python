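"""Anchored alignment vs full dynamic programming, and variant calling."""

import numpy as np
import pytest

import chlorotype as ct
from chlorotype.genome_io import AnnotationFeature
from chlorotype.variants import (
    DivergenceError,
    align_genomes,
    call_variants,
    decompose_mnps,
    gotoh_align,
    variant_counts,
)

from conftest import random_dna
from oracles import gotoh_score_and_ops, leftmost_indel_position, score_ops


def mutate(seq, rng, n_snps=0, indels=()):
    """Apply SNPs then (position-sorted, right-to-left) insertions/deletions."""
    s = list(seq)
    snp_pos = rng.choice(len(s), size=n_snps, replace=False) if n_snps else []
    for p in snp_pos:
        s[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[p]]
    out = "".join(s)
    for pos, ins_seq, del_len in sorted(indels, reverse=True):
        out = out[:pos] + (ins_seq or "") + out[pos + del_len :]
    return out


class TestGotoh:
    @pytest.mark.parametrize("case", range(6))
    def test_matches_plain_python_dp_score(self, case):
        rng = np.random.default_rng(300 + case)
        a = random_dna(rng, int(rng.integers(30, 120)))
        b = mutate(
            a, rng, n_snps=int(rng.integers(0, 4)),
            indels=[(int(rng.integers(5, len(a) - 10)), random_dna(rng, 3), 0)],
        )
        ops = gotoh_align(a, b)
        oracle_score, _ = gotoh_score_and_ops(a, b)
        assert score_ops(ops) == oracle_score

    def test_empty_sides(self):
        assert gotoh_align("", "ACGT") == [("I", 4)]
        assert gotoh_align("ACGT", "") == [("D", 4)]


class TestAlignGenomes:
    def test_self_alignment_is_all_match(self, canonical_pair):
        cs, _, _ = canonical_pair
        aln = align_genomes(cs, cs)
        assert aln.ops == [("=", len(cs))]
        assert aln.identity == 1.0

    def test_planted_insertion_and_snps_exact_op_counts(self, rng):
        ref = random_dna(rng, 5000)
        ins = random_dna(rng, 28)
        qry = mutate(ref, rng, n_snps=3, indels=[(2500, ins, 0)])
        aln = align_genomes(ref, qry)
        counts = aln.op_counts()
        assert counts["I"] == 28
        assert counts["X"] == 3
        assert counts["D"] == 0
        assert counts["="] == 5000 - 3

    @pytest.mark.parametrize("case", range(5))
    def test_event_set_equals_full_needleman_wunsch(self, case):
        """Anchored alignment and full DP give the same variant calls."""
        rng = np.random.default_rng(500 + case)
        n = int(rng.integers(800, 2000))
        ref = random_dna(rng, n)
        indels = []
        # well-separated planted events
        positions = sorted(
            rng.choice(np.arange(100, n - 100), size=3, replace=False), reverse=True
        )
        for i, pos in enumerate(positions):
            if i % 2 == 0:
                indels.append((int(pos), random_dna(rng, int(rng.integers(2, 12))), 0))
            else:
                indels.append((int(pos), "", int(rng.integers(2, 12))))
        qry = mutate(ref, rng, n_snps=4, indels=indels)
        aln_fast = align_genomes(ref, qry)
        ops_full = gotoh_align(ref, qry)  # full DP, no anchoring
        aln_full = ct.PairwiseAlignment("r", "q", ref, qry, ops_full)
        ev_fast = {
            (v.ref_pos, v.type, v.ref_allele, v.alt_allele)
            for v in call_variants(aln_fast, merge_mnp=False)
        }
        ev_full = {
            (v.ref_pos, v.type, v.ref_allele, v.alt_allele)
            for v in call_variants(aln_full, merge_mnp=False)
        }
        assert ev_fast == ev_full
        assert score_ops(aln_fast.ops) == score_ops(ops_full)

    def test_divergent_genomes_rejected(self, rng):
        a = random_dna(rng, 2000)
        b = random_dna(rng, 2000)
        with pytest.raises(DivergenceError, match="divergent"):
            align_genomes(a, b)


class TestCallVariants:
    def test_identical_sequences_no_variants(self, rng):
        s = random_dna(rng, 500)
        assert call_variants(align_genomes(s, s)) == []

    def test_repeat_insertion_left_normalized(self):
        # ACACAC -> ACACACAC : one 2-bp insertion shifted to the run start
        ref = "GGGT" + "ACACAC" + "TGGG"
        qry = "GGGT" + "ACACACAC" + "TGGG"
        variants = call_variants(align_genomes(ref, qry))
        assert len(variants) == 1
        v = variants[0]
        assert v.type == "insertion"
        assert v.length == 2
        # oracle: smallest equivalent placement
        oracle_pos0 = leftmost_indel_position(ref, qry)
        assert v.ref_pos == oracle_pos0  # anchor base sits just before the run
        assert v.alt_allele[1:] == "AC"

    @pytest.mark.parametrize("case", range(5))
    def test_single_indel_position_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(700 + case)
        ref = random_dna(rng, 300, gc=0.2)  # AT-rich: repeat-prone
        pos = int(rng.integers(50, 250))
        if case % 2:
            qry = mutate(ref, rng, indels=[(pos, random_dna(rng, 4, gc=0.2), 0)])
        else:
            qry = mutate(ref, rng, indels=[(pos, "", 4)])
        variants = call_variants(align_genomes(ref, qry))
        assert len(variants) == 1
        v = variants[0]
        oracle_pos0 = leftmost_indel_position(ref, qry)
        # VCF anchor base is one left of the event start (or at it, at pos 0)
        assert v.ref_pos == max(oracle_pos0, 1)

    def test_signed_indel_sum_equals_length_difference(self, rng):
        ref = random_dna(rng, 3000)
        qry = mutate(
            ref,
            rng,
            n_snps=5,
            indels=[(2400, random_dna(rng, 22), 0), (800, "", 9), (300, "AT", 0)],
        )
        variants = call_variants(align_genomes(ref, qry))
        assert sum(v.signed_length for v in variants) == len(qry) - len(ref)

    def test_symmetry_under_swapping_genomes(self, rng):
        ref = random_dna(rng, 1500)
        qry = mutate(ref, rng, n_snps=2, indels=[(700, random_dna(rng, 6), 0)])
        fwd = call_variants(align_genomes(ref, qry), merge_mnp=False)
        rev = call_variants(align_genomes(qry, ref), merge_mnp=False)
        assert len(fwd) == len(rev)
        fwd_alleles = sorted((v.type, v.ref_allele, v.alt_allele) for v in fwd)
        swap = {"insertion": "deletion", "deletion": "insertion", "SNP": "SNP"}
        rev_alleles = sorted(
            (swap[v.type], v.alt_allele, v.ref_allele) for v in rev
        )
        assert fwd_alleles == rev_alleles

    def test_mnp_merge_and_decompose_modes(self):
        ref = "AAAACCCCGGGG"
        qry = "AAAATTCCGGGG"  # two adjacent mismatches
        aln = align_genomes(ref, qry)
        merged = call_variants(aln, merge_mnp=True)
        assert [v.type for v in merged] == ["MNP"]
        assert merged[0].length == 2
        split = decompose_mnps(merged)
        assert [v.type for v in split] == ["SNP", "SNP"]
        direct = call_variants(aln, merge_mnp=False)
        assert [(v.ref_pos, v.alt_allele) for v in split] == [
            (v.ref_pos, v.alt_allele) for v in direct
        ]
        counts = variant_counts(merged)
        assert counts["snp_events"] == 1
        assert counts["snp_sites"] == 2

    def test_context_annotation(self, rng):
        ref = random_dna(rng, 1000)
        feats = [
            AnnotationFeature("geneA", "gene", 100, 300),
            AnnotationFeature("geneB", "gene", 600, 800),
        ]
        qry = mutate(ref, rng, indels=[(450, "CGTA", 0)])  # between the genes
        s = list(ref)
        s[150] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[150]]  # inside geneA
        qry = mutate("".join(s), rng, indels=[(450, "CGTA", 0)])
        variants = call_variants(align_genomes(ref, qry), annotation=feats)
        genic = [v for v in variants if v.context == "genic"]
        inter = [v for v in variants if v.context == "intergenic"]
        assert len(genic) == 1 and genic[0].context_detail == "geneA"
        assert len(inter) == 1 and inter[0].context_detail == "geneA-geneB"


class TestGeneVariantScan:
    def test_planted_snp_counted_once(self, rng):
        ref = random_dna(rng, 800)
        feats = [AnnotationFeature("G1", "gene", 100, 400)]
        s = list(ref)
        s[200] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[200]]
        variants = call_variants(align_genomes(ref, "".join(s)), annotation=feats)
        assert ct.gene_variant_scan(variants, ["G1"], feats) == {"G1": 1}

    def test_empty_variant_list_all_zero(self, canonical_pair):
        cs, _, _ = canonical_pair
        names = ["ndhD", "psaA", "psaB"]
        assert ct.gene_variant_scan([], names, cs.features) == {
            "ndhD": 0, "psaA": 0, "psaB": 0,
        }

    def test_unknown_gene_lists_available(self, canonical_pair):
        cs, _, _ = canonical_pair
        with pytest.raises(KeyError, match="nonexistent"):
            ct.gene_variant_scan([], ["nonexistent"], cs.features)

    def test_photosystem_genes_have_no_variation_in_demo_pair(
        self, canonical_pair, demo_variants
    ):
        """Cytotype differences lie in spacers, not conserved genes."""
        cs, _, truth = canonical_pair
        counts = ct.gene_variant_scan(
            demo_variants, ["ndhD", "psaA", "psaB"], cs.features
        )
        # SNPs may land anywhere outside marker spacers, so check against truth
        snp_hits = {g: 0 for g in counts}
        for g in counts:
            feats = [f for f in cs.features if f.name == g]
            for snp in truth.snps:
                for f in feats:
                    if f.start <= snp["pos"] < f.end:
                        snp_hits[g] += 1
        assert counts == snp_hits


def test_vcf_output_is_parseable(tmp_path, canonical_pair, demo_variants):
    cs, _, _ = canonical_pair
    path = tmp_path / "out.vcf"
    ct.write_vcf(demo_variants, cs.id, len(cs), str(path))
    lines = path.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.3"
    body = [l for l in lines if not l.startswith("#")]
    assert len(body) == len(demo_variants)
    for line in body:
        cols = line.split("\t")
        pos, ref_allele = int(cols[1]), cols[3]
        # REF field must match the reference sequence
        assert cs.sequence[pos - 1 : pos - 1 + len(ref_allele)] == ref_allele
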