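"""Region extraction, variant calling and coding-effect annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from haplomarker import (GeneModel, annotate_effect, apply_variants,
                         call_variants_from_alignment, extract_gene_region)
from haplomarker.errors import RegionError
from haplomarker.gene_region_effects import cds_sequence, _left_normalize
from haplomarker.genomic_io import RegionSequence, VariantRecord, revcomp
from conftest import make_toy_gene, random_seq


class TestExtraction:
    def test_plus_strand_region_length(self):
        rng = np.random.default_rng(0)
        chrom = random_seq(rng, 7000)
        g = GeneModel("g", "c", "+", 2501, 5500, ((2501, 5500),), 2000, 1000)
        r = extract_gene_region({"c": chrom}, g)
        assert len(r.seq) == 2000 + 3000 + 1000
        assert r.seq == chrom[500:6500]

    def test_truncation_at_chromosome_start_warns(self):
        rng = np.random.default_rng(1)
        chrom = random_seq(rng, 3000)
        g = GeneModel("g", "c", "+", 501, 1100, ((501, 1100),), 2000, 1000)
        with pytest.warns(UserWarning, match="truncated"):
            r = extract_gene_region({"c": chrom}, g)
        assert r.upstream_len == 500
        assert len(r.seq) == 500 + 600 + 1000

    def test_minus_strand_is_reverse_complement(self):
        rng = np.random.default_rng(2)
        chrom = random_seq(rng, 300)
        g = GeneModel("g", "c", "-", 220, 161, ((161, 220),), 30, 20)
        r = extract_gene_region({"c": chrom}, g)
        assert r.seq == revcomp(chrom[140:250])

    def test_absent_chromosome(self):
        g = GeneModel("g", "nope", "+", 11, 40, ((11, 40),), 5, 5)
        with pytest.raises(RegionError, match="nope"):
            extract_gene_region({"c": "ACGT" * 100}, g)


class TestCalling:
    def test_identical_sample_yields_no_variants(self, toy_gene):
        _, _, region = toy_gene
        smp = RegionSequence("s", "toy", region.seq, region.upstream_len,
                             region.downstream_len)
        variants, geno = call_variants_from_alignment(region, [smp])
        assert variants == []

    def test_substitution_coordinates(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 2600)
        ref = RegionSequence("ref", "g", seq, 2000, 300)
        col = 2004  # 0-based offset of ATG-relative +5
        alt = "A" if seq[col] != "A" else "G"
        smp = RegionSequence("s", "g", seq[:col] + alt + seq[col + 1:],
                             2000, 300)
        variants, geno = call_variants_from_alignment(ref, [smp])
        assert len(variants) == 1
        v = variants[0]
        assert (v.atg_pos, v.ref_allele, v.alt_allele) == (5, seq[col], alt)
        assert geno.loc[v.variant_id, "s"] == 1

    def test_deletion_in_homopolymer_reported_leftmost(self):
        rng = np.random.default_rng(4)
        left, right = random_seq(rng, 60), random_seq(rng, 60)
        left = left[:-1] + "C"          # stop leftward normalization here
        seq = left + "AAAA" + right
        ref = RegionSequence("ref", "g", seq, 30, 30)
        smp = RegionSequence("s", "g", left + "AAA" + right, 30, 30)
        variants, _ = call_variants_from_alignment(ref, [smp])
        assert len(variants) == 1
        v = variants[0]
        # oracle: smallest equivalent placement is the first A (offset 60)
        assert v.vclass == "deletion"
        assert v.atg_pos == ref.offset_to_atg(60)

    def test_ambiguous_sample_skipped(self, toy_gene):
        _, _, region = toy_gene
        bad = RegionSequence("bad", "toy", "N" * len(region.seq),
                             region.upstream_len, region.downstream_len)
        with pytest.warns(UserWarning, match="ambiguous"):
            variants, geno = call_variants_from_alignment(region, [bad])
        assert "bad" not in geno.columns

    @pytest.mark.parametrize("seed", range(12))
    def test_call_apply_round_trip(self, seed):
        """Calling then re-applying variants reconstructs each sample."""
        rng = np.random.default_rng(seed)
        gene, chrom = make_toy_gene(rng, n_exons=2, exon_len=60,
                                    intron_len=40, upstream=150,
                                    downstream=90)
        ref = extract_gene_region({"chr": chrom}, gene)
        seq = list(ref.seq)
        # random edits: substitutions and a small indel, well separated
        n = len(seq)
        for off in (40, 200, 330):
            seq[off] = "ACGT"[(("ACGT".index(seq[off])) + 1) % 4]
        del_at = 120
        mutant = "".join(seq[:del_at] + seq[del_at + 3:])
        ins_at = 260
        mutant = mutant[:ins_at] + "TTGCA" + mutant[ins_at:]
        smp = RegionSequence("s", "toy", mutant, ref.upstream_len,
                             ref.downstream_len)
        variants, geno = call_variants_from_alignment(ref, [smp])
        carried = [v for v in variants if geno.loc[v.variant_id, "s"] == 1]
        assert apply_variants(ref, carried) == mutant


class TestLeftNormalize:
    def test_exhaustive_equivalence_oracle(self):
        seq = "GGATTTTACC"   # T homopolymer at offsets 3..6
        # delete any single T of the run: all equivalent, leftmost is 3
        for pos in range(3, 7):
            p, r, a = _left_normalize(seq, pos, "T", "")
            assert (p, r, a) == (3, "T", "")
        # insertion of T anywhere within the run normalizes to before pos 3
        for pos in range(3, 8):
            p, r, a = _left_normalize(seq, pos, "", "T")
            assert (p, r, a) == (3, "", "T")


def _brute_force_snp_effect(cds_ref: str, cds_alt: str) -> str:
    """Independent oracle: translate both CDS and compare proteins."""
    p_ref = str(Seq(cds_ref).translate())
    p_alt = str(Seq(cds_alt).translate())
    if cds_alt[:3] != "ATG":
        return "start_loss"
    if p_ref == p_alt:
        return "synonymous"
    # position of first difference
    i = next(k for k, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b)
    if p_ref[i] == "*":
        return "stop_loss"
    if p_alt[i] == "*":
        return "premature_stop"
    return "missense"


class TestEffects:
    def test_frameshift_deletions_of_published_sizes(self, toy_gene):
        """In-CDS deletions of 13, 1 and 373 bp all shift the frame."""
        rng = np.random.default_rng(7)
        gene, chrom = make_toy_gene(rng, n_exons=1, exon_len=1200,
                                    intron_len=0, upstream=80,
                                    downstream=60)
        ref = extract_gene_region({"chr": chrom}, gene)
        for size in (13, 1, 373):
            off = ref.atg_to_offset(30)
            v = VariantRecord("d", 30, -1, ref.seq[off:off + size], "",
                              "deletion")
            assert annotate_effect(v, gene, ref).effect == "frameshift"
        v = VariantRecord("d", 30, -1, ref.seq[off:off + 9], "", "deletion")
        assert annotate_effect(v, gene, ref).effect == "inframe_indel"

    def test_upstream_snp_is_noncoding(self, toy_gene):
        gene, _, ref = toy_gene
        base = ref.base_at(-100)
        v = VariantRecord("u", -100, -1, base,
                          "A" if base != "A" else "C", "SNP")
        out = annotate_effect(v, gene, ref)
        assert (out.region, out.effect) == ("5'UTR", "noncoding")

    def test_stop_gain_from_codon_substitution(self):
        rng = np.random.default_rng(8)
        gene, chrom = make_toy_gene(rng, n_exons=1, exon_len=90,
                                    upstream=50, downstream=40)
        ref = extract_gene_region({"chr": chrom}, gene)
        cds = cds_sequence(ref, gene)
        # find a mid-CDS codon one substitution away from a stop
        for i in range(1, len(cds) // 3 - 1):
            codon = cds[i * 3:i * 3 + 3]
            for j, stop in ((1, "TAG"), (0, "TAA"), (2, "TGA")):
                for stop_c in ("TAA", "TAG", "TGA"):
                    diffs = [k for k in range(3) if codon[k] != stop_c[k]]
                    if len(diffs) == 1:
                        k = diffs[0]
                        atg = i * 3 + k + 1
                        v = VariantRecord("s", atg, -1, codon[k], stop_c[k],
                                          "SNP")
                        out = annotate_effect(v, gene, ref)
                        assert out.effect == "premature_stop"
                        return
        pytest.skip("no single-substitution stop in this toy CDS")

    def test_variant_outside_region_errors(self, toy_gene):
        gene, _, ref = toy_gene
        v = VariantRecord("x", gene.max_atg + 500, -1, "A", "C", "SNP")
        with pytest.raises(Exception):
            annotate_effect(v, gene, ref)

    @pytest.mark.parametrize("batch", range(4))
    def test_snp_effects_match_translation_oracle(self, batch):
        """Annotation agrees with whole-CDS translation on random SNPs."""
        rng = np.random.default_rng(100 + batch)
        checked = 0
        while checked < 300:
            gene, chrom = make_toy_gene(rng, n_exons=int(rng.integers(1, 4)),
                                        exon_len=30, intron_len=20,
                                        upstream=40, downstream=30)
            ref = extract_gene_region({"chr": chrom}, gene)
            cds = cds_sequence(ref, gene)
            for _ in range(10):
                idx = int(rng.integers(0, len(cds)))
                alt = "ACGT"[int(rng.integers(0, 4))]
                if cds[idx] == alt:
                    continue
                # map CDS index back to an ATG coordinate
                from haplomarker.genomic_io import exon_intervals_atg
                left = idx
                for lo, hi in exon_intervals_atg(gene):
                    ln = hi - lo + 1
                    if left < ln:
                        atg = lo + left
                        break
                    left -= ln
                v = VariantRecord("r", atg, -1, cds[idx], alt, "SNP")
                got = annotate_effect(v, gene, ref).effect
                want = _brute_force_snp_effect(
                    cds, cds[:idx] + alt + cds[idx + 1:])
                assert got == want, (cds, idx, alt)
                checked += 1

    def test_exonic_snp_effects_are_exclusive(self, mimic_suite):
        coding = {"synonymous", "missense", "premature_stop", "start_loss",
                  "stop_loss"}
        for panel in mimic_suite.values():
            for v in panel.variants:
                if v.vclass == "SNP" and v.region.startswith("exon"):
                    assert v.effect in coding
                else:
                    assert v.effect in ("noncoding", "frameshift",
                                        "inframe_indel")
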