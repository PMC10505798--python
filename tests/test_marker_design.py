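"""Restriction scanning, digestion arithmetic, primer and marker design."""

import numpy as np
import pytest

from haplomarker import (VariantRecord, design_caps, design_dcaps,
                         design_indel_marker, design_primer_pair, find_caps,
                         predict_digestion, scan_restriction_sites)
from haplomarker.errors import DesignError
from haplomarker.genomic_io import IUPAC, EnzymeDef, revcomp
from haplomarker.marker_design import (DEFAULT_ENZYMES, build_amplicon,
                                       cut_positions, digest,
                                       format_reference_size,
                                       parse_reference_size, wallace_tm)
from conftest import random_seq

ECO_RI = DEFAULT_ENZYMES[0]
HHA_I = DEFAULT_ENZYMES[2]
PST_I = DEFAULT_ENZYMES[3]


def brute_force_scan(seq: str, enzyme: EnzymeDef) -> list[int]:
    """Independent oracle: IUPAC-expanded substring comparison, both
    strands."""
    seq = seq.upper()
    motifs = {enzyme.motif.upper(), revcomp(enzyme.motif.upper())}
    hits = set()
    for motif in motifs:
        for p in range(len(seq) - len(motif) + 1):
            window = seq[p:p + len(motif)]
            if all(b in IUPAC[m] for b, m in zip(window, motif)):
                hits.add(p + 1)
    return sorted(hits)


class TestScan:
    def test_no_match(self):
        assert scan_restriction_sites("TTTTTT", HHA_I) == []

    def test_simple_match_one_based(self):
        assert scan_restriction_sites("AAGAATTCAA", ECO_RI) == [3]

    def test_iupac_degenerate_match(self):
        eco2 = DEFAULT_ENZYMES[1]
        assert scan_restriction_sites("ACCAGGA", eco2) == [2]
        assert scan_restriction_sites("ACCTGGA", eco2) == [2]
        assert scan_restriction_sites("ACCGGGA", eco2) == []

    def test_n_in_sequence_never_matches(self):
        assert scan_restriction_sites("AAGAATNCAA", ECO_RI) == []

    def test_non_palindromic_motif_scans_both_strands(self):
        enz = EnzymeDef("toy", "GACTC", 1)
        # revcomp(GACTC) = GAGTC present on the top strand
        assert scan_restriction_sites("TTGAGTCTT", enz) == [3]

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(17)
        enzymes = list(DEFAULT_ENZYMES) + [EnzymeDef("toy", "GANTC", 1),
                                           EnzymeDef("toy2", "RGCGCY", 2)]
        for _ in range(2000):
            seq = random_seq(rng, int(rng.integers(4, 40)))
            if rng.integers(4) == 0:   # sprinkle Ns
                pos = int(rng.integers(0, len(seq)))
                seq = seq[:pos] + "N" + seq[pos + 1:]
            e = enzymes[int(rng.integers(len(enzymes)))]
            assert scan_restriction_sites(seq, e) == brute_force_scan(seq, e)


class TestDigestion:
    def test_no_sites(self):
        assert predict_digestion(210, []) == [210]

    def test_published_fragment_arithmetic(self):
        assert predict_digestion(423, [202]) == [202, 221]

    def test_two_cuts_three_fragments(self):
        frags = predict_digestion(100, [30, 70])
        assert sorted(frags) == [30, 30, 40]
        assert sum(frags) == 100

    def test_conservation_on_random_digests(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            ln = int(rng.integers(50, 2000))
            cuts = sorted(set(rng.integers(1, ln, rng.integers(0, 6))))
            frags = predict_digestion(ln, cuts)
            assert sum(frags) == ln
            assert len(frags) == len(cuts) + 1

    def test_cut_positions_respect_offsets(self):
        # G^AATTC: cut after the G
        amp = "AAAGAATTCAAA"
        assert cut_positions(amp, ECO_RI) == [4]
        assert digest(amp, ECO_RI) == [4, 8]


class TestFindCaps:
    def test_alt_allele_completes_pst_site(self):
        left = "TTGACCTAGGATCGTACGATTAGCGA"
        ctx = left + "CTGC" + "C" + "GTTACGATCGGATTACGGTTAAGCGA"
        v = VariantRecord("t", 100, -1, "C", "A", "SNP")
        hits = find_caps(v, ctx, DEFAULT_ENZYMES, snp_index=len(left) + 4)
        assert ("Pst I", "alt") in [(e.name, a) for e, a in hits]

    def test_no_motif_for_either_allele(self):
        ctx = "T" * 21
        v = VariantRecord("t", 100, -1, "T", "G", "SNP")
        assert find_caps(v, ctx, [ECO_RI, HHA_I], snp_index=10) == []

    def test_site_in_both_alleles_excluded(self):
        # CCWGG covers the SNP with W: both A and T alleles match
        eco2 = DEFAULT_ENZYMES[1]
        ctx = "AAAACC" + "A" + "GGAAAA"
        v = VariantRecord("t", 100, -1, "A", "T", "SNP")
        assert find_caps(v, ctx, [eco2], snp_index=6) == []


class TestPrimerPair:
    def test_product_spans_target_within_range(self):
        rng = np.random.default_rng(31)
        template = random_seq(rng, 500)
        f, r = design_primer_pair(template, (240, 260), (100, 300))
        product = r.end - f.start + 1
        assert 100 <= product <= 300
        assert f.start <= 240 and r.end >= 260
        assert f.end < 240 and r.start > 260
        for p in (f, r):
            assert 18 <= len(p.seq) <= 24
            assert 52 <= wallace_tm(p.seq) <= 62
            assert p.seq[-1] in "GC"
        assert abs(f.tm - r.tm) <= 5
        # the reverse primer is the reverse complement of its binding site
        assert revcomp(r.seq) == template[r.start:r.end + 1]

    def test_impossible_product_range(self):
        rng = np.random.default_rng(32)
        template = random_seq(rng, 200)
        with pytest.raises(DesignError, match="product"):
            design_primer_pair(template, (90, 110), (10, 20))

    def test_failure_reports_most_violated_constraint(self):
        template = "AT" * 200   # Tm and GC hopeless everywhere
        with pytest.raises(DesignError, match="constraint"):
            design_primer_pair(template, (190, 210), (100, 300))


class TestDcaps:
    def _toy(self, seed=11):
        rng = np.random.default_rng(seed)
        ctx = random_seq(rng, 150) + "GACTT" + "T" + random_seq(rng, 150)
        v = VariantRecord("toy", 500, -1, "T", "C", "SNP")
        return v, ctx, 155

    def test_single_mismatch_creates_site_in_alt_only(self):
        v, ctx, idx = self._toy()
        m = design_dcaps(v, ctx, DEFAULT_ENZYMES, snp_index=idx,
                         elite_allele="alt")
        assert m.enzyme.name == "EcoR I"
        assert m.mtype == "dCAPS"
        mismatch_primer = m.fwd if m.fwd.mismatch_positions else m.rev
        assert len(mismatch_primer.mismatch_positions) == 1
        assert sum(c.islower() for c in mismatch_primer.seq) == 1
        # soundness: re-scan both primer-modified allele amplicons
        alt_ctx = ctx[:idx] + "C" + ctx[idx + 1:]
        amp_ref = build_amplicon(ctx, m.fwd, m.rev)
        amp_alt = build_amplicon(alt_ctx, m.fwd, m.rev)
        assert cut_positions(amp_alt, m.enzyme)
        assert not cut_positions(amp_ref, m.enzyme)
        # bands: cut allele is elite (alt)
        assert len(m.elite_bands) == 2 and len(m.other_bands) == 1
        assert sum(m.elite_bands) == sum(m.other_bands)

    def test_mismatch_never_at_primer_3prime_end(self):
        v, ctx, idx = self._toy(12)
        m = design_dcaps(v, ctx, DEFAULT_ENZYMES, snp_index=idx)
        p = m.fwd if m.fwd.mismatch_positions else m.rev
        assert (len(p.seq) - 1) not in p.mismatch_positions

    def test_infeasible_when_every_placement_needs_two_mismatches(self):
        rng = np.random.default_rng(13)
        # poly-C context: EcoR I placements always need >= 2 edits
        ctx = "C" * 150 + "C" + "C" * 150
        v = VariantRecord("toy", 500, -1, "C", "G", "SNP")
        with pytest.raises(DesignError, match="k=1"):
            design_dcaps(v, ctx, [ECO_RI], snp_index=150, k=1)

    def test_amplicon_within_requested_range(self):
        v, ctx, idx = self._toy(14)
        m = design_dcaps(v, ctx, DEFAULT_ENZYMES, snp_index=idx,
                         amplicon_range=(100, 300))
        assert 100 <= sum(m.other_bands) <= 300


class TestIndelMarker:
    def _indel_ctx(self, seed, size, kind):
        rng = np.random.default_rng(seed)
        ctx = random_seq(rng, 400 + (size if kind == "deletion" else 0)
                         + 400)
        idx = 400
        if kind == "deletion":
            v = VariantRecord("d", -900, -1, ctx[idx:idx + size], "",
                              "deletion")
        else:
            v = VariantRecord("i", -900, -1, "", random_seq(rng, size),
                              "insertion")
        return v, ctx, idx

    def test_17bp_deletion_band_sizes_differ_by_size(self):
        v, ctx, idx = self._indel_ctx(41, 17, "deletion")
        m = design_indel_marker(v, ctx, indel_offset=idx, elite_allele="alt")
        (eb,), (ob,) = m.elite_bands, m.other_bands
        assert ob - eb == 17
        assert 100 <= ob <= 300

    def test_large_insertion_long_allele_in_400_1000(self):
        v, ctx, idx = self._indel_ctx(42, 391, "insertion")
        m = design_indel_marker(v, ctx, indel_offset=idx, elite_allele="alt")
        (eb,), (ob,) = m.elite_bands, m.other_bands
        assert eb - ob == 391
        assert 400 <= eb <= 1000
        assert ob >= 100

    def test_size_classes_rejected_outside_rules(self):
        for size in (3, 50):
            v, ctx, idx = self._indel_ctx(43, size, "deletion")
            with pytest.raises(DesignError, match="size class"):
                design_indel_marker(v, ctx, indel_offset=idx)
        # but the override designs anyway
        v, ctx, idx = self._indel_ctx(44, 50, "deletion")
        m = design_indel_marker(v, ctx, indel_offset=idx, force=True)
        assert m.mtype == "Indel" and m.enzyme is None


class TestCaps:
    def test_caps_marker_discriminates(self):
        rng = np.random.default_rng(51)
        left = random_seq(rng, 520)
        right = random_seq(rng, 520)
        ctx = left[:-2] + "GC" + "T" + "C" + right[2:]
        v = VariantRecord("c", 551, -1, "T", "G", "SNP")
        m = design_caps(v, ctx, [HHA_I], snp_index=520, elite_allele="ref")
        assert m.enzyme.name == "Hha I"
        assert sorted(m.elite_bands) != sorted(m.other_bands)
        assert sum(m.elite_bands) == sum(m.other_bands)
        assert 300 <= sum(m.elite_bands) <= 800

    def test_caps_requires_natural_site(self):
        ctx = "T" * 1041
        v = VariantRecord("c", 551, -1, "T", "G", "SNP")
        with pytest.raises(DesignError, match="no natural"):
            design_caps(v, ctx, [HHA_I], snp_index=520)


class TestReferenceSizeNotation:
    @pytest.mark.parametrize("text,elite,other,indel", [
        ("423/(202, 221)", (423,), (202, 221), None),
        ("(20, 175)/195", (20, 175), (195,), None),
        ("(+391)/262", (653,), (262,), 391),
        ("(-17)/179", (162,), (179,), -17),
        ("866/(-514)", (866,), (352,), -514),
    ])
    def test_parse_published_notations(self, text, elite, other, indel):
        out = parse_reference_size(text)
        assert out["elite_bands"] == elite
        assert out["other_bands"] == other
        assert out["indel_size"] == indel

    def test_format_round_trips_through_parse(self):
        rng = np.random.default_rng(61)
        v, ctx, idx = TestIndelMarker()._indel_ctx(62, 17, "deletion")
        m = design_indel_marker(v, ctx, indel_offset=idx, elite_allele="alt")
        txt = format_reference_size(m)
        out = parse_reference_size(txt)
        assert out["elite_bands"] == m.elite_bands
        assert out["other_bands"] == m.other_bands
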