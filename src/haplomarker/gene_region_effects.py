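"""Gene-region extraction, variant calling and coding-effect annotation.

The analysis region of a gene is the 2-kb window upstream of the start
codon, the unspliced ORF, and the 1-kb window downstream of the stop codon,
always on the coding strand.  Variants are called per accession against the
reference region by global pairwise alignment, left-normalized, and
annotated with a region label (5'UTR / exon k / intron k / 3'UTR) and a
coding effect (synonymous, missense, premature_stop, start_loss, stop_loss,
inframe_indel, frameshift, noncoding).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import RegionError
from .genomic_io import (GeneModel, RegionSequence, VariantRecord,
                         atg_to_genomic, exon_intervals_atg, region_of,
                         revcomp)

FUNCTIONAL_EFFECTS = frozenset({
    "missense", "inframe_indel", "frameshift", "premature_stop",
    "start_loss", "stop_loss",
})

# global aligner for desk-scale gene regions: match 2, mismatch -3,
# gap of length L costs 7 + 2L
_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -3
_ALIGNER.open_gap_score = -9
_ALIGNER.extend_gap_score = -2


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def extract_gene_region(genome: Mapping[str, str], gene: GeneModel,
                        accession_id: str = "reference") -> RegionSequence:
    """Slice the analysis region of ``gene`` from ``genome``, coding strand.

    The region is truncated (with a warning) where it would run past a
    chromosome end.
    """
    if gene.chrom not in genome:
        raise RegionError(f"chromosome {gene.chrom!r} absent from genome")
    chrom_seq = genome[gene.chrom]
    if gene.strand == "+":
        lo = gene.atg_genomic_pos - gene.upstream_len
        hi = gene.stop_end_genomic_pos + gene.downstream_len
    else:
        lo = gene.stop_end_genomic_pos - gene.downstream_len
        hi = gene.atg_genomic_pos + gene.upstream_len
    t_lo, t_hi = max(lo, 1), min(hi, len(chrom_seq))
    if (t_lo, t_hi) != (lo, hi):
        warnings.warn(
            f"{gene.gene_id}: analysis region truncated at a chromosome end "
            f"({t_lo - lo} bp lost upstream, {hi - t_hi} bp downstream on "
            "the genomic axis)")
    raw = chrom_seq[t_lo - 1:t_hi].upper()
    if gene.strand == "+":
        seq = raw
        upstream = gene.atg_genomic_pos - t_lo
        downstream = t_hi - gene.stop_end_genomic_pos
    else:
        seq = revcomp(raw)
        upstream = t_hi - gene.atg_genomic_pos
        downstream = gene.stop_end_genomic_pos - t_lo
    return RegionSequence(accession_id=accession_id, gene_id=gene.gene_id,
                          seq=seq, upstream_len=upstream,
                          downstream_len=downstream)


def cds_sequence(ref: RegionSequence, gene: GeneModel) -> str:
    """Spliced CDS of the reference region, coding order."""
    parts = []
    for lo, hi in exon_intervals_atg(gene):
        parts.append(ref.seq[ref.atg_to_offset(lo):ref.atg_to_offset(hi) + 1])
    return "".join(parts)


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def _left_normalize(seq: str, pos: int, ref: str, alt: str
                    ) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent placement on ``seq``.

    ``pos`` is the 0-based offset of the first deleted base (deletion) or of
    the base before which the insertion sits (insertion of ``alt`` before
    ``seq[pos]`` conceptually handled via the deleted/inserted string).
    """
    allele = ref or alt
    while pos > 0 and allele and seq[pos - 1] == allele[-1]:
        pos -= 1
        allele = seq[pos] + allele[:-1] if ref else allele[-1] + allele[:-1]
        # for a deletion the deleted string tracks the reference window;
        # for an insertion the string rotates
    if ref:
        return pos, allele, alt
    return pos, ref, allele


def _diffs_from_alignment(ref_seq: str, sample_seq: str,
                          aligned: bool) -> list[tuple[int, str, str]]:
    """Yield (ref_offset, ref_allele, alt_allele) differences.

    Offsets are 0-based on the *ungapped* reference.  For insertions the
    offset is that of the reference base before which the insertion occurs.
    """
    if aligned or len(ref_seq) == len(sample_seq):
        a, b = ref_seq, sample_seq
    else:
        aln = _ALIGNER.align(ref_seq, sample_seq)[0]
        a, b = str(aln[0]), str(aln[1])
    diffs: list[tuple[int, str, str]] = []
    ref_off = 0  # bases of ungapped reference consumed
    i = 0
    n = len(a)
    while i < n:
        ca, cb = a[i], b[i]
        if ca != "-" and cb != "-":
            if ca != cb:
                diffs.append((ref_off, ca, cb))
            ref_off += 1
            i += 1
        elif ca == "-":           # insertion relative to reference
            j = i
            ins = []
            while j < n and a[j] == "-":
                ins.append(b[j])
                j += 1
            diffs.append((ref_off, "", "".join(ins)))
            i = j
        else:                      # deletion relative to reference
            j = i
            dele = []
            while j < n and b[j] == "-" and a[j] != "-":
                dele.append(a[j])
                j += 1
            diffs.append((ref_off, "".join(dele), ""))
            ref_off += j - i
            i = j
    return diffs


def call_variants_from_alignment(ref: RegionSequence,
                                 samples: Sequence[RegionSequence],
                                 aligned: bool = False,
                                 max_ambiguous_frac: float = 0.5,
                                 ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Call SNPs and indels of each sample against the reference region.

    When ``aligned`` is true (or the lengths already match) sequences are
    treated as alignment columns; otherwise each sample is globally aligned
    to the reference.  Returns the merged, left-normalized variant list (in
    ATG-coordinate order) and a variant-by-accession genotype table
    (0 = reference allele, 1 = alternate allele of that row).

    Samples whose sequence is more than ``max_ambiguous_frac`` non-ACGT are
    skipped with a warning.
    """
    ref_seq = ref.seq.upper()
    per_sample: dict[str, set[tuple]] = {}
    catalog: dict[tuple, VariantRecord] = {}
    for smp in samples:
        seq = smp.seq.upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if len(seq) and acgt / len(seq) < 1 - max_ambiguous_frac:
            warnings.warn(
                f"sample {smp.accession_id}: >{max_ambiguous_frac:.0%} "
                "ambiguous bases, skipped")
            continue
        keys = set()
        if aligned:
            if len(seq) != len(ref_seq):
                raise RegionError(
                    f"sample {smp.accession_id}: pre-aligned input must "
                    "match reference length")
            # strip shared gap columns is not needed for equal ungapped input
        for off, rallele, aallele in _diffs_from_alignment(
                ref_seq, seq, aligned):
            if rallele and aallele and len(rallele) == 1:
                vclass = "SNP"
                pos_off = off
            elif not rallele:                      # insertion before off
                pos_off, rallele, aallele = _left_normalize(
                    ref_seq, off, rallele, aallele)
                vclass = "insertion"
            else:                                   # deletion at off
                pos_off, rallele, aallele = _left_normalize(
                    ref_seq, off, rallele, aallele)
                vclass = "deletion"
            if vclass == "insertion":
                # anchor on the last reference base before the insertion
                atg = ref.offset_to_atg(max(pos_off - 1, 0))
            else:
                atg = ref.offset_to_atg(pos_off)
            key = (atg, rallele, aallele)
            if key not in catalog:
                catalog[key] = VariantRecord(
                    variant_id=f"{ref.gene_id}_{len(catalog) + 1:04d}",
                    atg_pos=atg, genomic_pos=-1, ref_allele=rallele,
                    alt_allele=aallele, vclass=vclass)
            keys.add(key)
        per_sample[smp.accession_id] = keys
    order = sorted(catalog, key=lambda k: (k[0], k[1], k[2]))
    variants = [catalog[k] for k in order]
    # re-number ids in coordinate order for stable output
    variants = [VariantRecord(variant_id=f"{ref.gene_id}_{i + 1:04d}",
                              atg_pos=v.atg_pos, genomic_pos=v.genomic_pos,
                              ref_allele=v.ref_allele,
                              alt_allele=v.alt_allele, vclass=v.vclass)
                for i, v in enumerate(catalog[k] for k in order)]
    geno = pd.DataFrame(
        {acc: [1 if key in keys else 0 for key in order]
         for acc, keys in per_sample.items()},
        index=[v.variant_id for v in variants], dtype="Int64")
    return variants, geno


def apply_variants(ref: RegionSequence, variants: Sequence[VariantRecord]
                   ) -> str:
    """Rebuild an accession's region sequence from reference + variants."""
    edits = []
    for v in variants:
        off = ref.atg_to_offset(v.atg_pos)
        if v.vclass == "SNP":
            edits.append((off, off + 1, v.alt_allele))
        elif v.vclass == "deletion":
            edits.append((off, off + len(v.ref_allele), ""))
        else:  # insertion after the anchor base at off
            edits.append((off + 1, off + 1, v.alt_allele))
    edits.sort(key=lambda e: e[0])
    for (s1, e1, _), (s2, _, _) in zip(edits, edits[1:]):
        if s2 < e1:
            raise RegionError("overlapping variants cannot be applied")
    out, cur = [], 0
    for s, e, ins in edits:
        out.append(ref.seq[cur:s])
        out.append(ins)
        cur = e
    out.append(ref.seq[cur:])
    return "".join(out)


# ---------------------------------------------------------------------------
# effect annotation
# ---------------------------------------------------------------------------

def _cds_index(atg: int, gene: GeneModel) -> int | None:
    """0-based index into the spliced CDS, or None for non-exonic bases."""
    consumed = 0
    for lo, hi in exon_intervals_atg(gene):
        if lo <= atg <= hi:
            return consumed + (atg - lo)
        consumed += hi - lo + 1
    return None


def _cds_span_removed(atg_first: int, length: int, gene: GeneModel) -> int:
    """Number of CDS bases inside [atg_first, atg_first+length-1]."""
    # the span is contiguous on the unspliced axis; +1 has no 0 predecessor
    positions = 0
    span_lo, span_hi = atg_first, atg_first + length - 1
    for lo, hi in exon_intervals_atg(gene):
        a, b = max(lo, span_lo), min(hi, span_hi)
        if a <= b:
            positions += b - a + 1
    return positions


def annotate_effect(v: VariantRecord, gene: GeneModel, ref: RegionSequence
                    ) -> VariantRecord:
    """Return a copy of ``v`` with ``region`` and ``effect`` filled in.

    Exonic SNPs are classified by translating the affected codon with both
    alleles; exonic indels by whether the number of removed/inserted CDS
    bases is a multiple of three.  A variant that touches both exon and
    intron is labelled by the exon it disrupts.
    """
    ref.atg_to_offset(v.atg_pos)  # raises if outside the region
    region = region_of(v.atg_pos, gene)
    effect = "noncoding"
    cds = cds_sequence(ref, gene)

    if v.vclass == "SNP":
        idx = _cds_index(v.atg_pos, gene)
        if idx is not None:
            codon_i = idx // 3
            codon = cds[codon_i * 3:codon_i * 3 + 3]
            pos_in = idx % 3
            alt_codon = codon[:pos_in] + v.alt_allele + codon[pos_in + 1:]
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq(alt_codon).translate())
            if codon_i == 0:
                effect = "synonymous" if aa_alt == aa_ref else "start_loss"
                if alt_codon != "ATG":
                    effect = "start_loss"
            elif aa_ref == "*":
                effect = "synonymous" if aa_alt == "*" else "stop_loss"
            elif aa_alt == "*":
                effect = "premature_stop"
            elif aa_alt == aa_ref:
                effect = "synonymous"
            else:
                effect = "missense"
        else:
            region_final = region
            return VariantRecord(**{**v.__dict__, "region": region_final,
                                    "effect": "noncoding"})
    else:
        if v.vclass == "deletion":
            first = v.atg_pos
            removed = _cds_span_removed(first, len(v.ref_allele), gene)
            touched_exon = removed > 0
            n_cds = removed
        else:  # insertion between anchor and the next base
            anchor_idx = _cds_index(v.atg_pos, gene)
            nxt = v.atg_pos + 1 if v.atg_pos != -1 else 1
            next_idx = None
            try:
                next_idx = _cds_index(nxt, gene)
            except Exception:  # pragma: no cover - end of region
                next_idx = None
            touched_exon = anchor_idx is not None and next_idx is not None
            n_cds = len(v.alt_allele) if touched_exon else 0
        if touched_exon:
            # relabel region by the exon touched if the anchor sits outside
            if not region.startswith("exon"):
                for k, (lo, hi) in enumerate(exon_intervals_atg(gene), 1):
                    if v.vclass == "deletion" and \
                            max(lo, v.atg_pos) <= min(hi, v.atg_pos + len(v.ref_allele) - 1):
                        region = f"exon {k}"
                        break
            effect = "frameshift" if n_cds % 3 else "inframe_indel"
        else:
            effect = "noncoding"

    if not region.startswith("exon") and effect != "noncoding" \
            and v.vclass == "SNP":  # pragma: no cover - geometry guard
        raise RegionError("exonic effect assigned to non-exonic SNP")
    return VariantRecord(**{**v.__dict__, "region": region, "effect": effect})


def annotate_all(variants: Sequence[VariantRecord], gene: GeneModel,
                 ref: RegionSequence) -> list[VariantRecord]:
    """Annotate region/effect and fill genomic coordinates for a batch."""
    out = []
    for v in variants:
        av = annotate_effect(v, gene, ref)
        gpos = atg_to_genomic(av.atg_pos, gene)
        out.append(VariantRecord(**{**av.__dict__, "genomic_pos": gpos}))
    return out
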