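"""Readers, writers and the two coordinate systems of the pipeline.

Everything downstream works on the *coding strand* of one gene at a time,
in a signed start-codon-relative coordinate system: the A of the ATG is
``+1``, the base immediately upstream is ``-1`` and there is no zero.  The
axis counts genomic (unspliced) bases, so intronic and downstream positions
are reachable (e.g. a position a few kb into intron 1 is simply a large
positive value).  Genomic coordinates are 1-based closed, the GFF3/VCF
convention.

This module owns:

* :class:`GeneModel` -- the anchor of the coordinate system,
* conversion between genomic and ATG-relative coordinates,
* GFF3 gene-model ingestion (via :mod:`gffutils`),
* VCF variant-matrix ingestion (via :mod:`cyvcf2`) and a minimal writer,
* FASTA and TSV readers/writers for panels, metadata and enzyme tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, GffError, VcfFormatError

SUBPOPULATIONS = (
    "XI", "XI-IM", "IM", "GJ-IM", "GJ-tem", "GJ-tro", "VI/Aro", "aus", "other",
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware, case preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Coordinates of one protein-coding gene.

    ``exons`` are the CDS intervals (1-based, closed, genomic), listed in
    coding order: ascending genomic position on the plus strand, descending
    on the minus strand.  ``atg_genomic_pos`` is the genomic coordinate of
    the A of the start codon; ``stop_end_genomic_pos`` that of the last base
    of the stop codon.
    """

    gene_id: str
    chrom: str
    strand: str
    atg_genomic_pos: int
    stop_end_genomic_pos: int
    exons: tuple[tuple[int, int], ...]
    upstream_len: int = 2000
    downstream_len: int = 1000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GffError(f"{self.gene_id}: strand must be '+' or '-'")
        cds_len = sum(e - s + 1 for s, e in self.exons)
        if cds_len % 3:
            raise GffError(
                f"{self.gene_id}: CDS length not a multiple of 3 ({cds_len})")
        # exons in coding order, non-overlapping
        starts = [s for s, _ in self.exons]
        ordered = sorted(starts, reverse=self.strand == "-")
        if starts != ordered:
            raise GffError(f"{self.gene_id}: exons not in coding order")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if min(e1, e2) >= max(s1, s2):
                raise GffError(f"{self.gene_id}: overlapping exons")
        first = self.exons[0]
        if not first[0] <= self.atg_genomic_pos <= first[1]:
            raise GffError(f"{self.gene_id}: ATG not inside the first exon")

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def body_len(self) -> int:
        """Unspliced length from the A of ATG through the end of the stop."""
        return abs(self.stop_end_genomic_pos - self.atg_genomic_pos) + 1

    @property
    def region_len(self) -> int:
        return self.upstream_len + self.body_len + self.downstream_len

    @property
    def max_atg(self) -> int:
        """Largest valid ATG-relative coordinate of the analysis region."""
        return self.body_len + self.downstream_len


@dataclass(frozen=True)
class AccessionMeta:
    accession_id: str
    subpopulation: str = "other"


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction enzyme: recognition motif (IUPAC) and top-strand cut.

    ``cut_offset`` is the number of motif bases left of the cut on the top
    strand: ``GAATTC`` with offset 1 cuts G^AATTC.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"{self.name}: motif shorter than 4 nt")
        bad = set(self.motif.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC motif codes {bad}")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(f"{self.name}: cut offset outside motif")

    @property
    def palindromic(self) -> bool:
        return revcomp(self.motif.upper()) == self.motif.upper()


@dataclass(frozen=True)
class VariantRecord:
    """One polymorphism on the coding strand of a gene region.

    Alleles are stored *unanchored*: a SNP has two single bases, an
    insertion has ``ref_allele == ""`` and a deletion has
    ``alt_allele == ""``.  ``atg_pos`` is the first deleted/substituted base
    for SNPs and deletions, and the last reference base before the inserted
    sequence for insertions (the VCF anchor).  Indels are left-normalized.
    """

    variant_id: str
    atg_pos: int
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    vclass: str                       # SNP | insertion | deletion
    region: str | None = None         # 5'UTR | exon k | intron k | 3'UTR
    effect: str | None = None

    def __post_init__(self) -> None:
        if self.atg_pos == 0:
            raise CoordinateError("no zero coordinate on the ATG axis")
        if self.vclass == "SNP":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNP alleles must be single bases")
        elif self.vclass == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion must have empty ref allele")
        elif self.vclass == "deletion":
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion must have empty alt allele")
        else:
            raise ValueError(f"unknown variant class {self.vclass!r}")

    @property
    def indel_len(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    def key(self) -> tuple:
        return (self.atg_pos, self.ref_allele, self.alt_allele)


@dataclass
class RegionSequence:
    """Coding-strand sequence of one accession's gene region.

    ``upstream_len`` is the number of upstream bases actually present
    (smaller than the requested length when the region was truncated at a
    chromosome end).
    """

    accession_id: str
    gene_id: str
    seq: str
    upstream_len: int
    downstream_len: int

    def __len__(self) -> int:
        return len(self.seq)

    # -- ATG axis <-> 0-based offset into seq -----------------------------
    def atg_to_offset(self, atg: int) -> int:
        if atg == 0:
            raise CoordinateError("no zero coordinate on the ATG axis")
        off = atg + self.upstream_len if atg < 0 else self.upstream_len + atg - 1
        if not 0 <= off < len(self.seq):
            raise CoordinateError(
                f"ATG-relative position {atg:+d} outside the region")
        return off

    def offset_to_atg(self, off: int) -> int:
        if not 0 <= off < len(self.seq):
            raise CoordinateError(f"offset {off} outside the region")
        return off - self.upstream_len if off < self.upstream_len \
            else off - self.upstream_len + 1

    def base_at(self, atg: int) -> str:
        return self.seq[self.atg_to_offset(atg)]


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def atg_to_genomic(atg: int, gene: GeneModel) -> int:
    """Map a signed ATG-relative coordinate to a genomic coordinate."""
    if atg == 0:
        raise CoordinateError("no zero coordinate on the ATG axis")
    if atg < -gene.upstream_len or atg > gene.max_atg:
        raise CoordinateError(
            f"{atg:+d} outside the analysis region of {gene.gene_id}")
    step = atg - 1 if atg > 0 else atg
    return gene.atg_genomic_pos + step if gene.strand == "+" \
        else gene.atg_genomic_pos - step


def genomic_to_atg(pos: int, gene: GeneModel) -> int:
    """Inverse of :func:`atg_to_genomic` over the gene's analysis region."""
    delta = pos - gene.atg_genomic_pos if gene.strand == "+" \
        else gene.atg_genomic_pos - pos
    atg = delta + 1 if delta >= 0 else delta
    if atg < -gene.upstream_len or atg > gene.max_atg:
        raise CoordinateError(
            f"genomic {pos} outside the analysis region of {gene.gene_id}")
    return atg


def exon_intervals_atg(gene: GeneModel) -> list[tuple[int, int]]:
    """Exon (CDS) intervals on the ATG axis, in coding order."""
    out = []
    for s, e in gene.exons:
        a, b = genomic_to_atg(s, gene), genomic_to_atg(e, gene)
        out.append((min(a, b), max(a, b)))
    return out


def region_of(atg: int, gene: GeneModel) -> str:
    """Label a position: 5'UTR, exon k, intron k or 3'UTR.

    Following the convention of gene-region haplotype studies, the whole
    upstream window is labelled 5'UTR and the downstream window 3'UTR.
    """
    if atg < 0:
        return "5'UTR"
    if atg > gene.body_len:
        return "3'UTR"
    for k, (lo, hi) in enumerate(exon_intervals_atg(gene), start=1):
        if lo <= atg <= hi:
            return f"exon {k}"
        if atg < lo:
            return f"intron {k - 1}"
    return f"intron {len(gene.exons)}"  # pragma: no cover - geometry exhausts


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path,
                     gene_ids: Sequence[str] | None = None,
                     upstream_len: int = 2000,
                     downstream_len: int = 1000) -> list[GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 file.

    One model per gene; when a gene has several mRNAs the first in file
    order is used.  Minus-strand genes are normalized so exons are listed
    in coding order.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        if gene_ids is not None and gid not in gene_ids:
            continue
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            raise GffError(f"gene {gid}: no CDS features")
        # restrict to the first mRNA when several are annotated
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            first = mrnas[0]
            cds = list(db.children(first, featuretype="CDS", order_by="start"))
            if not cds:
                raise GffError(f"gene {gid}: mRNA without CDS")
        ivals = sorted((c.start, c.end) for c in cds)
        if gene.strand == "-":
            ivals = ivals[::-1]
        atg = ivals[0][0] if gene.strand == "+" else ivals[0][1]
        stop_end = ivals[-1][1] if gene.strand == "+" else ivals[-1][0]
        models.append(GeneModel(
            gene_id=gid, chrom=gene.seqid, strand=gene.strand,
            atg_genomic_pos=atg, stop_end_genomic_pos=stop_end,
            exons=tuple(ivals), upstream_len=upstream_len,
            downstream_len=downstream_len))
    if gene_ids is not None:
        found = {m.gene_id for m in models}
        missing = [g for g in gene_ids if g not in found]
        if missing:
            raise GffError(f"genes not found in GFF3: {', '.join(missing)}")
    return models


def write_gff3(path: str | Path, gene: GeneModel) -> None:
    """Write a minimal GFF3 (gene/mRNA/exon/CDS) for one gene."""
    lo = min(gene.atg_genomic_pos, gene.stop_end_genomic_pos)
    hi = max(gene.atg_genomic_pos, gene.stop_end_genomic_pos)
    gid = gene.gene_id
    rows = [
        (gene.chrom, "haplomarker", "gene", lo, hi, ".", gene.strand, ".",
         f"ID={gid};Name={gid}"),
        (gene.chrom, "haplomarker", "mRNA", lo, hi, ".", gene.strand, ".",
         f"ID={gid}.1;Parent={gid}"),
    ]
    for i, (s, e) in enumerate(sorted(gene.exons), start=1):
        rows.append((gene.chrom, "haplomarker", "exon", s, e, ".",
                     gene.strand, ".", f"ID={gid}.1.exon{i};Parent={gid}.1"))
        rows.append((gene.chrom, "haplomarker", "CDS", s, e, ".",
                     gene.strand, "0", f"ID={gid}.1.cds{i};Parent={gid}.1"))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_matrix(path: str | Path,
                        panel: Sequence[AccessionMeta] | None = None,
                        ) -> tuple[list[dict], pd.DataFrame]:
    """Read a VCF into biallelic variant rows and a genotype table.

    Returns ``(variants, genotypes)`` where ``variants`` is a list of dicts
    with keys ``variant_id, chrom, genomic_pos, ref, alt`` (anchored VCF
    alleles, multi-allelic records split into biallelic rows) and
    ``genotypes`` is a variant-by-accession ``DataFrame`` of nullable
    integers: 0 = homozygous ref, 1 = homozygous alt of that row, ``NA`` =
    missing or heterozygous (unassignable in an inbred panel).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # noqa: BLE001 - cyvcf2 raises plain Exception
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if panel is not None:
        panel_ids = {a.accession_id for a in panel}
        extra = [s for s in samples if s not in panel_ids]
        if extra:
            warnings.warn(
                f"{len(extra)} VCF sample(s) not in the metadata panel: "
                + ", ".join(extra[:5]))
    variants: list[dict] = []
    rows: list[list] = []
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            gts = rec.genotypes  # [a1, a2, phased] per sample
            for j, alt in enumerate(rec.ALT, start=1):
                vid = rec.ID if rec.ID and len(rec.ALT) == 1 else (
                    f"{rec.ID or rec.CHROM + '_' + str(rec.POS)}_{j}"
                    if len(rec.ALT) > 1 else
                    f"{rec.CHROM}_{rec.POS}")
                variants.append(dict(variant_id=vid, chrom=rec.CHROM,
                                     genomic_pos=rec.POS, ref=rec.REF,
                                     alt=alt))
                calls = []
                for g in gts:
                    a1, a2 = g[0], g[1]
                    if a1 < 0 or a2 < 0 or a1 != a2:
                        calls.append(pd.NA)
                    elif a1 == j:
                        calls.append(1)
                    else:
                        calls.append(0)
                rows.append(calls)
    except VcfFormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise VcfFormatError(
            f"malformed VCF record near data line {lineno + 1}: {exc}"
        ) from exc
    geno = pd.DataFrame(rows, columns=samples,
                        index=[v["variant_id"] for v in variants],
                        dtype="Int64")
    return variants, geno


def write_vcf(path: str | Path, chrom: str, contig_len: int,
              records: Sequence[dict], genotypes: pd.DataFrame) -> None:
    """Write a minimal VCF 4.2 with homozygous GT calls.

    ``records`` need keys ``variant_id, genomic_pos, ref, alt`` (anchored
    alleles); ``genotypes`` is a variant-by-accession table of 0/1/NA.
    """
    samples = list(genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplomarker\n")
        fh.write(f"##contig=<ID={chrom},length={contig_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in sorted(records, key=lambda r: r["genomic_pos"]):
            calls = genotypes.loc[rec["variant_id"]]
            gt = ["./." if pd.isna(calls[s]) else
                  ("1/1" if calls[s] == 1 else "0/0") for s in samples]
            fh.write(f"{chrom}\t{rec['genomic_pos']}\t{rec['variant_id']}\t"
                     f"{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(gt) + "\n")


# ---------------------------------------------------------------------------
# FASTA / TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_accession_meta(path: str | Path) -> list[AccessionMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession_id", "subpopulation"} <= set(df.columns):
        raise VcfFormatError(
            "metadata TSV needs columns accession_id, subpopulation")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise VcfFormatError(f"duplicate accession id {dup!r} in metadata")
    return [AccessionMeta(r.accession_id, r.subpopulation)
            for r in df.itertuples()]


def write_accession_meta(path: str | Path, panel: Sequence[AccessionMeta]) -> None:
    pd.DataFrame({"accession_id": [a.accession_id for a in panel],
                  "subpopulation": [a.subpopulation for a in panel]}
                 ).to_csv(path, sep="\t", index=False)


def read_enzyme_table(path: str | Path) -> list[EnzymeDef]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "motif": str,
                                            "cut_offset": int})
    return [EnzymeDef(r.name, r.motif.upper(), int(r.cut_offset))
            for r in df.itertuples()]


def variant_table(variants: Sequence[VariantRecord],
                  genotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate variant records (one row each), optionally with genotypes."""
    df = pd.DataFrame({
        "variant_id": [v.variant_id for v in variants],
        "atg_pos": [v.atg_pos for v in variants],
        "genomic_pos": [v.genomic_pos for v in variants],
        "ref_allele": [v.ref_allele for v in variants],
        "alt_allele": [v.alt_allele for v in variants],
        "vclass": [v.vclass for v in variants],
        "region": [v.region for v in variants],
        "effect": [v.effect for v in variants],
    }).set_index("variant_id")
    if genotypes is not None:
        df = df.join(genotypes)
    return df


def write_variant_table(path: str | Path, variants: Sequence[VariantRecord],
                        genotypes: pd.DataFrame | None = None) -> None:
    variant_table(variants, genotypes).to_csv(path, sep="\t", na_rep=".")


def read_variant_table(path: str | Path
                       ) -> tuple[list[VariantRecord], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["."])
    fixed = ["variant_id", "atg_pos", "genomic_pos", "ref_allele",
             "alt_allele", "vclass", "region", "effect"]
    variants = []
    for r in df.itertuples():
        variants.append(VariantRecord(
            variant_id=r.variant_id, atg_pos=int(r.atg_pos),
            genomic_pos=int(r.genomic_pos),
            ref_allele="" if pd.isna(r.ref_allele) else r.ref_allele,
            alt_allele="" if pd.isna(r.alt_allele) else r.alt_allele,
            vclass=r.vclass,
            region=None if pd.isna(r.region) else r.region,
            effect=None if pd.isna(r.effect) else r.effect))
    acc_cols = [c for c in df.columns if c not in fixed]
    geno = df[acc_cols].apply(pd.to_numeric).astype("Int64")
    geno.index = df["variant_id"]
    return variants, geno
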