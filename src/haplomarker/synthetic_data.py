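"""Synthetic germplasm panels with planted, verified haplotype structure.

The generator emulates the study design behind gene-region haplotype
surveys of crop panels: a reference gene (upstream window, multi-exon ORF,
downstream window), a panel of inbred accessions partitioned into haplotype
groups by planted protein-altering variants and into haplotypes by planted
silent variants, an elite group carrying private alleles, and rare novel
haplotypes below the reporting threshold.  Every planted effect label is
verified at build time by re-annotating against the generated reference
(mutant-codon translation), and infeasible or confounded draws are
rejected and resampled.

Two entry points:

* :func:`simulate_panel` -- a randomized panel from a :class:`PanelConfig`;
* :func:`paper_mimic_suite` -- five fixed panel designs that reproduce the
  qualitative structure of the five rice salt-tolerance genes (a
  four-missense elite group; a premature-stop elite group with a natural
  CAPS site; two elite groups plus a promoter-indel elite pair; an elite
  group with exactly two private variants amenable only to dCAPS; an elite
  pair with a large promoter deletion), each supporting the same diagnostic
  marker types as the published marker set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError
from .gene_region_effects import (annotate_effect, apply_variants,
                                  extract_gene_region, cds_sequence,
                                  _left_normalize)
from .genomic_io import (AccessionMeta, GeneModel, RegionSequence,
                         VariantRecord, atg_to_genomic, write_accession_meta,
                         write_fasta, write_gff3, write_vcf,
                         write_variant_table)
from .haplotyping import EliteDefinition

CHROM_ID = "chr1"
PAD = 60            # chromosome padding either side of the analysis region
MIN_SPACING = 14    # clear bases demanded between planted variant spans

DEFAULT_SUBPOP_WEIGHTS: dict[str, float] = {
    "XI": 0.38, "XI-IM": 0.07, "IM": 0.05, "GJ-IM": 0.05,
    "GJ-tem": 0.15, "GJ-tro": 0.10, "VI/Aro": 0.05, "aus": 0.10,
    "other": 0.05,
}

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS and a + b + c != "ATG"]


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantPlan:
    """One planted polymorphism: where, what kind, and who carries it."""

    vid: str
    region: str                      # 5'UTR | exon | intron | 3'UTR
    kind: str                        # missense | synonymous | noncoding |
    #                                  premature_stop | deletion | insertion
    carriers: frozenset[str]         # hap ids carrying the alternate allele
    size: int = 0                    # indel length
    atg_pos: int | None = None       # requested position (local search around)
    embed_before: str = ""
    embed_after: str = ""
    ref_base: str | None = None
    alt_base: str | None = None
    frame_mod: int | None = None     # required CDS index of the SNP mod 3
    margin: int = 40                 # clear flank inside the region


@dataclass(frozen=True)
class HapPlan:
    hap_id: str
    group_id: str
    size: int
    novel: bool = False


@dataclass(frozen=True)
class EliteDefPlan:
    name: str
    alleles: Mapping[str, str]       # vid -> "REF" | "ALT"


@dataclass(frozen=True)
class QueryPlan:
    """A unique-variant query: elite targets and the planted answer."""

    name: str
    targets: tuple[str, ...]         # group ids and/or hap ids
    exclude: tuple[str, ...] = ()


@dataclass(frozen=True)
class MarkerPlan:
    name: str
    mtype: str                       # Indel | CAPS | dCAPS
    vid: str
    elite_allele: str                # ref | alt
    query: str                       # QueryPlan.name whose targets it detects
    enzymes: tuple[str, ...] = ()    # restrict to these enzyme names


@dataclass
class PanelPlan:
    gene_id: str
    seed: int
    haps: list[HapPlan]
    variants: list[VariantPlan]
    elite_defs: list[EliteDefPlan] = field(default_factory=list)
    queries: list[QueryPlan] = field(default_factory=list)
    marker_plans: list[MarkerPlan] = field(default_factory=list)
    upstream_len: int = 2000
    downstream_len: int = 1000
    exon_lens: tuple[int, ...] = (300, 300, 300)
    intron_lens: tuple[int, ...] = (300, 300)
    subpop_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_WEIGHTS))
    min_novel_size: int = 5


@dataclass(frozen=True)
class PanelConfig:
    """Knobs of the randomized generator.

    The defaults describe a desk-scale but structurally faithful panel: 60
    inbred accessions across the rice subpopulations, a three-exon gene
    with the standard 2-kb upstream / 1-kb downstream analysis windows,
    one reference group, one elite group defined by two exonic missense
    variants, three further groups from private missense variants, four
    silent variants splitting groups into haplotypes, and one rare novel
    haplotype below the five-accession reporting threshold.
    """

    seed: int = 0
    n_accessions: int = 60
    subpop_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBPOP_WEIGHTS))
    upstream_len: int = 2000
    downstream_len: int = 1000
    exon_lens: tuple[int, ...] = (300, 300, 300)
    intron_lens: tuple[int, ...] = (300, 300)
    n_functional_variants: int = 3   # non-elite groups, one private variant each
    n_silent_variants: int = 4
    elite_spec: tuple[str, ...] = ("exon", "exon")  # defining-variant regions
    rare_haplotype_sizes: tuple[int, ...] = (4,)
    indel_sizes: tuple[int, ...] = ()
    min_novel_size: int = 5

    def __post_init__(self) -> None:
        total = sum(self.subpop_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("subpopulation weights must sum to 1")
        if sum(self.exon_lens) % 3:
            raise ConfigError("total exon length must be a multiple of 3")
        if len(self.intron_lens) != len(self.exon_lens) - 1:
            raise ConfigError("need one fewer intron than exons")


@dataclass
class PanelTruth:
    """Ground truth of a simulated panel."""

    hap_members: dict[str, tuple[str, ...]]
    group_members: dict[str, tuple[str, ...]]
    novel_haps: set[str]
    dropped_accessions: set[str]
    elite_defs: dict[str, EliteDefinition]
    queries: list[dict]              # name, targets, exclude, expected_unique
    hap_group: dict[str, str]

    def kept_hap_members(self, min_novel_size: int = 5
                         ) -> dict[str, tuple[str, ...]]:
        return {h: m for h, m in self.hap_members.items()
                if not (h in self.novel_haps and len(m) < min_novel_size)}

    def expected_hap_sets(self, min_novel_size: int = 5) -> set[frozenset]:
        return {frozenset(m)
                for m in self.kept_hap_members(min_novel_size).values()}

    def expected_group_sets(self, min_novel_size: int = 5) -> set[frozenset]:
        out: dict[str, set[str]] = {}
        for h, members in self.kept_hap_members(min_novel_size).items():
            out.setdefault(self.hap_group[h], set()).update(members)
        return {frozenset(m) for m in out.values() if m}

    def target_member_set(self, targets: Iterable[str],
                          min_novel_size: int = 5) -> frozenset:
        kept = self.kept_hap_members(min_novel_size)
        members: set[str] = set()
        for t in targets:
            for h, m in kept.items():
                if h == t or self.hap_group[h] == t:
                    members.update(m)
        return frozenset(members)


@dataclass
class SimulatedPanel:
    """A fully materialized synthetic panel plus its ground truth."""

    plan: PanelPlan
    gene: GeneModel
    chrom_seq: str
    ref_region: RegionSequence
    variants: list[VariantRecord]
    genotypes: pd.DataFrame
    panel: list[AccessionMeta]
    sequenced: list[str]
    reference_accession: str
    truth: PanelTruth
    _seq_cache: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def gene_id(self) -> str:
        return self.plan.gene_id

    def variant(self, vid: str) -> VariantRecord:
        for v in self.variants:
            if v.variant_id == vid:
                return v
        raise KeyError(vid)

    def sequences(self) -> dict[str, str]:
        """Per-accession region sequences rebuilt from reference + variants."""
        if not self._seq_cache:
            for acc in self.genotypes.columns:
                carried = [v for v in self.variants
                           if self.genotypes.at[v.variant_id, acc] == 1]
                self._seq_cache[acc] = apply_variants(self.ref_region, carried)
        return dict(self._seq_cache)

    def elite_definitions(self) -> dict[str, EliteDefinition]:
        return self.truth.elite_defs

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "gff3": outdir / "gene.gff3",
            "panel_fasta": outdir / "panel.fa",
            "vcf": outdir / "panel.vcf",
            "meta": outdir / "panel_meta.tsv",
            "variants": outdir / "variants.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(paths["reference"], {CHROM_ID: self.chrom_seq})
        write_gff3(paths["gff3"], self.gene)
        write_fasta(paths["panel_fasta"], self.sequences())
        records = [self._anchored_vcf_record(v) for v in self.variants]
        write_vcf(paths["vcf"], CHROM_ID, len(self.chrom_seq), records,
                  self.genotypes)
        write_accession_meta(paths["meta"], self.panel)
        write_variant_table(paths["variants"], self.variants, self.genotypes)
        rows = []
        for h, members in self.truth.hap_members.items():
            for acc in members:
                rows.append((acc, self.truth.hap_group[h], h,
                             h in self.truth.novel_haps))
        pd.DataFrame(rows, columns=["accession_id", "group", "haplotype",
                                    "novel"]
                     ).to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def _anchored_vcf_record(self, v: VariantRecord) -> dict:
        reg = self.ref_region
        if v.vclass == "SNP":
            return dict(variant_id=v.variant_id, genomic_pos=v.genomic_pos,
                        ref=v.ref_allele, alt=v.alt_allele)
        if v.vclass == "insertion":
            base = reg.base_at(v.atg_pos)
            return dict(variant_id=v.variant_id, genomic_pos=v.genomic_pos,
                        ref=base, alt=base + v.alt_allele)
        anchor_atg = v.atg_pos - 1 if v.atg_pos != 1 else -1
        base = reg.base_at(anchor_atg)
        return dict(variant_id=v.variant_id,
                    genomic_pos=atg_to_genomic(anchor_atg, self.gene),
                    ref=base + v.ref_allele, alt=base)


# ---------------------------------------------------------------------------
# low-level builder
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_reference(rng: np.random.Generator, plan: PanelPlan
                    ) -> tuple[GeneModel, str, RegionSequence]:
    cds_len = sum(plan.exon_lens)
    n_codons = cds_len // 3
    body_codons = [ _CODONS[i] for i in rng.integers(0, len(_CODONS),
                                                     n_codons - 2) ]
    cds = "ATG" + "".join(body_codons) + "TAA"
    pieces, cpos = [], 0
    exon_coords = []
    cursor = PAD + plan.upstream_len + 1   # genomic coordinate of next base
    for i, elen in enumerate(plan.exon_lens):
        exon_coords.append((cursor, cursor + elen - 1))
        pieces.append(cds[cpos:cpos + elen])
        cpos += elen
        cursor += elen
        if i < len(plan.intron_lens):
            ilen = plan.intron_lens[i]
            intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
            pieces.append(intron)
            cursor += ilen
    body = "".join(pieces)
    upstream = _random_seq(rng, plan.upstream_len)
    downstream = _random_seq(rng, plan.downstream_len)
    chrom = (_random_seq(rng, PAD) + upstream + body + downstream
             + _random_seq(rng, PAD))
    gene = GeneModel(
        gene_id=plan.gene_id, chrom=CHROM_ID, strand="+",
        atg_genomic_pos=PAD + plan.upstream_len + 1,
        stop_end_genomic_pos=PAD + plan.upstream_len + len(body),
        exons=tuple(exon_coords),
        upstream_len=plan.upstream_len, downstream_len=plan.downstream_len)
    ref = extract_gene_region({CHROM_ID: chrom}, gene,
                              accession_id="reference")
    return gene, chrom, ref


def _subregion_offsets(plan: PanelPlan, gene: GeneModel, ref: RegionSequence,
                       region: str, margin: int) -> tuple[int, int]:
    """Inclusive offset interval of a region label, margins applied."""
    up, body = plan.upstream_len, gene.body_len
    if region == "5'UTR":
        lo, hi = 0, up - 1
    elif region == "3'UTR":
        lo, hi = up + body, len(ref.seq) - 1
    elif region.startswith("exon") or region.startswith("intron"):
        want_k = int(region.split()[1]) if " " in region else None
        from .genomic_io import exon_intervals_atg
        ivals = exon_intervals_atg(gene)
        if region.startswith("exon"):
            k = (want_k or 1) - 1
            a, b = ivals[k]
        else:
            k = (want_k or 1) - 1
            a, b = ivals[k][1] + 1, ivals[k + 1][0] - 1
        lo, hi = ref.atg_to_offset(a), ref.atg_to_offset(b)
    else:
        raise ConfigError(f"unknown region label {region!r}")
    return lo + margin, hi - margin


def _region_key(region: str) -> str:
    return region.split()[0] if region.startswith(("exon", "intron")) \
        else region


class _BuildFailure(Exception):
    pass


def _plant_variants(rng: np.random.Generator, plan: PanelPlan,
                    gene: GeneModel, ref: RegionSequence
                    ) -> tuple[RegionSequence, list[VariantRecord]]:
    """Place every planned variant, verifying intent; raises _BuildFailure."""
    region_seq = ref.seq
    used: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        return all(hi + MIN_SPACING < a or b + MIN_SPACING < lo
                   for a, b in used)

    out: list[VariantRecord] = []
    # indels last so left-normalization sees the final local context
    order = sorted(range(len(plan.variants)),
                   key=lambda i: plan.variants[i].kind in
                   ("deletion", "insertion"))
    placed: dict[int, VariantRecord] = {}
    for pi in order:
        vp = plan.variants[pi]
        tmp_ref = RegionSequence("reference", plan.gene_id, region_seq,
                                 ref.upstream_len, ref.downstream_len)
        lo, hi = _subregion_offsets(plan, gene, tmp_ref,
                                    vp.region, vp.margin)
        if lo > hi:
            raise _BuildFailure(f"{vp.vid}: region too small for margin")
        if vp.atg_pos is not None:
            base_off = tmp_ref.atg_to_offset(vp.atg_pos)
            candidates = [base_off + d for step in range(0, 45)
                          for d in ([0] if step == 0 else [step, -step])]
            candidates = [c for c in candidates if lo <= c <= hi]
        else:
            candidates = list(rng.integers(lo, hi + 1, 200))
        success = None
        for off in candidates:
            rec = _try_place(rng, vp, off, region_seq, gene, tmp_ref,
                             free)
            if rec is not None:
                success = rec
                break
        if success is None:
            raise _BuildFailure(f"could not place variant {vp.vid}")
        new_seq, record, span = success
        region_seq = new_seq
        used.append(span)
        placed[pi] = record
    out = [placed[i] for i in range(len(plan.variants))]
    final_ref = RegionSequence("reference", plan.gene_id, region_seq,
                               ref.upstream_len, ref.downstream_len)
    # final verification pass against the fully embedded reference
    for vp, rec in zip(plan.variants, out):
        check = annotate_effect(rec, gene, final_ref)
        if not _effect_matches(vp.kind, check.effect, check.region):
            raise _BuildFailure(
                f"{vp.vid}: effect drifted to {check.effect} after later "
                "embeds")
    cds = cds_sequence(final_ref, gene)
    prot = str(Seq(cds).translate())
    if "*" in prot[:-1] or not prot.endswith("*"):
        raise _BuildFailure("embedding broke the reference ORF")
    return final_ref, out


def _effect_matches(kind: str, effect: str, region: str) -> bool:
    if kind == "missense":
        return effect == "missense"
    if kind == "synonymous":
        return effect == "synonymous"
    if kind == "premature_stop":
        return effect == "premature_stop"
    if kind == "noncoding":
        return effect == "noncoding"
    if kind == "deletion":
        return effect in ("noncoding", "frameshift", "inframe_indel")
    if kind == "insertion":
        return effect in ("noncoding", "frameshift", "inframe_indel")
    raise ConfigError(f"unknown variant kind {kind!r}")


def _try_place(rng, vp: VariantPlan, off: int, region_seq: str,
               gene: GeneModel, tmp_ref: RegionSequence, free
               ) -> tuple[str, VariantRecord, tuple[int, int]] | None:
    """Attempt to place one variant at region offset ``off``."""
    n = len(region_seq)
    if vp.kind in ("deletion", "insertion"):
        size = vp.size
        if vp.kind == "deletion":
            span = (off - 1, off + size)
        else:
            span = (off - 1, off + 2)
        if span[0] < 0 or span[1] >= n or not free(*span):
            return None
        atg = tmp_ref.offset_to_atg(off)
        if vp.kind == "deletion":
            ref_allele = region_seq[off:off + size]
            pos2, ref2, alt2 = _left_normalize(region_seq, off, ref_allele, "")
            if abs(pos2 - off) > 8 or not free(pos2 - 1, pos2 + size):
                return None
            rec = VariantRecord(
                variant_id=vp.vid, atg_pos=tmp_ref.offset_to_atg(pos2),
                genomic_pos=-1, ref_allele=ref2, alt_allele="",
                vclass="deletion")
            span = (pos2 - 1, pos2 + size)
        else:
            ins = _random_seq(rng, size)
            # anchor at off: inserted between off and off+1
            pos2, _, ins2 = _left_normalize(region_seq, off + 1, "", ins)
            anchor = pos2 - 1
            if anchor < 1 or abs(anchor - off) > 8 \
                    or not free(anchor - 1, anchor + 2):
                return None
            rec = VariantRecord(
                variant_id=vp.vid, atg_pos=tmp_ref.offset_to_atg(anchor),
                genomic_pos=-1, ref_allele="", alt_allele=ins2,
                vclass="insertion")
            span = (anchor - 1, anchor + 2)
        check = annotate_effect(rec, gene, tmp_ref)
        if not _effect_matches(vp.kind, check.effect, check.region):
            return None
        rec = VariantRecord(**{**rec.__dict__, "region": check.region,
                               "effect": check.effect,
                               "genomic_pos": atg_to_genomic(rec.atg_pos,
                                                             gene)})
        return region_seq, rec, span

    # SNP (possibly with an embedded context)
    nb, na = len(vp.embed_before), len(vp.embed_after)
    span = (off - nb, off + na)
    if span[0] < 0 or span[1] >= n or not free(*span):
        return None
    if vp.frame_mod is not None:
        from .gene_region_effects import _cds_index
        atg = tmp_ref.offset_to_atg(off)
        idx = _cds_index(atg, gene)
        if idx is None or idx % 3 != vp.frame_mod:
            return None
    ref_base = vp.ref_base or region_seq[off]
    alt_opts = ([vp.alt_base] if vp.alt_base
                else [b for b in "ACGT" if b != ref_base])
    new_seq = (region_seq[:off - nb] + vp.embed_before + ref_base
               + vp.embed_after + region_seq[off + na + 1:])
    assert len(new_seq) == n
    tmp2 = RegionSequence("reference", tmp_ref.gene_id, new_seq,
                          tmp_ref.upstream_len, tmp_ref.downstream_len)
    # embedding must not break the reference ORF
    if nb or na or vp.ref_base:
        cds = cds_sequence(tmp2, gene)
        prot = str(Seq(cds).translate())
        if "*" in prot[:-1] or not prot.endswith("*") \
                or not cds.startswith("ATG"):
            return None
    atg = tmp2.offset_to_atg(off)
    for alt in alt_opts:
        if alt == ref_base:
            continue
        rec = VariantRecord(variant_id=vp.vid, atg_pos=atg, genomic_pos=-1,
                            ref_allele=ref_base, alt_allele=alt,
                            vclass="SNP")
        check = annotate_effect(rec, gene, tmp2)
        if _effect_matches(vp.kind, check.effect, check.region):
            rec = VariantRecord(**{**rec.__dict__, "region": check.region,
                                   "effect": check.effect,
                                   "genomic_pos": atg_to_genomic(atg, gene)})
            return new_seq, rec, span
    return None


def _expected_unique(plan: PanelPlan, query: QueryPlan) -> set[tuple[str, int]]:
    """Brute-force unique (vid, allele) pairs from the plan itself."""
    kept = [h for h in plan.haps
            if not (h.novel and h.size < plan.min_novel_size)]
    target_ids = set(query.targets)
    excl_ids = set(query.exclude)

    def in_set(h: HapPlan, ids: set[str]) -> bool:
        return h.hap_id in ids or h.group_id in ids

    targets = [h.hap_id for h in kept if in_set(h, target_ids)]
    others = [h.hap_id for h in kept
              if not in_set(h, target_ids) and not in_set(h, excl_ids)]
    out = set()
    for vp in plan.variants:
        carriers = vp.carriers
        t_all_alt = all(h in carriers for h in targets)
        o_any_alt = any(h in carriers for h in others)
        t_all_ref = all(h not in carriers for h in targets)
        o_any_ref = any(h not in carriers for h in others)
        if targets and t_all_alt and not o_any_alt:
            out.add((vp.vid, 1))
        elif targets and t_all_ref and not o_any_ref:
            out.add((vp.vid, 0))
    return out


def build_panel(plan: PanelPlan, max_attempts: int = 25) -> SimulatedPanel:
    """Materialize a plan; resamples on confounded random draws."""
    if not plan.haps:
        raise ConfigError("a panel needs at least one haplotype")
    if len({h.hap_id for h in plan.haps}) != len(plan.haps):
        raise ConfigError("duplicate haplotype ids in the plan")
    n_total = sum(h.size for h in plan.haps)
    if any(h.size < 1 for h in plan.haps):
        raise ConfigError("every planned haplotype needs at least one member")
    hap_ids = {h.hap_id for h in plan.haps}
    for vp in plan.variants:
        unknown = vp.carriers - hap_ids
        if unknown:
            raise ConfigError(f"{vp.vid}: unknown carrier haplotypes "
                              f"{sorted(unknown)}")
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([plan.seed & 0x7FFFFFFF, attempt])
        try:
            return _build_once(rng, plan)
        except _BuildFailure as exc:
            last_err = exc
    raise ConfigError(f"panel generation failed after {max_attempts} "
                      f"attempts: {last_err}")


def _build_once(rng: np.random.Generator, plan: PanelPlan) -> SimulatedPanel:
    gene, chrom, ref0 = _make_reference(rng, plan)
    ref, variants = _plant_variants(rng, plan, gene, ref0)
    # splice the embedded region back into the chromosome (plus strand)
    chrom = chrom[:PAD] + ref.seq + chrom[PAD + len(ref.seq):]

    # accessions
    counter = itertools.count(1)
    hap_members: dict[str, tuple[str, ...]] = {}
    reference_accession = None
    for h in plan.haps:
        members = []
        for _ in range(h.size):
            i = next(counter)
            members.append(f"ACC{i:04d}")
        hap_members[h.hap_id] = tuple(members)
    ref_hap = plan.haps[0]
    reference_accession = hap_members[ref_hap.hap_id][0]

    # genotype matrix
    accs = [a for h in plan.haps for a in hap_members[h.hap_id]]
    data = {}
    hap_of = {a: h.hap_id for h in plan.haps for a in hap_members[h.hap_id]}
    carrier_map = {vp.vid: vp.carriers for vp in plan.variants}
    for acc in accs:
        data[acc] = [1 if hap_of[acc] in carrier_map[v.variant_id] else 0
                     for v in variants]
    geno = pd.DataFrame(data, index=[v.variant_id for v in variants],
                        dtype="Int64")

    # metadata: each haplotype gets a "home" subpopulation bias
    labels = list(plan.subpop_weights)
    base_w = np.array([plan.subpop_weights[s] for s in labels], dtype=float)
    panel = []
    for h in plan.haps:
        w = base_w.copy()
        home = rng.integers(0, len(labels))
        w[home] *= 4.0
        w /= w.sum()
        for acc in hap_members[h.hap_id]:
            panel.append(AccessionMeta(acc, labels[rng.choice(
                len(labels), p=w)]))

    sequenced = [hap_members[h.hap_id][0] for h in plan.haps if not h.novel]

    group_members: dict[str, tuple[str, ...]] = {}
    for h in plan.haps:
        group_members.setdefault(h.group_id, ())
        group_members[h.group_id] += hap_members[h.hap_id]
    novel = {h.hap_id for h in plan.haps if h.novel}
    dropped = {a for h in plan.haps
               if h.novel and h.size < plan.min_novel_size
               for a in hap_members[h.hap_id]}

    vpos = {v.variant_id: v.atg_pos for v in variants}
    valt = {v.variant_id: (v.alt_allele if v.vclass == "SNP" else "ALT")
            for v in variants}
    vref = {v.variant_id: (v.ref_allele if v.vclass == "SNP" else "REF")
            for v in variants}
    elite_defs = {}
    for ed in plan.elite_defs:
        alleles = {}
        for vid, side in ed.alleles.items():
            base = valt[vid] if side == "ALT" else vref[vid]
            alleles[vpos[vid]] = base
        elite_defs[ed.name] = EliteDefinition(
            gene_id=plan.gene_id, alleles=alleles, source_note=ed.name)

    queries = [dict(name=q.name, targets=q.targets, exclude=q.exclude,
                    expected_unique=_expected_unique(plan, q))
               for q in plan.queries]

    truth = PanelTruth(hap_members=hap_members, group_members=group_members,
                       novel_haps=novel, dropped_accessions=dropped,
                       elite_defs=elite_defs, queries=queries,
                       hap_group={h.hap_id: h.group_id for h in plan.haps})
    return SimulatedPanel(
        plan=plan, gene=gene, chrom_seq=chrom, ref_region=ref,
        variants=variants, genotypes=geno, panel=panel,
        sequenced=sequenced, reference_accession=reference_accession,
        truth=truth)


# ---------------------------------------------------------------------------
# randomized generator
# ---------------------------------------------------------------------------

def _plan_from_config(cfg: PanelConfig) -> PanelPlan:
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 991])
    haps: list[HapPlan] = []
    variants: list[VariantPlan] = []

    groups = ["A", "E"] + [f"G{i}" for i in range(1, cfg.n_functional_variants + 1)]
    if not cfg.elite_spec:
        groups.remove("E")
    base_haps = {g: f"{g}-1" for g in groups}

    # silent variants each add one haplotype to a round-robin group
    extra_haps: list[tuple[str, str]] = []
    for i in range(cfg.n_silent_variants):
        g = groups[i % len(groups)]
        extra_haps.append((g, f"{g}-{sum(1 for gg, _ in extra_haps if gg == g) + 2}"))

    rare_haps = []
    for i, size in enumerate(cfg.rare_haplotype_sizes):
        g = groups[int(rng.integers(0, len(groups)))]
        rare_haps.append((g, f"{g}-rare{i + 1}", size))

    n_named = len(groups) + len(extra_haps)
    n_rare = sum(cfg.rare_haplotype_sizes)
    n_free = cfg.n_accessions - n_rare
    if n_free < n_named:
        raise ConfigError(
            f"{cfg.n_accessions} accessions cannot cover {n_named} "
            f"haplotypes plus {n_rare} rare members")
    # sizes: one guaranteed member each, remainder multinomial
    probs = rng.dirichlet(np.full(n_named, 1.5))
    extra = rng.multinomial(n_free - n_named, probs)
    sizes = 1 + extra

    named = [(g, base_haps[g]) for g in groups] + extra_haps
    for (g, hid), s in zip(named, sizes):
        haps.append(HapPlan(hap_id=hid, group_id=g, size=int(s)))
    for g, hid, s in rare_haps:
        haps.append(HapPlan(hap_id=hid, group_id=g, size=s, novel=True))
    # the reference haplotype must be first
    haps.sort(key=lambda h: h.hap_id != "A-1")

    hap_ids_of = lambda g: frozenset(h.hap_id for h in haps
                                     if h.group_id == g)

    n_ex, n_in = len(cfg.exon_lens), len(cfg.intron_lens)

    def rand_exon() -> str:
        return f"exon {int(rng.integers(1, n_ex + 1))}"

    def rand_intron() -> str:
        return f"intron {int(rng.integers(1, n_in + 1))}" if n_in \
            else "3'UTR"

    vn = itertools.count(1)
    if cfg.elite_spec:
        for region in cfg.elite_spec:
            kind = "missense" if region == "exon" else "noncoding"
            reg = rand_exon() if region == "exon" else (
                rand_intron() if region == "intron" else region)
            variants.append(VariantPlan(
                vid=f"v{next(vn):03d}", region=reg, kind=kind,
                carriers=hap_ids_of("E")))
        for size in cfg.indel_sizes:
            variants.append(VariantPlan(
                vid=f"v{next(vn):03d}", region="5'UTR",
                kind="deletion", size=size, carriers=hap_ids_of("E"),
                margin=40 + size))
    for i in range(1, cfg.n_functional_variants + 1):
        variants.append(VariantPlan(
            vid=f"v{next(vn):03d}", region=rand_exon(), kind="missense",
            carriers=hap_ids_of(f"G{i}")))
    for i, (g, hid) in enumerate(extra_haps):
        choice = i % 4
        if choice == 3:
            region, kind = rand_exon(), "synonymous"
        else:
            region = ["3'UTR", "5'UTR", None][choice] or rand_intron()
            kind = "noncoding"
        variants.append(VariantPlan(
            vid=f"v{next(vn):03d}", region=region, kind=kind,
            carriers=frozenset({hid})))
    for i, (g, hid, s) in enumerate(rare_haps):
        variants.append(VariantPlan(
            vid=f"v{next(vn):03d}", region="3'UTR", kind="noncoding",
            carriers=frozenset({hid})))

    elite_defs, queries = [], []
    if cfg.elite_spec:
        def_vids = [v.vid for v in variants[:len(cfg.elite_spec)]]
        elite_defs.append(EliteDefPlan(
            name="elite", alleles={vid: "ALT" for vid in def_vids}))
        queries.append(QueryPlan(name="elite", targets=("E",)))

    return PanelPlan(
        gene_id=f"SYN{cfg.seed % 100000:05d}", seed=cfg.seed, haps=haps,
        variants=variants, elite_defs=elite_defs, queries=queries,
        upstream_len=cfg.upstream_len, downstream_len=cfg.downstream_len,
        exon_lens=cfg.exon_lens, intron_lens=cfg.intron_lens,
        subpop_weights=cfg.subpop_weights,
        min_novel_size=cfg.min_novel_size)


def simulate_panel(cfg: PanelConfig) -> SimulatedPanel:
    """Generate a randomized panel; identical config+seed gives identical
    output."""
    plan = _plan_from_config(cfg)
    return build_panel(plan)


# ---------------------------------------------------------------------------
# the five fixed study-mimicking panels
# ---------------------------------------------------------------------------

def _mk(vid, region, kind, carriers, **kw):
    return VariantPlan(vid=vid, region=region, kind=kind,
                       carriers=frozenset(carriers), **kw)


def _mimic_skc1(seed: int) -> PanelPlan:
    """Elite group with four private missense variants; one natural CAPS
    (non-elite allele keeps the site) and two dCAPS-only private variants."""
    K = {"K-1", "K-2"}
    haps = [
        HapPlan("A-1", "A", 8), HapPlan("A-2", "A", 6),
        HapPlan("K-1", "K", 7), HapPlan("K-2", "K", 5),
        HapPlan("H-1", "H", 10), HapPlan("D-1", "D", 8),
        HapPlan("H-r1", "H", 3, novel=True),
    ]
    variants = [
        _mk("m1", "exon 1", "missense", K, atg_pos=60),
        # the CAPS target: the non-elite (reference) allele carries GCGC
        _mk("m2", "exon 1", "missense", K, atg_pos=150,
            embed_before="GC", embed_after="C", ref_base="G", margin=60),
        _mk("m3", "exon 2", "missense", K, atg_pos=650),
        _mk("m4", "exon 2", "missense", K, atg_pos=720),
        # dCAPS targets: one mismatch turns GACTT+allele into an EcoR I site
        _mk("u1", "5'UTR", "noncoding", K, atg_pos=-1250,
            embed_before="GACTT", ref_base="C", alt_base="T", margin=220),
        _mk("i1", "intron 2", "noncoding", K, atg_pos=1050,
            embed_before="GACTT", ref_base="T", alt_base="C", margin=60),
        _mk("h1", "exon 3", "missense", {"H-1", "H-r1"}, atg_pos=1260),
        _mk("d1", "exon 3", "missense", {"D-1"}, atg_pos=1320),
        _mk("s1", "3'UTR", "noncoding", {"A-2"}, atg_pos=1700),
        _mk("s2", "3'UTR", "noncoding", {"K-2"}, atg_pos=1760),
        _mk("s3", "3'UTR", "noncoding", {"H-r1"}, atg_pos=1820),
    ]
    return PanelPlan(
        gene_id="SKC1like", seed=seed, haps=haps, variants=variants,
        elite_defs=[EliteDefPlan("elite", {v: "ALT"
                                           for v in ("m1", "m2", "m3", "m4")})],
        queries=[QueryPlan("elite", targets=("K",))],
        marker_plans=[
            MarkerPlan("SKC1like_E1C", "CAPS", "m2", "alt", "elite",
                       enzymes=("Hha I",)),
            MarkerPlan("SKC1like_5Ud", "dCAPS", "u1", "alt", "elite",
                       enzymes=("EcoR I",)),
            MarkerPlan("SKC1like_I1d", "dCAPS", "i1", "alt", "elite",
                       enzymes=("EcoR I",)),
        ])


def _mimic_gs3(seed: int) -> PanelPlan:
    """Elite group defined by a premature stop that is also the only
    elite-private variant; the reference allele carries a Pst I site that
    the stop-creating allele destroys."""
    haps = [
        HapPlan("A-1", "A", 8), HapPlan("A-2", "A", 6),
        HapPlan("G-1", "G", 10), HapPlan("D-1", "D", 9),
        HapPlan("E-1", "E", 8), HapPlan("D-r1", "D", 3, novel=True),
    ]
    variants = [
        # CTG C AG -> CTG A AG: codon TGA (stop) in the elite allele while
        # the reference allele reads ...CTGCAG... (a Pst I site)
        _mk("stp", "exon 2", "premature_stop", {"G-1"}, atg_pos=700,
            embed_before="CTG", embed_after="AG", ref_base="C", alt_base="A",
            frame_mod=2, margin=60),
        _mk("d1", "exon 3", "missense", {"D-1", "D-r1"}, atg_pos=1260),
        _mk("e1", "exon 3", "missense", {"E-1"}, atg_pos=1320),
        _mk("s1", "3'UTR", "noncoding", {"A-2"}, atg_pos=1700),
        _mk("s2", "3'UTR", "noncoding", {"D-r1"}, atg_pos=1760),
    ]
    return PanelPlan(
        gene_id="GS3like", seed=seed, haps=haps, variants=variants,
        elite_defs=[EliteDefPlan("elite", {"stp": "ALT"})],
        queries=[QueryPlan("elite", targets=("G",))],
        marker_plans=[
            MarkerPlan("GS3like_E2C", "CAPS", "stp", "alt", "elite",
                       enzymes=("Pst I",)),
        ])


def _mimic_hak21(seed: int) -> PanelPlan:
    """Two elite groups (the reference group among them) defined by six
    reference-allele positions, plus a second elite pair -- a haplotype and
    a group -- detected by two promoter indels."""
    nonelite = {"E-1", "H-1", "F-1", "F-2", "J-1", "E-r1"}
    FJ = {"F-2", "J-1"}
    haps = [
        HapPlan("A-1", "A", 8), HapPlan("A-2", "A", 6),
        HapPlan("B-1", "B", 8),
        HapPlan("E-1", "E", 7), HapPlan("H-1", "H", 6),
        HapPlan("F-1", "F", 5), HapPlan("F-2", "F", 5),
        HapPlan("J-1", "J", 5),
        HapPlan("E-r1", "E", 4, novel=True),
    ]
    variants = [
        _mk("e1", "exon 1", "missense", nonelite, atg_pos=40),
        _mk("e2", "exon 1", "missense", nonelite, atg_pos=100),
        _mk("e3", "exon 1", "missense", nonelite, atg_pos=160),
        _mk("e4", "exon 1", "missense", nonelite, atg_pos=220),
        _mk("e5", "exon 2", "missense", nonelite, atg_pos=640),
        _mk("e6", "exon 2", "missense", nonelite, atg_pos=700),
        # CAPS target: reference allele carries a Dra I site (elite cut)
        _mk("c1", "intron 2", "noncoding", nonelite, atg_pos=1040,
            embed_before="TTT", embed_after="AA", ref_base="A", alt_base="G",
            margin=60),
        _mk("b1", "exon 3", "missense", {"B-1"}, atg_pos=1380),
        _mk("f1", "exon 3", "missense", {"F-1", "F-2"}, atg_pos=1410),
        _mk("j1", "exon 3", "missense", {"J-1"}, atg_pos=1440),
        _mk("h1", "exon 3", "missense", {"H-1"}, atg_pos=1470),
        _mk("p1", "5'UTR", "noncoding", FJ, atg_pos=-1900),
        _mk("ins391", "5'UTR", "insertion", FJ, size=391, atg_pos=-1100,
            margin=320),
        _mk("del17", "5'UTR", "deletion", FJ, size=17, atg_pos=-600,
            margin=160),
        _mk("s1", "3'UTR", "noncoding", {"A-2"}, atg_pos=1700),
        _mk("s2", "3'UTR", "noncoding", {"E-r1"}, atg_pos=1760),
    ]
    return PanelPlan(
        gene_id="HAK21like", seed=seed, haps=haps, variants=variants,
        elite_defs=[
            EliteDefPlan("elite_AB", {v: "REF" for v in
                                      ("e1", "e2", "e3", "e4", "e5", "e6")}),
            EliteDefPlan("elite_FJ", {"p1": "ALT"}),
        ],
        queries=[QueryPlan("elite_AB", targets=("A", "B")),
                 QueryPlan("elite_FJ", targets=("J", "F-2"))],
        marker_plans=[
            MarkerPlan("HAK21like_5U2", "Indel", "ins391", "alt", "elite_FJ"),
            MarkerPlan("HAK21like_5U1", "Indel", "del17", "alt", "elite_FJ"),
            MarkerPlan("HAK21like_I2C", "CAPS", "c1", "ref", "elite_AB",
                       enzymes=("Dra I",)),
        ])


def _mimic_pao3(seed: int) -> PanelPlan:
    """Elite group defined by three missense variants of which two are
    shared with another group, leaving exactly two elite-private variants;
    the exonic one supports only a dCAPS assay."""
    B = {"B-1", "B-2"}
    haps = [
        HapPlan("A-1", "A", 7), HapPlan("A-2", "A", 5),
        HapPlan("B-1", "B", 6), HapPlan("B-2", "B", 4),
        HapPlan("C-1", "C", 8), HapPlan("D-1", "D", 6),
        HapPlan("A-r1", "A", 4, novel=True),
    ]
    BC = B | {"C-1"}
    variants = [
        _mk("m1", "exon 1", "missense", BC, atg_pos=60),
        # dCAPS target: non-elite allele is cut after a one-base mismatch
        _mk("m2", "exon 2", "missense", B, atg_pos=650,
            embed_before="GACTT", ref_base="C", margin=60),
        _mk("m3", "exon 3", "missense", BC, atg_pos=1260),
        _mk("u1", "5'UTR", "noncoding", B, atg_pos=-1141),
        _mk("d1", "exon 3", "missense", {"D-1"}, atg_pos=1320),
        _mk("s1", "3'UTR", "noncoding", {"A-2"}, atg_pos=1700),
        _mk("s2", "3'UTR", "noncoding", {"B-2"}, atg_pos=1760),
        _mk("s3", "3'UTR", "noncoding", {"A-r1"}, atg_pos=1820),
    ]
    return PanelPlan(
        gene_id="PAO3like", seed=seed, haps=haps, variants=variants,
        elite_defs=[EliteDefPlan("elite", {v: "ALT"
                                           for v in ("m1", "m2", "m3")})],
        queries=[QueryPlan("elite", targets=("B",))],
        marker_plans=[
            MarkerPlan("PAO3like_E9d", "dCAPS", "m2", "alt", "elite",
                       enzymes=("EcoR I",)),
        ])


def _mimic_rst1(seed: int) -> PanelPlan:
    """Two elite groups (the reference group among them) defined by four
    reference-allele positions; a large promoter deletion and two CAPS
    sites separate elite from non-elite."""
    nonelite = {"G-1", "H-1", "G-r1"}
    haps = [
        HapPlan("A-1", "A", 7), HapPlan("A-2", "A", 5),
        HapPlan("B-1", "B", 10),
        HapPlan("G-1", "G", 9), HapPlan("H-1", "H", 8),
        HapPlan("G-r1", "G", 4, novel=True),
    ]
    variants = [
        _mk("r1", "exon 1", "missense", nonelite, atg_pos=60),
        _mk("r2", "exon 1", "missense", nonelite, atg_pos=150),
        _mk("r3", "exon 1", "missense", nonelite, atg_pos=240),
        # CAPS target: reference (elite) allele carries a Hae III site
        _mk("r4", "exon 2", "missense", nonelite, atg_pos=850,
            embed_before="GG", embed_after="C", ref_base="C", margin=60),
        # CAPS target: the non-elite allele creates a Hinf I site; placed
        # well upstream of the 514-bp deletion so both classes amplify
        _mk("v5U", "5'UTR", "noncoding", nonelite, atg_pos=-2100,
            embed_before="GAA", embed_after="C", ref_base="G", alt_base="T",
            margin=250),
        _mk("del514", "5'UTR", "deletion", nonelite, size=514,
            atg_pos=-1300, margin=330),
        _mk("b1", "exon 3", "missense", {"B-1"}, atg_pos=1400),
        _mk("g1", "exon 3", "missense", {"G-1", "G-r1"}, atg_pos=1430),
        _mk("h1", "exon 3", "missense", {"H-1"}, atg_pos=1460),
        _mk("s1", "3'UTR", "noncoding", {"A-2"}, atg_pos=1700),
        _mk("s2", "3'UTR", "noncoding", {"G-r1"}, atg_pos=1760),
    ]
    return PanelPlan(
        gene_id="RST1like", seed=seed, haps=haps, variants=variants,
        upstream_len=2600,
        elite_defs=[EliteDefPlan("elite", {v: "REF"
                                           for v in ("r1", "r2", "r3", "r4")})],
        queries=[QueryPlan("elite", targets=("A", "B"))],
        marker_plans=[
            MarkerPlan("RST1like_5U", "Indel", "del514", "ref", "elite"),
            MarkerPlan("RST1like_5UC", "CAPS", "v5U", "ref", "elite",
                       enzymes=("Hinf I",)),
            MarkerPlan("RST1like_E2C", "CAPS", "r4", "ref", "elite",
                       enzymes=("Hae III",)),
        ])


MIMIC_BUILDERS = {
    "SKC1-like": _mimic_skc1,
    "GS3-like": _mimic_gs3,
    "OsHAK21-like": _mimic_hak21,
    "OsPAO3-like": _mimic_pao3,
    "RST1-like": _mimic_rst1,
}


def paper_mimic_suite(seed: int = 20230830) -> dict[str, SimulatedPanel]:
    """Build the five study-mimicking panels (deterministic per seed)."""
    return {name: build_panel(builder(seed + i))
            for i, (name, builder) in enumerate(MIMIC_BUILDERS.items())}
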