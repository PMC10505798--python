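"""Two-tier haplotype classification of a germplasm panel.

Tier 1 (*haplotype groups*) partitions accessions by their genotype at the
protein-altering ("functional") variants of a gene: missense, in-frame
indel, frameshift, premature stop, start loss, stop loss.  Tier 2
(*haplotypes*) refines each group by the remaining variants (synonymous
exonic SNPs and everything in the upstream window, introns and downstream
window).

Naming follows the field convention: the reference accession's group is
HapA and its haplotype HapA-1; other groups are lettered by descending
member count, haplotypes within a group numbered by descending count.
Novel haplotypes (no member in the designated sequenced subset) smaller
than a minimum size are dropped and their accessions reported as
unassigned.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ClassificationError
from .gene_region_effects import FUNCTIONAL_EFFECTS
from .genomic_io import AccessionMeta, VariantRecord


@dataclass
class Haplotype:
    name: str
    parent_group: str
    genotype: tuple[int, ...]          # alleles over ALL classifying variants
    members: list[str]
    novel: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeGroup:
    name: str
    defining_genotype: tuple[int, ...]  # alleles over functional variants
    haplotypes: list[Haplotype] = field(default_factory=list)
    elite: bool = False

    @property
    def members(self) -> list[str]:
        return [a for h in self.haplotypes for a in h.members]

    @property
    def size(self) -> int:
        return sum(h.size for h in self.haplotypes)


@dataclass
class HaplotypeAssignment:
    """Result of classification for one gene."""

    gene_id: str
    groups: list[HaplotypeGroup]
    unassigned: list[str]
    variants: list[VariantRecord]
    functional_ids: list[str]
    silent_ids: list[str]
    genotypes: pd.DataFrame            # variant x accession, 0/1/NA
    elite_haplotypes: list[str] = field(default_factory=list)

    def group_of(self, accession: str) -> str | None:
        for g in self.groups:
            if accession in g.members:
                return g.name
        return None

    def haplotype_of(self, accession: str) -> str | None:
        for g in self.groups:
            for h in g.haplotypes:
                if accession in h.members:
                    return h.name
        return None

    def find(self, name: str) -> HaplotypeGroup | Haplotype:
        for g in self.groups:
            if g.name == name:
                return g
            for h in g.haplotypes:
                if h.name == name:
                    return h
        raise KeyError(name)

    def members_of(self, names: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for n in names:
            node = self.find(n)
            out.update(node.members)
        return out

    @property
    def assigned(self) -> list[str]:
        return [a for g in self.groups for a in g.members]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for h in g.haplotypes:
                for a in h.members:
                    rows.append((a, self.gene_id, g.name, h.name,
                                 g.elite, h.name in self.elite_haplotypes))
        for a in self.unassigned:
            rows.append((a, self.gene_id, None, None, False, False))
        return pd.DataFrame(rows, columns=[
            "accession_id", "gene", "group", "haplotype",
            "group_elite", "haplotype_elite"])


@dataclass(frozen=True)
class EliteDefinition:
    """Published defining alleles of an elite haplotype, ATG-relative.

    ``alleles`` maps ATG position -> required base(s); the wildcard ``ALT``
    means "the non-reference allele at that site" (used when a source gives
    positions but not nucleotides), ``REF`` the reference allele.
    """

    gene_id: str
    alleles: Mapping[int, str]
    source_note: str = ""

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.alleles))


_LETTERS = list(string.ascii_uppercase) + [
    a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]


def _letter(i: int) -> str:
    return _LETTERS[i]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_haplotypes(variants: Sequence[VariantRecord],
                        genotypes: pd.DataFrame,
                        panel: Sequence[AccessionMeta],
                        reference_accession: str,
                        sequenced_accessions: Iterable[str] | None = None,
                        min_novel_size: int = 5,
                        gene_id: str | None = None) -> HaplotypeAssignment:
    """Partition a panel into haplotype groups and haplotypes.

    ``genotypes`` is a variant-by-accession table of 0 (reference allele),
    1 (alternate) or NA (missing / heterozygous); accessions with any NA at
    a classifying variant are excluded and reported as unassigned.

    ``sequenced_accessions`` designates the subset anchored by full-length
    sequencing: haplotypes containing none of them are *novel* and are
    dropped when smaller than ``min_novel_size``.  ``None`` disables the
    novel-haplotype filter.
    """
    if gene_id is None:
        gene_id = variants[0].variant_id.rsplit("_", 1)[0] if variants else "gene"
    panel_ids = [a.accession_id for a in panel]
    accs = [a for a in panel_ids if a in genotypes.columns]
    missing_meta = [c for c in genotypes.columns if c not in panel_ids]
    if missing_meta:
        warnings.warn(f"{len(missing_meta)} genotyped accession(s) missing "
                      "from the metadata panel: "
                      + ", ".join(missing_meta[:5]))
        accs += missing_meta
    if reference_accession not in accs:
        raise ClassificationError(
            f"reference accession {reference_accession!r} not genotyped")

    vindex = [v.variant_id for v in variants]
    for v in variants:
        if v.effect is None:
            raise ClassificationError(
                f"variant {v.variant_id} has no effect annotation")
    functional = [v.variant_id for v in variants
                  if v.effect in FUNCTIONAL_EFFECTS]
    silent = [v.variant_id for v in variants
              if v.effect not in FUNCTIONAL_EFFECTS]
    geno = genotypes.reindex(vindex)

    ref_col = geno[reference_accession]
    if ref_col.isna().any():
        bad = ref_col.index[ref_col.isna()][0]
        raise ClassificationError(
            f"reference accession {reference_accession!r} has a missing "
            f"call at classifying variant {bad}")

    assigned: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {}
    unassigned: list[str] = []
    func_geno = geno.loc[functional] if functional else geno.iloc[0:0]
    for acc in accs:
        col = geno[acc]
        if col.isna().any():
            unassigned.append(acc)
            continue
        fkey = tuple(int(x) for x in (func_geno[acc] if functional else ()))
        full = tuple(int(x) for x in col)
        assigned[acc] = (fkey, full)

    # tier 1: group by functional genotype, tier 2: by full genotype
    groups_raw: dict[tuple, dict[tuple, list[str]]] = {}
    for acc, (fkey, full) in assigned.items():
        groups_raw.setdefault(fkey, {}).setdefault(full, []).append(acc)

    sequenced = set(sequenced_accessions) if sequenced_accessions is not None \
        else None

    # novel-haplotype filter (applies before naming, sizes matter post-drop)
    if sequenced is not None:
        for fkey in list(groups_raw):
            haps = groups_raw[fkey]
            for full in list(haps):
                members = haps[full]
                if not (set(members) & sequenced) \
                        and len(members) < min_novel_size:
                    unassigned.extend(members)
                    del haps[full]
            if not haps:
                del groups_raw[fkey]

    ref_fkey, ref_full = assigned[reference_accession]
    if ref_fkey not in groups_raw:   # pragma: no cover - ref never filtered
        raise ClassificationError("reference haplotype was filtered out")

    def group_sort_key(fkey: tuple) -> tuple:
        members = [a for m in groups_raw[fkey].values() for a in m]
        return (-len(members), min(members))

    order = sorted(groups_raw, key=group_sort_key)
    order.remove(ref_fkey)
    order.insert(0, ref_fkey)

    groups: list[HaplotypeGroup] = []
    for gi, fkey in enumerate(order):
        gname = f"Hap{_letter(gi)}"
        haps_raw = groups_raw[fkey]
        hap_order = sorted(haps_raw,
                           key=lambda f: (-len(haps_raw[f]),
                                          min(haps_raw[f])))
        if fkey == ref_fkey:
            hap_order.remove(ref_full)
            hap_order.insert(0, ref_full)
        haplotypes = []
        for hi, full in enumerate(hap_order, start=1):
            members = sorted(haps_raw[full])
            novel = sequenced is not None and not (set(members) & sequenced)
            haplotypes.append(Haplotype(
                name=f"{gname}-{hi}", parent_group=gname,
                genotype=full, members=members, novel=novel))
        groups.append(HaplotypeGroup(name=gname, defining_genotype=fkey,
                                     haplotypes=haplotypes))
    return HaplotypeAssignment(
        gene_id=gene_id, groups=groups, unassigned=sorted(unassigned),
        variants=list(variants), functional_ids=functional,
        silent_ids=silent, genotypes=geno)


# ---------------------------------------------------------------------------
# elite flagging
# ---------------------------------------------------------------------------

def _allele_at(assignment: HaplotypeAssignment, genotype: tuple[int, ...],
               atg_pos: int) -> tuple[int, str, str]:
    """(allele index, ref base, alt base) of a haplotype at an ATG position."""
    for i, v in enumerate(assignment.variants):
        if v.atg_pos == atg_pos:
            return genotype[i], v.ref_allele, v.alt_allele
    raise ClassificationError(
        f"elite-defining position {atg_pos:+d} absent from the variant table")


def _carries(assignment: HaplotypeAssignment, genotype: tuple[int, ...],
             definition: EliteDefinition) -> bool:
    for pos, required in definition.alleles.items():
        allele, ref, alt = _allele_at(assignment, genotype, pos)
        carried = alt if allele == 1 else ref
        if required == "ALT":
            if allele != 1:
                return False
        elif required == "REF":
            if allele != 0:
                return False
        elif carried != required:
            return False
    return True


def mark_elite(assignment: HaplotypeAssignment,
               definitions: Sequence[EliteDefinition]) -> HaplotypeAssignment:
    """Flag groups/haplotypes carrying all defining alleles of a definition.

    A haplotype is elite when its full genotype carries every defining
    allele of at least one definition; a group is elite when all of its
    haplotypes are.  Zero, one or several groups may end up flagged.
    """
    # validate positions first so absent ones error out up front
    known = {v.atg_pos for v in assignment.variants}
    for d in definitions:
        absent = [p for p in d.positions if p not in known]
        if absent:
            raise ClassificationError(
                f"{d.gene_id}: elite-defining position(s) absent from the "
                "variant table: "
                + ", ".join(f"{p:+d}" for p in absent))
    elite_haps: list[str] = []
    for g in assignment.groups:
        flags = []
        for h in g.haplotypes:
            hit = any(_carries(assignment, h.genotype, d)
                      for d in definitions)
            flags.append(hit)
            if hit:
                elite_haps.append(h.name)
        g.elite = bool(flags) and all(flags)
    assignment.elite_haplotypes = elite_haps
    if not elite_haps:
        warnings.warn("no haplotype carries all elite-defining alleles")
    return assignment


# ---------------------------------------------------------------------------
# unique variants
# ---------------------------------------------------------------------------

def find_unique_variants(assignment: HaplotypeAssignment,
                         targets: Iterable[str],
                         exclude: Iterable[str] = (),
                         ) -> list[tuple[VariantRecord, int]]:
    """Variants whose allele is carried by exactly the target members.

    Returns ``(variant, allele)`` pairs where ``allele`` (0 = reference,
    1 = alternate) is carried by every member of every target
    group/haplotype and by no assigned accession outside
    ``targets ∪ exclude``.  ``exclude`` waives rare types the caller wants
    ignored.  Accessions with a missing call at a variant are not counted
    as carriers or non-carriers for that variant.
    """
    targets = list(targets)
    exclude = list(exclude)
    if not targets:
        raise ClassificationError("empty target set")
    overlap = set(targets) & set(exclude)
    if overlap:
        raise ClassificationError(
            f"targets and exclude overlap: {sorted(overlap)}")
    tmembers = assignment.members_of(targets)
    waived = assignment.members_of(exclude) | set(assignment.unassigned)
    others = [a for a in assignment.genotypes.columns
              if a not in tmembers and a not in waived]
    out: list[tuple[VariantRecord, int]] = []
    geno = assignment.genotypes
    for v in assignment.variants:
        row = geno.loc[v.variant_id]
        for allele in (1, 0):
            in_t = row[list(tmembers)].dropna()
            in_o = row[others].dropna()
            if len(in_t) and (in_t == allele).all() \
                    and not (in_o == allele).any():
                out.append((v, allele))
                break
    return out


# ---------------------------------------------------------------------------
# subpopulation tallies
# ---------------------------------------------------------------------------

def subpop_distribution(assignment: HaplotypeAssignment,
                        panel: Sequence[AccessionMeta],
                        level: str = "haplotype") -> pd.DataFrame:
    """Contingency table of haplotype (or group) x subpopulation counts."""
    sub = {a.accession_id: a.subpopulation for a in panel}
    rows = []
    for g in assignment.groups:
        for h in g.haplotypes:
            for acc in h.members:
                name = h.name if level == "haplotype" else g.name
                rows.append((name, sub.get(acc, "other")))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["haplotype", "subpopulation"])
    return pd.crosstab(df["haplotype"], df["subpopulation"])


def group_summary(assignment: HaplotypeAssignment) -> pd.DataFrame:
    rows = []
    for g in assignment.groups:
        rows.append((g.name, g.size, len(g.haplotypes), g.elite,
                     ";".join(str(x) for x in g.defining_genotype)))
    return pd.DataFrame(rows, columns=[
        "group", "n_accessions", "n_haplotypes", "elite",
        "defining_genotype"])
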