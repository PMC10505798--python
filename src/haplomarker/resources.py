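"""Bundled reference tables: the default enzyme library, the published
marker table for the five rice salt-tolerance genes, and the published
elite-haplotype definitions.

The marker table is a faithful replica of the printed marker set (primer
sequences, band notation, enzymes); the elite-definition table records the
ATG-relative positions of the reported defining variants per gene, with
``REF``/``ALT`` wildcards because the sources give positions rather than
nucleotides for several genes.
"""

from __future__ import annotations

from importlib import resources as _ir

import pandas as pd

from .genomic_io import EnzymeDef
from .haplotyping import EliteDefinition
from .marker_design import parse_reference_size

# the one published dCAPS row whose printed primers carry no lowercase
# designed-mismatch base (presumably lost in typesetting); exempted from
# the lowercase check
LOWERCASE_EXEMPT = ("SKC1 5Ud",)


def _path(name: str):
    return _ir.files("haplomarker.data") / name


def load_default_enzymes() -> list[EnzymeDef]:
    df = pd.read_csv(_path("enzymes.tsv"), sep="\t")
    return [EnzymeDef(r.name, r.motif, int(r.cut_offset))
            for r in df.itertuples()]


def load_published_markers() -> pd.DataFrame:
    df = pd.read_csv(_path("published_markers.tsv"), sep="\t",
                     dtype=str, keep_default_na=False)
    return df


def load_elite_definitions() -> dict[str, EliteDefinition]:
    df = pd.read_csv(_path("elite_definitions.tsv"), sep="\t", dtype=str)
    out: dict[str, EliteDefinition] = {}
    for name, sub in df.groupby("definition_name", sort=False):
        alleles = {int(p): a for p, a in zip(sub["atg_pos"], sub["allele"])}
        out[name] = EliteDefinition(gene_id=sub["gene_id"].iloc[0],
                                    alleles=alleles,
                                    source_note=sub["source_note"].iloc[0])
    return out


def check_marker_table(df: pd.DataFrame) -> list[str]:
    """Consistency checks on a marker table in the printed dialect.

    Returns a list of human-readable problems (empty = clean): primer
    lengths 18-24 nt, digestion fragments summing to the amplicon, dCAPS
    small fragment equal to the mismatch-bearing primer's length, lowercase
    designed mismatch present in dCAPS primers (modulo the known exemption).
    """
    problems = []
    for r in df.itertuples():
        for side, primer in (("F", r.primer_f), ("R", r.primer_r)):
            if not 18 <= len(primer) <= 24:
                problems.append(
                    f"{r.marker_name}: {side} primer length {len(primer)}")
        sizes = parse_reference_size(r.reference_size)
        for cls in ("elite_bands", "other_bands"):
            bands = sizes[cls]
            if bands is None:
                problems.append(f"{r.marker_name}: unresolvable {cls}")
        eb, ob = sizes["elite_bands"], sizes["other_bands"]
        if r.marker_type in ("CAPS", "dCAPS") and eb and ob:
            cut, uncut = (eb, ob) if len(eb) > len(ob) else (ob, eb)
            if len(uncut) != 1 or sum(cut) != uncut[0]:
                problems.append(
                    f"{r.marker_name}: fragments {cut} do not sum to the "
                    f"amplicon {uncut}")
        if r.marker_type == "dCAPS" and eb and ob:
            cut = eb if len(eb) > len(ob) else ob
            has_lower = any(c.islower() for c in r.primer_f + r.primer_r)
            if not has_lower and r.marker_name not in LOWERCASE_EXEMPT:
                problems.append(
                    f"{r.marker_name}: dCAPS primers carry no designed "
                    "mismatch")
            plen = (len(r.primer_f)
                    if any(c.islower() for c in r.primer_f)
                    or r.marker_name in LOWERCASE_EXEMPT
                    else len(r.primer_r))
            if min(cut) != plen:
                problems.append(
                    f"{r.marker_name}: small fragment {min(cut)} != primer "
                    f"length {plen}")
        if r.marker_type == "Indel":
            if sizes["indel_size"] is None:
                problems.append(f"{r.marker_name}: Indel row without a "
                                "signed indel size")
            if r.restriction_enzyme.strip():
                problems.append(f"{r.marker_name}: Indel row with an enzyme")
    return problems
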