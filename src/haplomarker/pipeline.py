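"""End-to-end orchestration: classify a panel, flag elites, find unique
variants, design the planned markers and calibrate their band patterns on
the panel itself.

Marker band expectations are *calibrated*: after a marker is designed from
the local sequence context, every accession is genotyped in silico and the
elite/other lanes are re-derived from the actual allele classes (the same
way published marker sets are validated on a representative accession
panel).  A marker whose two classes do not produce two clean, resolvable
lanes is rejected.
"""

from __future__ import annotations

from typing import Iterable

from .errors import ClassificationError, DesignError
from .genomic_io import VariantRecord
from .haplotyping import (HaplotypeAssignment, classify_haplotypes,
                          find_unique_variants, mark_elite)
from .insilico_genotyping import band_pattern, gel_for, lanes_equal, merge_lane
from .marker_design import (DEFAULT_ENZYMES, MarkerSpec, design_caps,
                            design_dcaps, design_indel_marker)
from .synthetic_data import SimulatedPanel

_CONTEXT_WINDOW = {"CAPS": 520, "dCAPS": 210, "Indel": 220}


def classify_panel(panel: SimulatedPanel,
                   min_novel_size: int | None = None) -> HaplotypeAssignment:
    """Run two-tier classification + elite flagging on a simulated panel."""
    if min_novel_size is None:
        min_novel_size = panel.plan.min_novel_size
    assignment = classify_haplotypes(
        panel.variants, panel.genotypes, panel.panel,
        panel.reference_accession,
        sequenced_accessions=panel.sequenced,
        min_novel_size=min_novel_size, gene_id=panel.gene_id)
    defs = list(panel.truth.elite_defs.values())
    if defs:
        mark_elite(assignment, defs)
    return assignment


def resolve_truth_names(assignment: HaplotypeAssignment,
                        panel: SimulatedPanel,
                        plan_ids: Iterable[str]) -> list[str]:
    """Map plan-level group/haplotype ids to the assignment's Hap names."""
    names = []
    for pid in plan_ids:
        mset = panel.truth.target_member_set([pid],
                                             panel.plan.min_novel_size)
        hit = None
        for g in assignment.groups:
            if frozenset(g.members) == mset:
                hit = g.name
                break
            for h in g.haplotypes:
                if frozenset(h.members) == mset:
                    hit = h.name
                    break
        if hit is None:
            raise ClassificationError(
                f"no classified group/haplotype matches planned {pid!r}")
        names.append(hit)
    return names


def _context(panel: SimulatedPanel, v: VariantRecord, window: int
             ) -> tuple[str, int, set[int]]:
    """Design context around a variant plus the offsets of every *other*
    segregating position inside it (primers must stay off those)."""
    seq = panel.ref_region.seq
    off = panel.ref_region.atg_to_offset(v.atg_pos)
    lo = max(off - window, 0)
    hi = min(off + window + max(len(v.ref_allele) - 1, 0), len(seq) - 1)
    forbidden: set[int] = set()
    for other in panel.variants:
        if other.variant_id == v.variant_id:
            continue
        o = panel.ref_region.atg_to_offset(other.atg_pos)
        if other.vclass == "deletion":
            span = range(o, o + len(other.ref_allele))
        elif other.vclass == "insertion":
            span = range(o, o + 2)      # the junction the insertion splits
        else:
            span = range(o, o + 1)
        forbidden.update(p - lo for p in span if lo <= p <= hi)
    return seq[lo:hi + 1], off - lo, forbidden


def calibrate_marker(marker: MarkerSpec, panel: SimulatedPanel) -> MarkerSpec:
    """Re-derive elite/other band patterns from the panel's allele classes.

    Requires every accession of a class to produce one identical lane and
    the two class lanes to be gel-resolvable; raises otherwise.
    """
    vid = marker.target_variant.variant_id
    elite_val = 1 if marker.elite_allele == "alt" else 0
    lanes = {"elite": set(), "other": set()}
    for acc, seq in panel.sequences().items():
        allele = panel.genotypes.at[vid, acc]
        cls = "elite" if allele == elite_val else "other"
        pat = band_pattern(seq, marker, acc)
        if pat is None:
            raise DesignError(
                f"{marker.name}: no amplification for {acc}")
        lanes[cls].add(tuple(sorted(pat.bands)))
    for cls, seen in lanes.items():
        if len(seen) != 1:
            raise DesignError(
                f"{marker.name}: {cls} class produced {len(seen)} distinct "
                "lanes; amplicon overlaps an uncorrelated variant")
    eb, ob = next(iter(lanes["elite"])), next(iter(lanes["other"]))
    gel = gel_for(list(eb) + list(ob))
    if lanes_equal(merge_lane(eb, gel), merge_lane(ob, gel), gel):
        raise DesignError(f"{marker.name}: class lanes not resolvable")
    marker.elite_bands, marker.other_bands = tuple(eb), tuple(ob)
    return marker


def design_markers_for_panel(panel: SimulatedPanel,
                             calibrate: bool = True) -> list[MarkerSpec]:
    """Design every planned marker of a panel from unique elite variants."""
    assignment = classify_panel(panel)
    unique_by_query: dict[str, set[tuple[str, int]]] = {}
    for q in panel.truth.queries:
        targets = resolve_truth_names(assignment, panel, q["targets"])
        exclude = resolve_truth_names(assignment, panel, q["exclude"])
        found = find_unique_variants(assignment, targets, exclude)
        unique_by_query[q["name"]] = {(v.variant_id, a) for v, a in found}
    markers = []
    for mp in panel.plan.marker_plans:
        v = panel.variant(mp.vid)
        want_allele = 1 if mp.elite_allele == "alt" else 0
        if (mp.vid, want_allele) not in unique_by_query.get(mp.query, set()):
            raise DesignError(
                f"{mp.name}: target variant {mp.vid} is not unique to the "
                f"{mp.query} haplotypes")
        enzymes = [e for e in DEFAULT_ENZYMES
                   if not mp.enzymes or e.name in mp.enzymes]
        window = _CONTEXT_WINDOW[mp.mtype]
        if mp.mtype == "Indel" and v.indel_len > 30:
            window = v.indel_len + 700
        ctx, idx, forbidden = _context(panel, v, window)
        detected = tuple(resolve_truth_names(
            assignment, panel,
            next(q["targets"] for q in panel.truth.queries
                 if q["name"] == mp.query)))
        if mp.mtype == "CAPS":
            m = design_caps(v, ctx, enzymes, snp_index=idx,
                            elite_allele=mp.elite_allele, name=mp.name,
                            gene_id=panel.gene_id, detected=detected,
                            forbidden=forbidden)
        elif mp.mtype == "dCAPS":
            m = design_dcaps(v, ctx, enzymes, snp_index=idx,
                             elite_allele=mp.elite_allele, name=mp.name,
                             gene_id=panel.gene_id, detected=detected,
                             forbidden=forbidden)
        else:
            m = design_indel_marker(v, ctx, indel_offset=idx,
                                    elite_allele=mp.elite_allele,
                                    name=mp.name, gene_id=panel.gene_id,
                                    detected=detected, forbidden=forbidden)
        if calibrate:
            m = calibrate_marker(m, panel)
        markers.append(m)
    return markers


def design_suite_markers(suite: dict[str, SimulatedPanel]
                         ) -> dict[str, list[MarkerSpec]]:
    """Design the full marker set across a panel suite."""
    return {name: design_markers_for_panel(p) for name, p in suite.items()}
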