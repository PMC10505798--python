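"""Design of Indel, CAPS and dCAPS diagnostic markers from unique variants.

Marker rules, as practised for gel-scored intragenic markers:

* an insertion/deletion of 7-30 bp becomes an **Indel marker** scored by
  amplicon length (amplicon 100-300 bp, PAGE); an indel over 100 bp gets a
  400-1,000 bp amplicon (agarose);
* a SNP where one allele's context already contains a restriction site
  becomes a **CAPS marker** (amplicon 300-800 bp);
* a SNP with no natural site becomes a **dCAPS marker**: up to ``k``
  deliberate mismatches in a primer abutting the SNP create a site in
  exactly one allele's amplicon (amplicon 100-300 bp).

Primer scoring is deliberately simple and deterministic: length 18-24 nt,
GC 30-70 %, Wallace-rule melting temperature (2 degC per A/T + 4 degC per
G/C) within 52-62 degC, pair Tm difference <= 5 degC, G/C 3' clamp outside
mononucleotide runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DesignError
from .genomic_io import IUPAC, EnzymeDef, VariantRecord, revcomp

# the default library: common, cheap enzymes used for rice CAPS work
DEFAULT_ENZYMES: tuple[EnzymeDef, ...] = (
    EnzymeDef("EcoR I", "GAATTC", 1),
    EnzymeDef("EcoR II", "CCWGG", 0),
    EnzymeDef("Hha I", "GCGC", 3),
    EnzymeDef("Pst I", "CTGCAG", 5),
    EnzymeDef("Dra I", "TTTAAA", 3),
    EnzymeDef("Hinf I", "GANTC", 1),
    EnzymeDef("Hae III", "GGCC", 2),
)

PRIMER_MIN, PRIMER_MAX = 18, 24
TM_MIN, TM_MAX = 52.0, 62.0
GC_MIN, GC_MAX = 0.30, 0.70
TM_PAIR_DIFF = 5.0
CAPS_RANGE = (300, 800)
DCAPS_RANGE = (100, 300)
INDEL_SMALL_RANGE = (100, 300)
INDEL_LARGE_RANGE = (400, 1000)
MIN_CUT_MARGIN = 20  # preferred distance of the diagnostic cut from ends


# ---------------------------------------------------------------------------
# restriction-site scanning and digestion
# ---------------------------------------------------------------------------

def _matches_at(seq: str, motif: str, p: int) -> bool:
    """Motif match at 0-based position p; N in the sequence never matches."""
    if p < 0 or p + len(motif) > len(seq):
        return False
    for base, code in zip(seq[p:p + len(motif)], motif):
        if base not in IUPAC[code]:
            return False
    return True


def scan_restriction_sites(seq: str, enzyme: EnzymeDef) -> list[int]:
    """All 1-based top-strand start positions of the recognition site.

    Both orientations are scanned for non-palindromic motifs; positions are
    match starts on the given (top) strand.
    """
    seq = seq.upper()
    motifs = [enzyme.motif.upper()]
    if not enzyme.palindromic:
        motifs.append(revcomp(enzyme.motif.upper()))
    hits = set()
    for motif in motifs:
        for p in range(len(seq) - len(motif) + 1):
            if _matches_at(seq, motif, p):
                hits.add(p + 1)
    return sorted(hits)


def cut_positions(seq: str, enzyme: EnzymeDef) -> list[int]:
    """Top-strand cut points (bases left of the cut), deduplicated.

    Only cuts strictly inside the sequence are returned, since a cut at
    either boundary produces no new fragment.
    """
    seq = seq.upper()
    L = len(enzyme.motif)
    cuts = set()
    for p in range(len(seq) - L + 1):
        if _matches_at(seq, enzyme.motif.upper(), p):
            cuts.add(p + enzyme.cut_offset)
        if not enzyme.palindromic and \
                _matches_at(seq, revcomp(enzyme.motif.upper()), p):
            cuts.add(p + L - enzyme.cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def predict_digestion(amplicon_len: int, site_positions: Sequence[int],
                      enzyme: EnzymeDef | None = None) -> list[int]:
    """Fragment sizes from cut points; sum equals the amplicon length."""
    cuts = sorted(set(c for c in site_positions if 0 < c < amplicon_len))
    bounds = [0, *cuts, amplicon_len]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def digest(amplicon: str, enzyme: EnzymeDef | None) -> list[int]:
    """Band sizes of an amplicon after (optional) digestion."""
    if enzyme is None:
        return [len(amplicon)]
    return predict_digestion(len(amplicon), cut_positions(amplicon, enzyme))


# ---------------------------------------------------------------------------
# primers
# ---------------------------------------------------------------------------

def wallace_tm(seq: str) -> float:
    s = seq.upper()
    return 2.0 * (s.count("A") + s.count("T")) \
        + 4.0 * (s.count("G") + s.count("C"))


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(seq) if seq else 0.0


@dataclass(frozen=True)
class PrimerSpec:
    """One primer as synthesized; designed mismatches are lowercase.

    ``start`` is the 0-based offset of the leftmost template base of the
    binding site on the design template (top strand); a reverse primer's
    sequence is the reverse complement of that template slice.
    """

    seq: str
    start: int
    strand: str = "F"                  # F | R
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mismatch_positions and \
                (len(self.seq) - 1) in self.mismatch_positions:
            raise DesignError("designed mismatch at the primer 3' terminus")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """0-based offset of the rightmost bound template base."""
        return self.start + len(self.seq) - 1

    @property
    def tm(self) -> float:
        return wallace_tm(self.seq)


def _primer_checks(seq: str) -> list[str]:
    """Names of violated primer constraints (empty when admissible)."""
    bad = []
    if not PRIMER_MIN <= len(seq) <= PRIMER_MAX:
        bad.append("length")
    if any(b not in "ACGT" for b in seq.upper()):
        bad.append("ambiguous_base")
    if not GC_MIN <= gc_fraction(seq) <= GC_MAX:
        bad.append("gc_content")
    if not TM_MIN <= wallace_tm(seq) <= TM_MAX:
        bad.append("tm")
    if seq[-1].upper() not in "GC":
        bad.append("gc_clamp")
    elif len(seq) >= 4 and len(set(seq[-4:].upper())) == 1:
        bad.append("clamp_in_run")
    return bad


def design_primer_pair(template: str,
                       must_span: tuple[int, int],
                       product_range: tuple[int, int],
                       fixed_forward: PrimerSpec | None = None,
                       max_candidates: int = 60,
                       forbidden: Iterable[int] = (),
                       ) -> tuple[PrimerSpec, PrimerSpec]:
    """Pick a deterministic admissible primer pair on ``template``.

    ``must_span`` is a 0-based closed interval that the product must
    contain strictly between the primers; the product is measured from the
    forward primer's 5' end to the reverse primer's 5' end, inclusive.
    ``forbidden`` lists template offsets a primer may not cover (segregating
    positions elsewhere in the panel would abolish binding for one allele
    class).  Among admissible pairs the one with the smallest
    (product length, Tm difference, forward start) is returned.
    """
    template = template.upper()
    forbidden = set(forbidden)
    lo, hi = must_span
    pmin, pmax = product_range
    if pmin < 2 * PRIMER_MIN:
        pmin = max(pmin, 2 * PRIMER_MIN)
    if pmax < 2 * PRIMER_MIN:
        raise DesignError(
            "product range shorter than two primers; failed constraint: "
            "product_length")
    fails: Counter[str] = Counter()

    def f_candidates() -> list[PrimerSpec]:
        if fixed_forward is not None:
            return [fixed_forward]
        out = []
        for fe in range(lo - 1, -1, -1):          # 3' end, closest first
            for ln in range(PRIMER_MIN, PRIMER_MAX + 1):
                fs = fe - ln + 1
                if fs < 0:
                    continue
                if forbidden and forbidden & set(range(fs, fe + 1)):
                    fails.update(["covers_variable_site"])
                    continue
                seq = template[fs:fe + 1]
                bad = _primer_checks(seq)
                if bad:
                    fails.update(bad)
                    continue
                out.append(PrimerSpec(seq=seq, start=fs, strand="F"))
            if len(out) >= max_candidates:
                break
        return out

    def best_r_for(f: PrimerSpec) -> tuple[tuple, PrimerSpec] | None:
        """Smallest admissible product for this forward primer."""
        rs_lo = max(hi + 1, f.start + pmin - PRIMER_MAX)
        rs_hi = min(len(template) - PRIMER_MIN, f.start + pmax - PRIMER_MIN)
        for rs in range(rs_lo, rs_hi + 1):        # ascending: smallest first
            for ln in range(PRIMER_MIN, PRIMER_MAX + 1):
                re_ = rs + ln - 1
                if re_ >= len(template):
                    continue
                product = re_ - f.start + 1
                if not pmin <= product <= pmax:
                    fails.update(["product_length"])
                    continue
                if forbidden and forbidden & set(range(rs, re_ + 1)):
                    fails.update(["covers_variable_site"])
                    continue
                seq = revcomp(template[rs:re_ + 1])
                bad = _primer_checks(seq)
                if bad:
                    fails.update(bad)
                    continue
                r = PrimerSpec(seq=seq, start=rs, strand="R")
                dt = abs(f.tm - r.tm)
                if dt > TM_PAIR_DIFF:
                    fails.update(["tm_pair_difference"])
                    continue
                return ((product, dt, f.start), r)
        return None

    best = None
    for f in f_candidates():
        hit = best_r_for(f)
        if hit is None:
            continue
        key, r = hit
        if best is None or key < best[0]:
            best = (key, f, r)
    if best is None:
        worst = fails.most_common(1)
        reason = worst[0][0] if worst else "no_candidate_region"
        raise DesignError(
            f"no admissible primer pair; most frequently failed "
            f"constraint: {reason}")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# marker specification
# ---------------------------------------------------------------------------

@dataclass
class MarkerSpec:
    """A designed diagnostic marker with expected band patterns."""

    name: str
    gene_id: str
    mtype: str                          # Indel | CAPS | dCAPS
    target_variant: VariantRecord
    fwd: PrimerSpec
    rev: PrimerSpec
    enzyme: EnzymeDef | None
    elite_bands: tuple[int, ...]
    other_bands: tuple[int, ...]
    elite_allele: str                   # ref | alt
    detected_haplotypes: tuple[str, ...] = ()
    template_start_atg: int | None = None   # ATG coord of template offset 0
    alternatives: list["MarkerSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mtype == "Indel" and self.enzyme is not None:
            raise DesignError("Indel markers carry no enzyme")
        if self.mtype in ("CAPS", "dCAPS") and self.enzyme is None:
            raise DesignError(f"{self.mtype} markers need an enzyme")
        if Counter(self.elite_bands) == Counter(self.other_bands):
            raise DesignError("marker does not discriminate allele classes")
        if any(b < 1 for b in self.elite_bands + self.other_bands):
            raise DesignError("band sizes must be >= 1 bp")

    @property
    def elite_amplicon_len(self) -> int:
        return sum(self.elite_bands)

    @property
    def other_amplicon_len(self) -> int:
        return sum(self.other_bands)


def _apply_primer_bases(template: str, primer: PrimerSpec) -> str:
    """Substitute a primer's synthesized bases into the template slice."""
    s = list(template)
    if primer.strand == "F":
        enc = primer.seq.upper()
    else:
        enc = revcomp(primer.seq).upper()
    s[primer.start:primer.start + len(primer.seq)] = list(enc)
    return "".join(s)


def build_amplicon(template: str, fwd: PrimerSpec, rev: PrimerSpec) -> str:
    """Amplicon between primer 5' ends, carrying the primer-encoded bases."""
    mod = _apply_primer_bases(_apply_primer_bases(template, fwd), rev)
    return mod[fwd.start:rev.end + 1]


# ---------------------------------------------------------------------------
# CAPS
# ---------------------------------------------------------------------------

def _substitute(context: str, idx: int, base: str) -> str:
    return context[:idx] + base + context[idx + 1:]


def _overlapping_sites(context: str, enzyme: EnzymeDef, idx: int) -> list[int]:
    """0-based starts of recognition sites covering position ``idx``."""
    L = len(enzyme.motif)
    return [p - 1 for p in scan_restriction_sites(context, enzyme)
            if p - 1 <= idx <= p - 1 + L - 1]


def find_caps(v: VariantRecord, context: str,
              enzymes: Sequence[EnzymeDef] = DEFAULT_ENZYMES,
              snp_index: int | None = None) -> list[tuple[EnzymeDef, str]]:
    """Enzymes whose site covers the SNP in exactly one allele's context.

    ``context`` carries the reference allele at ``snp_index`` (defaults to
    the central base).  Returns ``(enzyme, cutting_allele)`` pairs where
    ``cutting_allele`` is ``"ref"`` or ``"alt"``; enzymes with a covering
    site in both alleles are excluded.
    """
    if v.vclass != "SNP":
        raise DesignError("CAPS design needs a SNP")
    context = context.upper()
    idx = len(context) // 2 if snp_index is None else snp_index
    if context[idx] != v.ref_allele:
        raise DesignError(
            f"context base {context[idx]} at the SNP index does not match "
            f"the reference allele {v.ref_allele}")
    alt_ctx = _substitute(context, idx, v.alt_allele)
    out = []
    for e in enzymes:
        in_ref = bool(_overlapping_sites(context, e, idx))
        in_alt = bool(_overlapping_sites(alt_ctx, e, idx))
        if in_ref ^ in_alt:
            out.append((e, "ref" if in_ref else "alt"))
    return out


def _gel_for(bands: Iterable[int]) -> str:
    return "PAGE" if max(bands) < 300 else "agarose"


def _bands_distinct_resolvable(b1: Sequence[int], b2: Sequence[int]) -> bool:
    """True when two lanes are distinguishable on the appropriate gel."""
    from .insilico_genotyping import merge_lane, lanes_equal
    gel = _gel_for(list(b1) + list(b2))
    m1, m2 = merge_lane(b1, gel), merge_lane(b2, gel)
    return not lanes_equal(m1, m2, gel)


def design_caps(v: VariantRecord, context: str,
                enzymes: Sequence[EnzymeDef] = DEFAULT_ENZYMES,
                snp_index: int | None = None,
                amplicon_range: tuple[int, int] = CAPS_RANGE,
                elite_allele: str = "alt",
                name: str = "", gene_id: str = "",
                detected: tuple[str, ...] = (),
                forbidden: Iterable[int] = ()) -> MarkerSpec:
    """Design a CAPS marker for a SNP with a natural allele-specific site.

    The amplicon is placed so the diagnostic cut sits at least
    ``MIN_CUT_MARGIN`` bp from both ends when the context allows it; an
    enzyme is rejected when constitutive sites leave the two allele band
    patterns indistinguishable.
    """
    context = context.upper()
    idx = len(context) // 2 if snp_index is None else snp_index
    candidates = find_caps(v, context, enzymes, idx)
    if not candidates:
        raise DesignError(f"no natural allele-specific site at "
                          f"{v.atg_pos:+d} for any enzyme")
    alt_ctx = _substitute(context, idx, v.alt_allele)
    errors = []
    for enzyme, cutting in candidates:
        try:
            fwd, rev = design_primer_pair(
                context,
                (max(idx - MIN_CUT_MARGIN, 0),
                 min(idx + MIN_CUT_MARGIN, len(context) - 1)),
                amplicon_range, forbidden=forbidden)
        except DesignError as exc:
            errors.append(f"{enzyme.name}: {exc}")
            continue
        amp_ref = build_amplicon(context, fwd, rev)
        amp_alt = build_amplicon(alt_ctx, fwd, rev)
        bands_ref = digest(amp_ref, enzyme)
        bands_alt = digest(amp_alt, enzyme)
        if not _bands_distinct_resolvable(bands_ref, bands_alt):
            errors.append(f"{enzyme.name}: allele band patterns not "
                          "resolvable")
            continue
        elite = bands_alt if elite_allele == "alt" else bands_ref
        other = bands_ref if elite_allele == "alt" else bands_alt
        return MarkerSpec(
            name=name or f"{gene_id or v.variant_id}_CAPS",
            gene_id=gene_id, mtype="CAPS", target_variant=v,
            fwd=fwd, rev=rev, enzyme=enzyme,
            elite_bands=tuple(elite), other_bands=tuple(other),
            elite_allele=elite_allele, detected_haplotypes=detected)
    raise DesignError("CAPS design failed for every candidate enzyme: "
                      + "; ".join(errors))


# ---------------------------------------------------------------------------
# dCAPS
# ---------------------------------------------------------------------------

def _pick_base(code: str) -> str:
    """Deterministic concrete base for an IUPAC code."""
    return IUPAC[code][0]


def _dcaps_one_orientation(v_ref: str, v_alt: str, context: str, idx: int,
                           enzymes: Sequence[EnzymeDef], k: int,
                           amplicon_range: tuple[int, int],
                           orientation: str) -> list[dict]:
    """Raw dCAPS placements with the mismatch-bearing primer left of the SNP.

    The caller runs this on both the given context ("F") and its reverse
    complement ("R").  Returns candidate dicts, validated downstream.
    """
    out = []
    context = context.upper()
    for enzyme in enzymes:
        motifs = [enzyme.motif.upper()]
        if not enzyme.palindromic:
            motifs.append(revcomp(enzyme.motif.upper()))
        for motif in motifs:
            L = len(motif)
            for d in range(L):                  # SNP at motif index d
                w = idx - d                     # window start on context
                if w < 0 or w + L > len(context):
                    continue
                code = motif[d]
                ref_in = v_ref in IUPAC[code]
                alt_in = v_alt in IUPAC[code]
                if ref_in == alt_in:
                    continue                    # not diagnostic at the SNP
                # bases right of the SNP are template-only: must match as is
                if any(context[w + i] not in IUPAC[motif[i]]
                       for i in range(d + 1, L)):
                    continue
                mism = [i for i in range(d)
                        if context[w + i] not in IUPAC[motif[i]]]
                if len(mism) > k:
                    continue
                if d >= 1 and (d - 1) in mism:
                    continue                    # would sit at primer 3' end
                if d == 0 and mism:
                    continue
                out.append(dict(enzyme=enzyme, motif=motif, window=w,
                                snp_motif_index=d,
                                mismatch_ctx=[w + i for i in mism],
                                mismatch_bases={w + i: _pick_base(motif[i])
                                                for i in mism},
                                cut_allele="ref" if ref_in else "alt",
                                orientation=orientation))
    return out


def _fixed_primer_for(context: str, idx: int, cand: dict) -> PrimerSpec | None:
    """Build the mismatch-bearing forward primer ending at the base before
    the SNP, choosing the admissible length closest to the Tm midpoint."""
    end = idx - 1                       # 0-based inclusive 3' end
    need = cand["mismatch_ctx"]
    min_len_cover = (end - min(need) + 1 + 1) if need else PRIMER_MIN
    best, best_strict = None, None
    for ln in range(max(PRIMER_MIN, min_len_cover), PRIMER_MAX + 1):
        fs = end - ln + 1
        if fs < 0:
            continue
        bases = list(context[fs:end + 1].upper())
        mpos = []
        for ci, nb in cand["mismatch_bases"].items():
            bases[ci - fs] = nb.lower()
            mpos.append(ci - fs)
        seq = "".join(bases)
        if (ln - 1) in mpos:
            continue
        up = seq.upper()
        if any(b not in "ACGT" for b in up):
            continue
        score = abs(wallace_tm(up) - (TM_MIN + TM_MAX) / 2)
        bad = [c for c in _primer_checks(up) if c not in
               ("gc_clamp", "clamp_in_run")]   # 3' end is forced by the SNP
        primer = PrimerSpec(seq=seq, start=fs, strand="F",
                            mismatch_positions=tuple(sorted(mpos)))
        if not bad and (best_strict is None or score < best_strict[0]):
            best_strict = (score, primer)
        if best is None or score < best[0]:
            best = (score, primer)
    pick = best_strict or best
    return pick[1] if pick else None


def design_dcaps(v: VariantRecord, context: str,
                 enzymes: Sequence[EnzymeDef] = DEFAULT_ENZYMES,
                 k: int = 1,
                 amplicon_range: tuple[int, int] = DCAPS_RANGE,
                 snp_index: int | None = None,
                 elite_allele: str = "alt",
                 name: str = "", gene_id: str = "",
                 detected: tuple[str, ...] = (),
                 forbidden: Iterable[int] = ()) -> MarkerSpec:
    """Design a dCAPS marker: <=k primer mismatches create a site in one
    allele's amplicon.

    Both primer orientations are tried; candidates are validated by
    re-scanning the primer-modified amplicons of both alleles and ranked by
    (number of designed mismatches, least-centred cut distance, amplicon
    length).  The diagnostic small fragment is the primer-side piece.
    """
    if v.vclass != "SNP":
        raise DesignError("dCAPS design needs a SNP")
    context = context.upper()
    idx = len(context) // 2 if snp_index is None else snp_index
    if context[idx] != v.ref_allele:
        raise DesignError("context base at the SNP index does not match the "
                          "reference allele")
    diagnostics: dict[str, str] = {}
    specs: list[tuple[tuple, MarkerSpec]] = []
    forbidden = set(forbidden)
    for orientation in ("F", "R"):
        if orientation == "F":
            ctx, i2 = context, idx
            ref_b, alt_b = v.ref_allele, v.alt_allele
            forb = forbidden
        else:
            ctx, i2 = revcomp(context), len(context) - 1 - idx
            ref_b, alt_b = revcomp(v.ref_allele), revcomp(v.alt_allele)
            forb = {len(context) - 1 - o for o in forbidden}
        cands = _dcaps_one_orientation(ref_b, alt_b, ctx, i2, enzymes, k,
                                       amplicon_range, orientation)
        alt_ctx = _substitute(ctx, i2, alt_b)
        for cand in cands:
            primer = _fixed_primer_for(ctx, i2, cand)
            ename = cand["enzyme"].name
            if primer is None:
                diagnostics.setdefault(ename, "no admissible fixed primer")
                continue
            if forb & set(range(primer.start, primer.end + 1)):
                diagnostics.setdefault(
                    ename, "mismatch primer covers a variable site")
                continue
            try:
                fwd, rev = design_primer_pair(
                    ctx, (i2, cand["window"] + len(cand["motif"]) - 1),
                    amplicon_range, fixed_forward=primer, forbidden=forb)
            except DesignError as exc:
                diagnostics.setdefault(ename, str(exc))
                continue
            amp_ref = build_amplicon(ctx, fwd, rev)
            amp_alt = build_amplicon(alt_ctx, fwd, rev)
            enzyme = cand["enzyme"]
            cuts_ref = cut_positions(amp_ref, enzyme)
            cuts_alt = cut_positions(amp_alt, enzyme)
            designed_cut_in = ("ref" if cuts_ref and not cuts_alt else
                               "alt" if cuts_alt and not cuts_ref else None)
            if designed_cut_in is None or designed_cut_in != cand["cut_allele"]:
                # constitutive sites elsewhere may still be tolerable if the
                # band multisets stay distinct; fall through to that check
                pass
            bands_ref = predict_digestion(len(amp_ref), cuts_ref)
            bands_alt = predict_digestion(len(amp_alt), cuts_alt)
            # soundness: the designed site must cut exactly one allele
            cut_allele_cuts = cuts_alt if cand["cut_allele"] == "alt" else cuts_ref
            other_cuts = cuts_ref if cand["cut_allele"] == "alt" else cuts_alt
            site_cut = [c for c in cut_allele_cuts if c not in other_cuts]
            if not site_cut:
                diagnostics.setdefault(
                    ename, "designed site not allele-specific after "
                    "re-scanning")
                continue
            if not _bands_distinct_resolvable(bands_ref, bands_alt):
                diagnostics.setdefault(
                    ename, "allele band patterns not resolvable")
                continue
            elite = bands_alt if elite_allele == "alt" else bands_ref
            other = bands_ref if elite_allele == "alt" else bands_alt
            amp_len = len(amp_ref)
            centred = min(abs(c - amp_len / 2) for c in site_cut)
            key = (len(cand["mismatch_ctx"]), centred, amp_len,
                   enzymes.index(enzyme) if enzyme in enzymes else 99,
                   orientation)
            spec = MarkerSpec(
                name=name or f"{gene_id or v.variant_id}_dCAPS",
                gene_id=gene_id, mtype="dCAPS", target_variant=v,
                fwd=fwd, rev=rev, enzyme=enzyme,
                elite_bands=tuple(elite), other_bands=tuple(other),
                elite_allele=elite_allele, detected_haplotypes=detected)
            specs.append((key, spec))
    if not specs:
        per_enzyme = "; ".join(f"{e.name}: "
                               f"{diagnostics.get(e.name, 'no placement')}"
                               for e in enzymes)
        raise DesignError(f"no dCAPS design for {v.atg_pos:+d} with k={k} "
                          f"({per_enzyme})")
    specs.sort(key=lambda t: t[0])
    best = specs[0][1]
    best.alternatives = [s for _, s in specs[1:4]]
    return best


# ---------------------------------------------------------------------------
# Indel markers
# ---------------------------------------------------------------------------

def design_indel_marker(v: VariantRecord, context: str,
                        indel_offset: int | None = None,
                        elite_allele: str = "alt",
                        force: bool = False,
                        name: str = "", gene_id: str = "",
                        detected: tuple[str, ...] = (),
                        forbidden: Iterable[int] = ()) -> MarkerSpec:
    """Design a length-polymorphism marker flanking an indel.

    ``context`` carries the *reference* allele; ``indel_offset`` is the
    0-based context offset of the first deleted base (deletion) or of the
    anchor base before the insertion.  Indels of 7-30 bp get a 100-300 bp
    amplicon; indels over 100 bp a 400-1,000 bp amplicon; other sizes are
    rejected unless ``force`` is set.
    """
    if v.vclass not in ("insertion", "deletion"):
        raise DesignError("Indel marker design needs an insertion/deletion")
    size = v.indel_len
    if 7 <= size <= 30:
        product_range = INDEL_SMALL_RANGE
    elif size > 100:
        # keep the short allele's product a scoreable size too
        if size + INDEL_SMALL_RANGE[0] > INDEL_LARGE_RANGE[1]:
            raise DesignError(f"indel of {size} bp leaves no admissible "
                              "amplicon size")
        product_range = (max(INDEL_LARGE_RANGE[0],
                             size + INDEL_SMALL_RANGE[0]),
                         INDEL_LARGE_RANGE[1])
    elif force:
        product_range = INDEL_SMALL_RANGE if size < 7 else INDEL_LARGE_RANGE
    else:
        raise DesignError(
            f"indel of {size} bp outside the marker size classes "
            "(7-30 bp or >100 bp); pass force=True to override")
    context = context.upper()
    idx = len(context) // 2 if indel_offset is None else indel_offset
    forbidden = set(forbidden)
    if v.vclass == "deletion":
        long_template = context
        span = (max(idx - 1, 0),
                min(idx + len(v.ref_allele), len(context) - 1))
    else:
        ins_len = len(v.alt_allele)
        long_template = (context[:idx + 1] + v.alt_allele.upper()
                         + context[idx + 1:])
        span = (max(idx, 0), min(idx + ins_len + 1,
                                 len(long_template) - 1))
        # map forbidden context offsets onto the insertion-bearing template
        forbidden = {o if o <= idx else o + ins_len for o in forbidden}
    fwd, rev = design_primer_pair(long_template, span, product_range,
                                  forbidden=forbidden)
    long_len = rev.end - fwd.start + 1
    short_len = long_len - size
    long_is_ref = v.vclass == "deletion"
    band_ref = long_len if long_is_ref else short_len
    band_alt = short_len if long_is_ref else long_len
    elite = (band_alt,) if elite_allele == "alt" else (band_ref,)
    other = (band_ref,) if elite_allele == "alt" else (band_alt,)
    if not _bands_distinct_resolvable(elite, other):
        raise DesignError("allele amplicons not resolvable on the scoring gel")
    # report primers in reference-context coordinates for deletions; for
    # insertions the template includes the inserted bases
    return MarkerSpec(
        name=name or f"{gene_id or v.variant_id}_Indel",
        gene_id=gene_id, mtype="Indel", target_variant=v,
        fwd=fwd, rev=rev, enzyme=None,
        elite_bands=elite, other_bands=other,
        elite_allele=elite_allele, detected_haplotypes=detected)


# ---------------------------------------------------------------------------
# marker table (the printed-table dialect)
# ---------------------------------------------------------------------------

def format_reference_size(m: MarkerSpec) -> str:
    """Band notation: elite class before '/', other class after.

    Multi-fragment classes are bracketed, e.g. ``423/(202, 221)``; Indel
    rows bracket the class carrying the indel allele as its signed size,
    e.g. ``(-17)/179``.
    """
    if m.mtype == "Indel":
        signed = len(m.target_variant.alt_allele) \
            - len(m.target_variant.ref_allele)
        tok = f"({signed:+d})"
        if m.elite_allele == "alt":
            return f"{tok}/{m.other_bands[0]}"
        return f"{m.elite_bands[0]}/{tok}"

    def side(bands: tuple[int, ...]) -> str:
        if len(bands) == 1:
            return str(bands[0])
        return "(" + ", ".join(str(b) for b in sorted(bands)) + ")"

    return f"{side(m.elite_bands)}/{side(m.other_bands)}"


def parse_reference_size(text: str) -> dict:
    """Parse the printed band notation into per-class band sizes.

    Returns a dict with keys ``elite_bands``, ``other_bands`` (tuples of bp,
    either may be None when only derivable from the indel size) and
    ``indel_size`` (signed bp, or None for CAPS/dCAPS rows).
    """
    text = text.strip()
    depth, cutp = 0, None
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "/" and depth == 0:
            cutp = i
            break
    if cutp is None:
        raise ValueError(f"no top-level '/' in {text!r}")
    sides = [text[:cutp].strip(), text[cutp + 1:].strip()]
    indel_size = None
    parsed: list[tuple[int, ...] | None] = []
    signed_side = None
    for si, s in enumerate(sides):
        if s.startswith("(") and s.endswith(")"):
            inner = s[1:-1].strip()
            if inner.startswith(("+", "-")):
                indel_size = int(inner)
                parsed.append(None)
                signed_side = si
                continue
            parsed.append(tuple(sorted(int(x) for x in inner.split(","))))
        else:
            parsed.append((int(s),))
    if indel_size is not None and signed_side is not None:
        other_side = parsed[1 - signed_side]
        if other_side is not None and len(other_side) == 1:
            parsed[signed_side] = (other_side[0] + indel_size,)
    return dict(elite_bands=parsed[0], other_bands=parsed[1],
                indel_size=indel_size)


def markers_to_frame(markers: Sequence[MarkerSpec]):
    import pandas as pd

    rows = []
    for m in markers:
        rows.append(dict(
            gene=m.gene_id,
            variation_position=f"{m.target_variant.atg_pos:+d}",
            variation_id=m.target_variant.variant_id,
            marker_type=m.mtype,
            marker_name=m.name,
            primer_f=m.fwd.seq,
            primer_r=m.rev.seq,
            reference_size=format_reference_size(m),
            restriction_enzyme=m.enzyme.name if m.enzyme else "",
            haplotypes=";".join(m.detected_haplotypes),
        ))
    return pd.DataFrame(rows)


def write_marker_table(path, markers: Sequence[MarkerSpec]) -> None:
    markers_to_frame(markers).to_csv(path, sep="\t", index=False)
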