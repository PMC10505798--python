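"""Virtual PCR, digestion and gel scoring: the computational twin of
running designed markers on a germplasm panel.

Everything here is deterministic.  Primer binding is exact except at the
designed (lowercase) mismatch positions, which tolerate any template base
by construction; the amplicon carries the primer-encoded bases.  A simple
gel-resolution model decides whether two fragments co-migrate: 6 %
polyacrylamide (PAGE) resolves differences of at least max(4 bp, 2 % of
the smaller fragment); 2 % agarose at least max(20 bp, 5 %).  Lanes whose
largest band is under 300 bp are scored on PAGE, larger ones on agarose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import GenotypingError
from .genomic_io import RegionSequence, revcomp
from .marker_design import MarkerSpec, digest


# ---------------------------------------------------------------------------
# gel model
# ---------------------------------------------------------------------------

def resolvable(b1: int, b2: int, gel: str) -> bool:
    """Can two fragment sizes be told apart on the given gel?"""
    if b1 < 1 or b2 < 1:
        raise ValueError("fragment sizes must be >= 1 bp")
    diff = abs(b1 - b2)
    small = min(b1, b2)
    if gel == "PAGE":
        return diff >= max(4, 0.02 * small)
    if gel == "agarose":
        return diff >= max(20, 0.05 * small)
    raise ValueError(f"unknown gel {gel!r}")


def gel_for(bands: Sequence[int]) -> str:
    """PAGE for lanes whose largest band is under 300 bp, else agarose."""
    return "PAGE" if max(bands) < 300 else "agarose"


def merge_lane(bands: Sequence[int], gel: str) -> list[int]:
    """Collapse co-migrating fragments into single apparent bands."""
    out: list[list[int]] = []
    for b in sorted(bands):
        if out and not resolvable(out[-1][-1], b, gel):
            out[-1].append(b)
        else:
            out.append([b])
    return [round(sum(c) / len(c)) for c in out]


def lanes_equal(l1: Sequence[int], l2: Sequence[int], gel: str) -> bool:
    """Two (merged) lanes look identical on the gel."""
    if len(l1) != len(l2):
        return False
    return all(not resolvable(a, b, gel)
               for a, b in zip(sorted(l1), sorted(l2)))


@dataclass(frozen=True)
class BandPattern:
    marker: str
    accession_id: str
    bands: tuple[int, ...]
    gel: str


@dataclass(frozen=True)
class GenotypeCall:
    marker: str
    accession_id: str
    call: str                  # elite | other | unknown | no_amplification


# ---------------------------------------------------------------------------
# virtual PCR
# ---------------------------------------------------------------------------

def _binding_sites(template: str, site_seq: str,
                   tolerated: frozenset[int],
                   max_mismatches: int) -> list[int]:
    """0-based starts where ``site_seq`` matches the template.

    ``tolerated`` are 0-based positions within ``site_seq`` where any
    template base is accepted (the designed mismatches); other positions
    allow at most ``max_mismatches`` differences.
    """
    L = len(site_seq)
    out = []
    for p in range(len(template) - L + 1):
        mm = 0
        ok = True
        for i in range(L):
            if i in tolerated:
                continue
            if template[p + i] != site_seq[i]:
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            out.append(p)
    return out


def virtual_pcr(template: RegionSequence | str, marker: MarkerSpec,
                max_unintended_mismatches: int = 0) -> str | None:
    """Predicted amplicon of a marker on a template, or None.

    Multiple alternative products raise a non-specific-marker error; the
    returned amplicon spans the primer 5' ends inclusive and carries the
    primer-encoded bases (so designed mismatches propagate).
    """
    seq = (template.seq if isinstance(template, RegionSequence)
           else template).upper()
    f = marker.fwd
    r = marker.rev
    f_site = f.seq.upper()
    f_tol = frozenset(f.mismatch_positions)
    # the reverse primer anneals to the top strand as its reverse complement
    r_site = revcomp(r.seq).upper()
    r_tol = frozenset(len(r.seq) - 1 - i for i in r.mismatch_positions)
    f_hits = _binding_sites(seq, f_site, f_tol, max_unintended_mismatches)
    r_hits = _binding_sites(seq, r_site, r_tol, max_unintended_mismatches)
    products = []
    for fs in f_hits:
        for rs in r_hits:
            if rs + len(r_site) <= fs + len(f_site):
                continue
            if rs < fs + len(f_site):
                continue            # overlapping primers: no product
            products.append((fs, rs))
    if not products:
        return None
    if len(products) > 1:
        loci = ", ".join(f"[{fs}..{rs + len(r_site) - 1}]"
                         for fs, rs in products[:5])
        raise GenotypingError(
            f"non-specific marker {marker.name}: alternative products at "
            f"{loci}")
    fs, rs = products[0]
    amp = list(seq[fs:rs + len(r_site)])
    amp[:len(f_site)] = list(f_site)
    amp[-len(r_site):] = list(r_site)
    return "".join(amp)


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def band_pattern(template: RegionSequence | str, marker: MarkerSpec,
                 accession_id: str = "",
                 max_unintended_mismatches: int = 0) -> BandPattern | None:
    amp = virtual_pcr(template, marker, max_unintended_mismatches)
    if amp is None:
        return None
    bands = tuple(digest(amp, marker.enzyme))
    return BandPattern(marker=marker.name, accession_id=accession_id,
                       bands=bands, gel=gel_for(bands))


def genotype_accession(template: RegionSequence | str, marker: MarkerSpec,
                       accession_id: str = "",
                       max_unintended_mismatches: int = 0) -> GenotypeCall:
    """Call elite/other/unknown/no_amplification for one accession.

    The observed lane is compared with the marker's expected elite and
    other lanes after merging co-migrating fragments; a lane matching
    neither class exactly (or both) is reported unknown.
    """
    if isinstance(template, RegionSequence) and not accession_id:
        accession_id = template.accession_id
    pat = band_pattern(template, marker, accession_id,
                       max_unintended_mismatches)
    if pat is None:
        return GenotypeCall(marker.name, accession_id, "no_amplification")
    gel = gel_for(list(pat.bands) + list(marker.elite_bands)
                  + list(marker.other_bands))
    obs = merge_lane(pat.bands, gel)
    is_elite = lanes_equal(obs, merge_lane(marker.elite_bands, gel), gel)
    is_other = lanes_equal(obs, merge_lane(marker.other_bands, gel), gel)
    if is_elite and not is_other:
        call = "elite"
    elif is_other and not is_elite:
        call = "other"
    else:
        call = "unknown"
    return GenotypeCall(marker.name, accession_id, call)


def genotype_panel(panel: Mapping[str, str] | Sequence[RegionSequence],
                   markers: Sequence[MarkerSpec],
                   max_unintended_mismatches: int = 0,
                   ) -> pd.DataFrame:
    """Accession-by-marker matrix of genotype calls."""
    if isinstance(panel, Mapping):
        items = list(panel.items())
    else:
        items = [(r.accession_id, r.seq) for r in panel]
    rows = {}
    for acc, seq in items:
        rows[acc] = {m.name: genotype_accession(seq, m, acc,
                                                max_unintended_mismatches
                                                ).call
                     for m in markers}
    return pd.DataFrame.from_dict(rows, orient="index")
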