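# Methods

This note records the models, conventions and numerical choices behind
`haplomarker`, and what the synthetic panels do and do not establish about
real germplasm data.

## Coordinate system and analysis region

All per-gene work happens on the coding strand of one *analysis region*:
`upstream_len` bases before the start codon (default 2,000), the unspliced
ORF, and `downstream_len` bases after the stop codon (default 1,000).
Positions are signed start-codon-relative integers with the A of the ATG at
+1, the adjacent upstream base at −1 and no zero; the axis counts genomic
(unspliced) bases, so intronic and downstream positions are directly
addressable. Following the convention of gene-region haplotype surveys, the
whole upstream window is labelled 5'UTR and the downstream window 3'UTR,
without inferring transcript UTR boundaries. Genomic coordinates are
1-based closed (GFF3/VCF convention); minus-strand genes are normalized on
ingestion so sequences, alleles and exon order are all coding-strand.

## Variant calling and effect annotation

Per-accession region sequences are compared to the reference either as
pre-aligned equal-length strings or through a bundled global aligner
(Biopython's `PairwiseAligner`; match 2, mismatch −3, a gap of length L
costs 7 + 2L). These scores favour one compact indel over scattered
mismatches at the desk scale of a 3–8 kb gene region; the alignment itself
is standard, so an externally aligned input is accepted unchanged. Indels
are left-normalized (shifted to the smallest coordinate among equivalent
placements) because single printed positions are the field's convention.
Alleles are stored unanchored (deletion alt = "", insertion ref = ""); the
VCF writer re-anchors. Samples more than 50 % ambiguous bases are skipped
with a warning.

Effects: exonic SNPs are classified by translating the affected codon with
both alleles (synonymous / missense / premature stop / stop loss); any SNP
in the first codon is a start loss; exonic indels are frameshift when the
number of affected CDS bases is not a multiple of three, else in-frame. A
variant straddling an exon boundary is labelled by the exon it disrupts and
scored by the CDS bases it removes. Everything else is noncoding. The test
suite checks the SNP classifier against an independent oracle that
translates the whole mutant CDS and diffs the proteins.

## Haplotype classification

Tier 1 keys accessions by their genotype vector over *functional* variants
(missense, in-frame indel, frameshift, premature stop, start/stop loss);
tier 2 refines by the remaining variants. Accessions are assumed inbred:
heterozygous or missing calls at any classifying variant exclude the
accession (reported as unassigned) rather than guessing. The reference
accession's group is HapA and its haplotype HapA-1; remaining groups are
lettered by descending member count with ties broken by the
lexicographically smallest member id, haplotypes numbered likewise within
groups. Novel haplotypes — those containing no member of the designated
fully-sequenced subset — are dropped below five members, the reporting
threshold used for imputed panels; haplotypes anchored by a sequenced
accession are kept at any size.

Elite definitions are position→allele maps (with `REF`/`ALT` wildcards for
sources that print positions but not nucleotides). A haplotype is elite
when it carries every defining allele of at least one definition; a group
is elite when all its haplotypes are, and the two levels are reported
separately because elite status of a group does not always propagate to
every sub-haplotype.

The unique-variant scan accepts **either** allele as the diagnostic one:
when the reference accession itself belongs to an elite group (as happens
for two of the five rice genes), the allele private to the elite set is the
reference allele, so restricting the scan to alternate alleles would
miss every such marker target. An `exclude` set reproduces the published
practice of waiving rare types when declaring uniqueness.

## Marker design

Size rules: Indels of 7–30 bp → 100–300 bp amplicons; >100 bp → 400–1,000
bp amplicons, additionally constrained so the short allele's product stays
≥100 bp (scoreable on a gel); 31–100 bp and <7 bp are rejected unless
forced. CAPS amplicons are 300–800 bp, dCAPS 100–300 bp.

Restriction scanning expands IUPAC codes and scans both strands for
non-self-complementary motifs; an N in the sequence never matches. The
default library is seven cheap, common enzymes (EcoR I, EcoR II, Hha I,
Pst I, Dra I, Hinf I, Hae III) in a user-extensible TSV; "common and cheap"
is operationalized as this configurable whitelist. Digestion is pure
arithmetic on top-strand cut points; fragment sizes always sum to the
amplicon length.

dCAPS design enumerates, for each enzyme and both orientations, every
placement of the motif over the SNP where the motif base at the SNP accepts
exactly one allele; bases 3' of the SNP must match the template as-is, and
up to *k* = 1 template mismatches 5' of the SNP become lowercase primer
substitutions (never at the primer's 3'-terminal base, mirroring
standard dCAPS practice and the single lowercase bases in published
primers). Every candidate is validated by rebuilding both alleles'
primer-modified amplicons and re-scanning them; candidates are ranked by
(fewest mismatches, most central cut, smallest amplicon) and the best is
emitted with alternatives attached. Fragment sizes are the *physical* cut
positions; for an EcoR I dCAPS the primer-side fragment is therefore
primer length − 4, whereas published tables round it to the primer length —
a display convention the bundled replica preserves verbatim.

Primer scoring is deliberately simple and deterministic (the original
assays were designed with commercial software whose scoring is not
reproducible): length 18–24 nt, GC 30–70 %, Wallace-rule Tm
(2 °C·AT + 4 °C·GC) within 52–62 °C, pair ΔTm ≤ 5 °C, 3' G/C clamp outside
mononucleotide runs ≥4. Among admissible pairs the smallest product wins,
ties by ΔTm — this also keeps amplicons from overlapping unrelated
variants. Nearest-neighbour thermodynamics, hairpin/dimer ΔG and multiplex
compatibility are out of scope.

Designed markers are *calibrated*: every accession of the panel is
genotyped in silico and the elite/other lanes are re-derived from the
actual allele classes (published marker sets are validated on a
representative accession panel in the same spirit). A marker whose classes
do not yield two clean, gel-resolvable lanes — e.g. because its amplicon
overlaps an uncorrelated segregating variant — is rejected.

## Gel model and genotype calls

Lanes whose largest band is under 300 bp are scored on 6 % PAGE, larger on
2 % agarose, following the published gel-class split. The resolution
thresholds are this package's own model, stated explicitly because the
sources name only gel recipes: PAGE resolves |Δ| ≥ max(4 bp, 2 % of the
smaller fragment), agarose |Δ| ≥ max(20 bp, 5 %). Co-migrating fragments
within a lane merge into one apparent band before comparison. Primer
binding is exact except at designed mismatch positions (a tolerance flag
exists for robustness experiments); more than one potential product raises
a non-specific-marker error. A lane matching exactly one expected class is
called elite or other; anything else is unknown, and amplification failure
is its own call. No genotyping-error model is included.

## Synthetic panels

The generator emulates the study design of gene-region haplotype surveys:
a random reference gene (exon lengths and intron lengths configurable;
default three 300-bp exons, two 300-bp introns, 2-kb/1-kb flanks), an
inbred panel (default 60 accessions) drawn over the rice subpopulation
labels (XI, XI-IM, IM, GJ-IM, GJ-tem, GJ-tro, VI/Aro, aus, other) with
per-haplotype subpopulation skew, one reference group, one elite group
defined by two exonic missense variants, three further groups from private
missense variants, four silent variants splitting groups into haplotypes,
and one rare novel haplotype of four members sitting below the reporting
threshold. Every planted variant is placed with spacing constraints and
*verified*: the generated reference is re-annotated and the variant's
region and effect must equal the intent (synonymous variants are verified
by translation, embedded restriction-site contexts must not break the open
reading frame), with rejection and resampling of confounded draws. Ground
truth (memberships, elite sets, expected unique alleles) is computed from
the plan by an independent code path, not by running the classifier.

Five fixed plans mirror the qualitative structure of the published
five-gene marker set: an elite group with four private missense variants
(one natural CAPS site, two dCAPS-only targets); an elite group defined by
a premature stop that destroys a Pst I site present in the reference allele
(the published band table shows the elite amplicon uncut, which fixes the
site on the non-elite allele); two elite groups including the reference
group, defined by six reference alleles, plus a second elite pair — a
group and a single haplotype — detected by 391-bp and 17-bp promoter
indels; an elite group with exactly two private variants; and an elite
pair with a 514-bp promoter deletion and two CAPS sites. Positions are
structural analogs, not the printed coordinates; in particular the large
promoter indels are placed inside the declared upstream window (the
published markers at −2447 and −2858 lie beyond the stated 2-kb region,
so the fifth panel uses a 2.6-kb window). Together the five panels support
3+1+3+1+3 = 11 markers of the same types as the published set.

What the panels do **not** emulate: linkage and recombination (haplotype
structure is label-only), genotyping error and imputation noise, multiple
genes per chromosome, transcript-level UTRs, and the real panels' sample
sizes (the published group counts per gene depend on a 4,726-accession
imputed panel and are not reproducible at this scale). Passing tests
therefore demonstrate correctness of the algorithms under clean,
structurally faithful conditions, not robustness to noisy field data.

## Problem sizes

The default test battery uses 60-accession random panels (200 seeds for the
recovery property), ~40–55-accession mimic panels, 4.5–6.5-kb gene regions,
10,000 random cases for the restriction-scan oracle and ~300 random
single-variant toys per batch for the effect-annotation oracle; the full
suite runs in well under a minute on one CPU, and `scripts/acceptance.py`
in about ten seconds.
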