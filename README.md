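# haplomarker

Gene-region haplotype classification and diagnostic-marker development for
inbred crop germplasm panels, with rice salt-tolerance genes as the worked
case.

## The problem

Breeders who want to introgress a cloned gene need two things: to know which
accessions of a germplasm panel carry the favourable (*elite*) haplotype,
and a cheap gel-scored assay that distinguishes that haplotype from every
other one in the panel. `haplomarker` implements that workflow end to end
for a single gene region — the 2-kb window upstream of the start codon, the
unspliced ORF, and the 1-kb window downstream of the stop codon, all on the
coding strand, with positions on a signed start-codon-relative axis (the A
of the ATG is **+1**, the base upstream is **−1**, there is no zero, and
intron bases are counted).

The pipeline stages are:

1. **Extraction & variant calling** (`genomic_io`, `gene_region_effects`) —
   slice the analysis region from a reference genome + GFF3, call SNPs and
   left-normalized indels per accession (global pairwise alignment, or a
   VCF genotype matrix), and annotate every variant with a region label
   (5'UTR / exon *k* / intron *k* / 3'UTR) and a coding effect (synonymous,
   missense, premature stop, start/stop loss, in-frame indel, frameshift).
2. **Two-tier haplotyping** (`haplotyping`) — *haplotype groups* share a
   genotype at all protein-altering variants; *haplotypes* refine groups by
   silent variants. The reference accession's group is HapA (haplotype
   HapA-1); other groups are lettered by descending size. Novel haplotypes
   (no fully-sequenced member) with fewer than five accessions are dropped.
   Published elite definitions flag elite groups/haplotypes, and a
   unique-variant scan finds alleles carried by *exactly* the elite members
   — the prerequisite for a diagnostic marker.
3. **Marker design** (`marker_design`) — an indel of 7–30 bp becomes an
   **Indel marker** (100–300 bp amplicon); >100 bp gets a 400–1,000 bp
   amplicon. A SNP whose context gives one allele a natural restriction
   site becomes a **CAPS marker** (300–800 bp); otherwise a **dCAPS
   marker** (100–300 bp) is designed by placing ≤1 deliberate mismatch
   (lowercase in the primer) so the site forms in only one allele's
   amplicon. Primer scoring is deterministic: 18–24 nt, GC 30–70 %,
   Wallace-rule Tm (2·AT + 4·GC °C) in 52–62 °C, pair ΔTm ≤ 5 °C, G/C
   clamp.
4. **In-silico genotyping** (`insilico_genotyping`) — virtual PCR and
   digestion predict each accession's band pattern; lanes under 300 bp are
   scored on 6 % PAGE (resolution max(4 bp, 2 %)), larger on 2 % agarose
   (max(20 bp, 5 %)); band patterns map to elite/other/unknown calls.
5. **Synthetic panels** (`synthetic_data`) — a generator plants verified
   haplotype structure (functional and silent variants, elite-private
   alleles, rare novel haplotypes, engineered restriction-site contexts)
   so every stage is testable without any external download, including
   five panels mirroring the structure of the published five-gene rice
   salt-tolerance marker set (11 markers: 3+1+3+1+3).

The package ships a replica of the published marker table (primers, band
notation such as `423/(202, 221)` and `(-17)/179`, enzymes) and the
published elite-haplotype definitions as bundled TSV fixtures.

## Worked example

Simulate a 30-accession panel with two extra haplotype groups, an elite
group carrying two private missense variants plus a 17-bp promoter
deletion, and one rare novel haplotype; then run the pipeline from
sequences:

```
$ printf 'n_accessions: 30\nn_functional_variants: 2\nn_silent_variants: 3\nindel_sizes: [17]\nrare_haplotype_sizes: [4]\n' > cfg.yml
$ haplomarker simulate --config cfg.yml --seed 11 --out fx
panel of 30 accessions, 9 variants -> fx
$ haplomarker extract --genome fx/reference.fa --gff fx/gene.gff3 --gene SYN00011 --out region.fa
wrote 4500 bp region for SYN00011 to region.fa
$ haplomarker callvars --gene-region region.fa --panel fx/panel.fa --gff fx/gene.gff3 --gene SYN00011 --out vars.tsv
9 variants across 30 accessions -> vars.tsv
$ haplomarker haplotypes --variants vars.tsv --meta fx/panel_meta.tsv --reference ACC0001 --out-prefix hap
4 haplotype groups, 8 haplotypes, 0 unassigned
$ haplomarker unique --variants vars.tsv --meta fx/panel_meta.tsv --reference ACC0001 --targets HapB
SYN00011_0002   -954    5'UTR   noncoding       allele=-
SYN00011_0004   +236    exon 1  missense        allele=C
SYN00011_0005   +658    exon 2  missense        allele=A
# 3 unique variant(s)
```

The nine called variants partition the panel into four haplotype groups
(HapA is the reference accession's group; the four members of the rare
novel haplotype were folded into their group here because all accessions
count as sequenced in this run). Group HapB turns out to carry three
private alleles — the planted 17-bp promoter deletion at −954 and the two
planted missense variants — and each of those supports a marker: the
deletion an Indel marker, the SNPs a CAPS or dCAPS assay.

Designing a marker from the library (here on the panel mimicking the
polyamine-oxidase gene, whose elite group has exactly two private variants,
only one of them exonic):

```python
>>> from haplomarker import paper_mimic_suite
>>> from haplomarker.pipeline import design_markers_for_panel
>>> from haplomarker.marker_design import markers_to_frame
>>> suite = paper_mimic_suite()
>>> print(markers_to_frame(design_markers_for_panel(suite["OsPAO3-like"])))
    gene variation_position variation_id marker_type  marker_name           primer_f               primer_r reference_size restriction_enzyme haplotypes
PAO3like               +662           m2       dCAPS PAO3like_E9d TGCCGGCGCTATGGAaTT GTCAATGCTGTAATGTCATTAC   100/(14, 86)             EcoR I       HapB
```

The lowercase `a` is the designed mismatch: it converts the non-elite
allele's amplicon into an EcoR I substrate, so non-elite accessions show
two fragments (14 + 86 bp) and elite accessions one uncut 100-bp band.

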