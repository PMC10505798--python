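"""Two-tier haplotype classification, elite flagging and unique variants."""

import numpy as np
import pandas as pd
import pytest

from haplomarker import (classify_haplotypes, find_unique_variants,
                         mark_elite, subpop_distribution)
from haplomarker.errors import ClassificationError
from haplomarker.genomic_io import AccessionMeta, VariantRecord
from haplomarker.haplotyping import EliteDefinition


def make_variants(specs):
    """specs: list of (atg_pos, effect)."""
    out = []
    for i, (pos, effect) in enumerate(specs, 1):
        region = "exon 1" if effect != "noncoding" else "5'UTR"
        out.append(VariantRecord(f"v{i}", pos, 1000 + pos, "A", "C", "SNP",
                                 region, effect))
    return out


def geno_frame(rows, accs):
    return pd.DataFrame(rows, index=[f"v{i+1}" for i in range(len(rows))],
                        columns=accs, dtype="Int64")


def panel_for(accs, subpop="XI"):
    return [AccessionMeta(a, subpop) for a in accs]


class TestClassification:
    def test_monomorphic_panel_single_group(self):
        accs = ["NIP", "a2", "a3"]
        variants = []
        geno = pd.DataFrame(index=[], columns=accs, dtype="Int64")
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
        assert [g.name for g in a.groups] == ["HapA"]
        assert [h.name for h in a.groups[0].haplotypes] == ["HapA-1"]
        assert sorted(a.groups[0].members) == sorted(accs)

    def test_two_tier_partition(self):
        # one missense splitting 4/2, one synonymous splitting the 4 into 3/1
        accs = ["NIP", "a2", "a3", "a4", "b1", "b2"]
        variants = make_variants([(10, "missense"), (40, "synonymous")])
        geno = geno_frame([[0, 0, 0, 0, 1, 1],
                           [0, 0, 0, 1, 0, 0]], accs)
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
        assert [(g.name, g.size) for g in a.groups] == [("HapA", 4),
                                                        ("HapB", 2)]
        hapA = a.groups[0]
        assert [(h.name, h.size) for h in hapA.haplotypes] == [("HapA-1", 3),
                                                               ("HapA-2", 1)]

    def test_reference_group_named_first_even_if_small(self):
        accs = ["NIP", "b1", "b2", "b3"]
        variants = make_variants([(10, "missense")])
        geno = geno_frame([[0, 1, 1, 1]], accs)
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
        assert a.group_of("NIP") == "HapA"
        assert a.groups[1].size == 3

    def test_rare_novel_haplotype_dropped(self):
        accs = ["NIP", "a2", "a3"] + [f"n{i}" for i in range(4)]
        variants = make_variants([(10, "missense")])
        geno = geno_frame([[0, 0, 0, 1, 1, 1, 1]], accs)
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP",
                                sequenced_accessions=["NIP", "a2", "a3"],
                                min_novel_size=5)
        assert len(a.groups) == 1
        assert sorted(a.unassigned) == [f"n{i}" for i in range(4)]
        # at 5 members the novel haplotype is kept
        accs2 = accs + ["n4"]
        geno2 = geno_frame([[0, 0, 0, 1, 1, 1, 1, 1]], accs2)
        a2 = classify_haplotypes(variants, geno2, panel_for(accs2), "NIP",
                                 sequenced_accessions=["NIP", "a2", "a3"],
                                 min_novel_size=5)
        assert len(a2.groups) == 2
        assert a2.groups[1].haplotypes[0].novel

    def test_missing_and_het_calls_excluded(self):
        accs = ["NIP", "a2", "miss"]
        variants = make_variants([(10, "missense")])
        geno = geno_frame([[0, 0, pd.NA]], accs)
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
        assert a.unassigned == ["miss"]

    def test_reference_missing_call_is_an_error(self):
        accs = ["NIP", "a2"]
        variants = make_variants([(10, "missense")])
        geno = geno_frame([[pd.NA, 0]], accs)
        with pytest.raises(ClassificationError, match="missing"):
            classify_haplotypes(variants, geno, panel_for(accs), "NIP")

    def test_partition_and_refinement_laws(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_acc, n_var = 18, 5
            accs = ["NIP"] + [f"a{i}" for i in range(n_acc - 1)]
            effects = [rng.choice(["missense", "synonymous", "noncoding"])
                       for _ in range(n_var)]
            variants = make_variants(
                [(10 + 20 * i, e) for i, e in enumerate(effects)])
            geno = geno_frame(rng.integers(0, 2, (n_var, n_acc)), accs)
            geno["NIP"] = 0
            a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
            # partition law
            all_members = [m for g in a.groups for h in g.haplotypes
                           for m in h.members]
            assert sorted(all_members + a.unassigned) == sorted(accs)
            assert len(set(all_members)) == len(all_members)
            for g in a.groups:
                assert sorted(g.members) == sorted(
                    m for h in g.haplotypes for m in h.members)
            # refinement law: same haplotype -> identical genotype column
            for g in a.groups:
                for h in g.haplotypes:
                    cols = geno[h.members]
                    assert (cols.nunique(axis=1) == 1).all()
                fidx = [i for i, v in enumerate(variants)
                        if v.effect == "missense"]
                cols = geno[g.members].iloc[fidx]
                if fidx:
                    assert (cols.nunique(axis=1) == 1).all()


class TestElite:
    def _assignment(self):
        accs = ["NIP", "a2", "k1", "k2", "g1"]
        variants = [
            VariantRecord("v1", 3474, 4474, "G", "T", "SNP", "exon 9",
                          "missense"),
            VariantRecord("v2", -500, 500, "A", "C", "SNP", "5'UTR",
                          "noncoding"),
        ]
        geno = geno_frame([[0, 0, 1, 1, 0],
                           [0, 0, 0, 0, 1]], accs)
        return classify_haplotypes(variants, geno, panel_for(accs), "NIP")

    def test_single_group_flagged(self):
        a = self._assignment()
        mark_elite(a, [EliteDefinition("g", {3474: "T"})])
        flags = {g.name: g.elite for g in a.groups}
        assert sum(flags.values()) == 1
        assert flags[a.group_of("k1")]

    def test_multiple_groups_may_be_elite(self):
        # definition on the REF allele of v1: both non-carrier groups qualify
        accs = ["NIP", "a2", "k1", "k2", "g1"]
        variants = [
            VariantRecord("v1", 100, 1100, "G", "T", "SNP", "exon 1",
                          "missense"),
            VariantRecord("v2", 200, 1200, "A", "C", "SNP", "exon 1",
                          "missense"),
        ]
        geno = geno_frame([[0, 0, 1, 1, 0],
                           [0, 0, 0, 0, 1]], accs)
        a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
        mark_elite(a, [EliteDefinition("g", {100: "REF"})])
        elite = {g.name for g in a.groups if g.elite}
        assert elite == {a.group_of("NIP"), a.group_of("g1")}

    def test_group_elite_requires_all_its_haplotypes(self):
        # v2 splits HapA into two haplotypes; only HapA-1 carries the
        # required reference allele, so the group itself is not flagged
        a = self._assignment()
        mark_elite(a, [EliteDefinition("g", {-500: "REF", 3474: "REF"})])
        assert not a.find(a.group_of("NIP")).elite
        assert a.haplotype_of("NIP") in a.elite_haplotypes
        assert a.haplotype_of("g1") not in a.elite_haplotypes

    def test_no_group_elite_warns(self):
        a = self._assignment()
        # no haplotype carries both the k-group allele and the g1 allele
        bogus = EliteDefinition("g", {3474: "T", -500: "C"})
        with pytest.warns(UserWarning, match="no haplotype"):
            mark_elite(a, [bogus])
        assert not any(g.elite for g in a.groups)

    def test_absent_position_is_an_error(self):
        a = self._assignment()
        with pytest.raises(ClassificationError, match=r"\+9999"):
            mark_elite(a, [EliteDefinition("g", {9999: "A"})])

    def test_alt_wildcard(self):
        a = self._assignment()
        mark_elite(a, [EliteDefinition("g", {3474: "ALT"})])
        assert any(g.elite for g in a.groups)


class TestUniqueVariants:
    def _setup(self, rows, accs):
        variants = make_variants([(10 * (i + 1),
                                   "missense" if i == 0 else "noncoding")
                                  for i in range(len(rows))])
        geno = geno_frame(rows, accs)
        return classify_haplotypes(variants, geno, panel_for(accs), "NIP")

    def test_private_allele_found(self):
        accs = ["NIP", "a2", "k1", "k2"]
        a = self._setup([[0, 0, 1, 1],      # group split
                         [0, 0, 1, 1],      # private to the k group
                         [0, 1, 0, 0]], accs)
        kgroup = a.group_of("k1")
        found = find_unique_variants(a, [kgroup])
        assert {(v.variant_id, al) for v, al in found} == {("v1", 1),
                                                           ("v2", 1)}

    def test_no_private_allele_empty(self):
        accs = ["NIP", "a2", "b1"]
        a = self._setup([[0, 1, 1],
                         [0, 1, 1]], accs)
        found = find_unique_variants(a, [a.group_of("NIP")])
        # the reference allele is private to NIP's group here
        assert {(v.variant_id, al) for v, al in found} == {("v1", 0),
                                                           ("v2", 0)}
        # but a group genotypically identical to another at all sites
        # yields nothing
        accs2 = ["NIP", "a2", "b1", "b2"]
        a2 = self._setup([[0, 0, 1, 1],
                          [0, 1, 0, 1]], accs2)
        silent_hap = a2.haplotype_of("a2")
        assert find_unique_variants(a2, [silent_hap]) == []

    def test_exclude_waives_rare_types(self):
        accs = ["NIP", "k1", "k2", "c1"]
        a = self._setup([[0, 1, 1, 0],
                         [0, 1, 1, 1]], accs)   # v2 shared with c1
        kgroup = a.group_of("k1")
        cgroup = a.group_of("c1")
        vids = {v.variant_id for v, _ in find_unique_variants(a, [kgroup])}
        assert vids == {"v1"}
        vids = {v.variant_id
                for v, _ in find_unique_variants(a, [kgroup], [cgroup])}
        assert vids == {"v1", "v2"}

    def test_target_exclude_overlap_errors(self):
        accs = ["NIP", "k1"]
        a = self._setup([[0, 1]], accs)
        g = a.group_of("k1")
        with pytest.raises(ClassificationError, match="overlap"):
            find_unique_variants(a, [g], [g])

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n_acc, n_var = 12, 4
            accs = ["NIP"] + [f"a{i}" for i in range(n_acc - 1)]
            variants = make_variants(
                [(10 + 15 * i, rng.choice(["missense", "noncoding"]))
                 for i in range(n_var)])
            geno = geno_frame(rng.integers(0, 2, (n_var, n_acc)), accs)
            geno["NIP"] = 0
            a = classify_haplotypes(variants, geno, panel_for(accs), "NIP")
            target = a.groups[-1].name
            tset = set(a.find(target).members)
            found = {(v.variant_id, al)
                     for v, al in find_unique_variants(a, [target])}
            brute = set()
            for v in variants:
                row = geno.loc[v.variant_id]
                for allele in (1, 0):
                    carriers = {c for c in accs if row[c] == allele}
                    if tset <= carriers and carriers <= tset:
                        brute.add((v.variant_id, allele))
                        break
            assert found == brute


class TestSubpopDistribution:
    def test_counts_and_row_sums(self):
        accs = ["NIP", "a2", "a3", "a4", "a5"]
        variants = make_variants([(10, "missense")])
        geno = geno_frame([[0, 0, 1, 1, 1]], accs)
        panel = [AccessionMeta("NIP", "GJ-tem"), AccessionMeta("a2", "GJ-tem"),
                 AccessionMeta("a3", "XI"), AccessionMeta("a4", "XI"),
                 AccessionMeta("a5", "aus")]
        a = classify_haplotypes(variants, geno, panel, "NIP")
        tab = subpop_distribution(a, panel)
        assert tab.loc["HapA-1", "GJ-tem"] == 2
        assert tab.loc["HapB-1", "XI"] == 2
        assert tab.loc["HapB-1", "aus"] == 1
        sizes = {h.name: h.size for g in a.groups for h in g.haplotypes}
        assert all(tab.loc[n].sum() == s for n, s in sizes.items())

    def test_empty_panel(self):
        a = classify_haplotypes([], pd.DataFrame(index=[], columns=["NIP"],
                                                 dtype="Int64"),
                                [AccessionMeta("NIP")], "NIP")
        tab = subpop_distribution(a, [AccessionMeta("NIP")])
        assert tab.loc["HapA-1", "other"] == 1
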