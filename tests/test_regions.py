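"""Region typing, Nei-Li diversity with substitution classes, methylation."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_nei_li
from splicerescue import simulate as sim
from splicerescue.annotation import SpliceJunction
from splicerescue.regions import (
    SUBSTITUTION_CLASSES,
    corrected_pi,
    methylation_by_region,
    nei_li_pi,
    type_regions,
)


class TestTypeRegions:
    def test_skipped_exon_labelled_whole(self, bc10_fx):
        m = bc10_fx.model
        j = SpliceJunction(m.chrom, m.introns[5][0], m.introns[6][1])
        regions = type_regions(m, [(j, "SE_single")])
        se = [r for r in regions if r.region_class == "SE"]
        assert [(r.start, r.end) for r in se] == [m.exons[6]]

    def test_a3s_splits_exon_into_a3s_and_ue(self, wda1_fx):
        m = wda1_fx.model
        s, e = m.introns[1]
        j = SpliceJunction(m.chrom, s, e + 9)
        regions = type_regions(m, [(j, "A3S")])
        a3s = [r for r in regions if r.region_class == "A3S"]
        assert [(r.start, r.end) for r in a3s] == [(e, e + 9)]
        ue = [r for r in regions if r.region_class == "UE"]
        assert [(r.start, r.end) for r in ue] == [(e + 9, m.exons[2][1])]

    def test_untouched_exons_are_ce(self, wda1_fx):
        m = wda1_fx.model
        s, e = m.introns[1]
        regions = type_regions(m, [(SpliceJunction(m.chrom, s, e + 9), "A3S")])
        ce = {r.interval for r in regions if r.region_class == "CE"}
        assert ce == {m.exons[0], m.exons[1], m.exons[3], m.exons[4]}

    def test_se_plus_a5e_partition(self, bc10_fx):
        """Hand-constructed partition for one skip and one 5' extension."""
        m = bc10_fx.model
        skip = SpliceJunction(m.chrom, m.introns[5][0], m.introns[6][1])
        s, e = m.introns[1]
        ext = SpliceJunction(m.chrom, s + 12, e)  # exon 2 extends 12 nt
        regions = type_regions(m, [(skip, "SE_single"), (ext, "A5E")])
        by_class = {}
        for r in regions:
            by_class.setdefault(r.region_class, []).append(r.interval)
        assert by_class["SE"] == [m.exons[6]]
        assert by_class["A5E"] == [(s, s + 12)]
        assert (s + 12, e) in by_class["UI"]
        # exons adjacent to the extension become UE, the rest CE
        assert m.exons[1] in by_class["UE"] or m.exons[2] in by_class["UE"]

    def test_exonic_bases_partition_exactly_once(self, bc10_fx):
        m = bc10_fx.model
        skip = SpliceJunction(m.chrom, m.introns[5][0], m.introns[6][1])
        s, e = m.introns[1]
        events = [(skip, "SE_single"),
                  (SpliceJunction(m.chrom, s, e + 9), "A3S")]
        regions = type_regions(m, events)
        exonic_classes = {"CE", "UE", "SE", "A5S", "A3S"}
        covered = []
        for r in regions:
            if r.region_class in exonic_classes:
                covered.extend(range(r.start, r.end))
        expected = []
        for es, ee in m.exons:
            expected.extend(range(es, ee))
        assert sorted(covered) == expected  # disjoint + complete


class TestNeiLi:
    def test_identical_haplotypes_zero(self):
        assert nei_li_pi(["ACGT" * 25] * 4) == 0.0

    def test_two_haplotypes_single_difference(self):
        """Frequencies .5/.5 and 1 diff in 100 sites: pi = 2*.5*.5*0.01."""
        anc = "C" + "A" * 99
        h1 = anc
        h2 = "A" + "A" * 99
        pi = nei_li_pi([h1, h2], [0.5, 0.5], substitution_class="C:G->A:T",
                       ancestral=anc)
        assert pi == pytest.approx(0.005)

    def test_three_haplotypes_match_brute_force(self):
        rng = np.random.default_rng(4)
        L = 200
        anc = "".join(rng.choice(list("ACGT"), L))
        haps = []
        for _ in range(3):
            h = list(anc)
            for i in rng.choice(L, 12, replace=False):
                h[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[h[i]]
            haps.append("".join(h))
        freqs = [0.5, 0.3, 0.2]
        assert nei_li_pi(haps, freqs) == pytest.approx(
            brute_nei_li(haps, freqs), abs=1e-15)

    def test_class_restricted_sums_to_total(self):
        """Per-class pi values sum to the unrestricted pi when every
        segregating site has one ancestral and one derived allele."""
        cfg = sim.SyntheticConfig(seed=6, group_size=8,
                                  panel_region_length=500,
                                  class_mutation_rate=0.01)
        panel = sim.simulate_haplotype_panel(cfg)
        seqs = panel.groups["group1"]
        total = nei_li_pi(seqs)
        by_class = sum(
            nei_li_pi(seqs, substitution_class=c, ancestral=panel.ancestral)
            for c in SUBSTITUTION_CLASSES
        )
        assert by_class == pytest.approx(total, abs=1e-12)

    def test_between_group_mode_matches_brute_force(self):
        rng = np.random.default_rng(8)
        L = 150
        anc = "".join(rng.choice(list("ACGT"), L))
        def mutate(k):
            h = list(anc)
            for i in rng.choice(L, k, replace=False):
                h[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[h[i]]
            return "".join(h)
        g1 = [mutate(5), mutate(8)]
        g2 = [mutate(3), mutate(6), mutate(9)]
        f1, f2 = [0.6, 0.4], [0.2, 0.5, 0.3]
        assert nei_li_pi(g1, f1, seqs2=g2, freqs2=f2) == pytest.approx(
            brute_nei_li(g1, f1, g2, f2), abs=1e-15)

    def test_uncovered_sites_excluded(self):
        h1, h2 = "ACGTN" + "A" * 5, "ACGTA" + "A" * 5
        # the N site is dropped entirely: no differences over 9 covered sites
        assert nei_li_pi([h1, h2]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nei_li_pi(["ACGT", "ACG"])


class TestCorrectedPi:
    def test_gc_correction(self):
        res = corrected_pi(0.004, "ACGT" * 25, "C:G->A:T")
        assert res.content == pytest.approx(0.5)
        assert res.pi_corrected == pytest.approx(0.008)

    def test_content_one_identity(self):
        res = corrected_pi(0.01, "GCGC" * 10, "C:G->T:A")
        assert res.pi_corrected == pytest.approx(0.01)

    def test_at_classes_use_at_content(self):
        res = corrected_pi(0.004, "AACG" * 10, "A:T->G:C")
        assert res.content == pytest.approx(0.5)

    def test_zero_content_flagged(self):
        res = corrected_pi(0.0, "AAAA", "C:G->A:T")
        assert res.pi_corrected is None
        assert "zero-content" in res.flags

    def test_uniform_rates_give_flat_corrected_pi(self):
        """Panels over GC-poor and GC-rich regions with equal per-site class
        rates have similar corrected pi (construction guarantee)."""
        rng = np.random.default_rng(10)
        L, n = 4000, 20
        values = []
        for gc in (0.3, 0.7):
            anc = "".join(
                rng.choice(list("GC"), ) if rng.random() < gc
                else rng.choice(list("AT"))
                for _ in range(L)
            )
            seqs = [list(anc) for _ in range(n)]
            # C:G->A:T mutations at rate r per eligible (G/C) site
            for i, b in enumerate(anc):
                if b in "GC" and rng.random() < 0.05:
                    m = int(rng.integers(1, n))
                    der = "A" if b == "C" else "T"
                    for c in rng.choice(n, m, replace=False):
                        seqs[c][i] = der
            haps = ["".join(s) for s in seqs]
            pi = nei_li_pi(haps, substitution_class="C:G->A:T", ancestral=anc)
            values.append(corrected_pi(pi, anc, "C:G->A:T").pi_corrected)
        lo, hi = sorted(values)
        assert hi / lo < 1.35  # flat up to sampling noise


class TestMethylation:
    def _region(self, bc10_fx):
        from splicerescue.regions import RegionAnnotation

        m = bc10_fx.model
        return RegionAnnotation(m.gene_id, m.chrom, 100, 200, "CE")

    def _calls(self, depths, meth_fraction, chrom, start=100, n=10):
        rows = []
        for i in range(n):
            d = depths[i % len(depths)]
            meth = int(round(d * meth_fraction))
            rows.append({
                "chrom": chrom, "pos": start + i * 5, "strand": "+",
                "context": "CpG", "count_methylated": meth,
                "count_unmethylated": d - meth,
            })
        return pd.DataFrame(rows)

    def test_low_depth_sites_drop_region(self, bc10_fx):
        region = self._region(bc10_fx)
        calls = self._calls([3], 0.5, region.chrom)
        out = methylation_by_region(calls, [region])
        level = out[(out.context == "CpG")].level.iloc[0]
        assert np.isnan(level)

    def test_low_coverage_region_discarded(self, bc10_fx):
        region = self._region(bc10_fx)
        # 6 of 10 sites covered (60% < 70%)
        calls = self._calls([10, 10, 10, 2, 2, 10, 10, 2, 10, 2], 0.5,
                            region.chrom)
        out = methylation_by_region(calls, [region])
        assert np.isnan(out[(out.context == "CpG")].level.iloc[0])

    def test_uniform_half_methylation(self, bc10_fx):
        region = self._region(bc10_fx)
        calls = self._calls([10], 0.5, region.chrom)
        out = methylation_by_region(calls, [region])
        assert out[(out.context == "CpG")].level.iloc[0] == pytest.approx(0.5)

    def test_multi_sample_average(self, bc10_fx):
        region = self._region(bc10_fx)
        s1 = self._calls([10], 0.2, region.chrom)
        s2 = self._calls([10], 0.6, region.chrom)
        out = methylation_by_region([s1, s2], [region])
        row = out[(out.context == "CpG")].iloc[0]
        assert row.level == pytest.approx(0.4)
        assert row.n_samples == 2
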