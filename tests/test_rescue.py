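"""The rescue caller: mature transcripts, ORF scans, verdicts, classifications."""

import numpy as np
import pytest

from conftest import make_toy_model
from oracles import naive_verdict
from splicerescue import simulate as sim
from splicerescue.annotation import SpliceJunction
from splicerescue.rescue import (
    IsoformModel,
    VariantSpec,
    build_mature_transcript,
    call_rescue,
    canonical_isoform,
    indel_distance_to_splice_site,
    scan_orf,
    single_novel_isoform,
)


class TestMatureTranscript:
    def test_canonical_chain_concatenates_exons(self):
        m = make_toy_model(["ATGAAC", "CCGTAA"], ["GT" + "A" * 70 + "AG"], utr5=0)
        mt = build_mature_transcript(m, canonical_isoform(m))
        assert mt.seq == "ATGAACCCGTAA"
        assert mt.coords == list(range(17, 23)) + list(range(97, 103))

    def test_deletion_shortens_by_one(self):
        m = make_toy_model(["ATGAAC", "CCGTAA"], ["GT" + "A" * 70 + "AG"], utr5=0)
        v = VariantSpec(m.chrom, 20, 1, 0)
        mt = build_mature_transcript(m, canonical_isoform(m), v)
        assert len(mt.seq) == 11
        assert mt.variant_retained
        assert mt.retained_variant_delta == -1

    def test_exon_skip_removes_exon_and_variant(self, bc10_fx):
        """Skipping exon 7 drops both the exon and a deletion inside it."""
        m = bc10_fx.model
        iso = bc10_fx.isoforms["skip7"]
        v = bc10_fx.variants["del22"]
        mt = build_mature_transcript(m, iso, v)
        chrom = m.chrom_seq()
        expected = "".join(
            chrom[s:e] for i, (s, e) in enumerate(m.exons) if i != 6
        )
        assert mt.seq == expected
        assert not mt.variant_retained
        assert mt.retained_variant_delta == 0
        assert "variant-not-retained" in mt.flags

    def test_boundary_spanning_deletion_partially_applied(self, wda1_fx):
        m = wda1_fx.model
        # deletion straddling the end of exon 2 into intron 2
        pos = m.exons[1][1] - 4
        v = VariantSpec(m.chrom, pos, 10, 0)
        mt = build_mature_transcript(m, canonical_isoform(m), v)
        assert "boundary-spanning" in mt.flags
        assert mt.retained_variant_delta == -4

    def test_minus_strand_transcript_matches_spliced_sequence(self, small_dataset):
        _, ds = small_dataset
        for m in ds.models:
            mt = build_mature_transcript(m, canonical_isoform(m))
            assert mt.seq == m.spliced_sequence()


class TestScanOrf:
    def test_canonical_stop_used(self):
        scan = scan_orf("ATGAAACCCTAA", 0, 9)
        assert scan.canonical_stop_used
        assert scan.ptc_status == "canonical"
        assert scan.first_stop_pos == 9

    def test_premature_stop(self):
        scan = scan_orf("ATGTAACCCTAA", 0, 9)
        assert not scan.canonical_stop_used
        assert scan.ptc_status == "premature"

    def test_posterior_stop(self):
        # frame shifted so the only in-frame stop lies past the canonical one
        scan = scan_orf("ATGAAACCACCCTAA", 0, 9)
        assert scan.ptc_status == "posterior_to_canonical"

    def test_non_stop_flagged(self):
        scan = scan_orf("ATGAAACCACCC", 0, 9)
        assert scan.ptc_status == "none"
        assert "non-stop" in scan.flags


class TestWda1LikeCalls:
    """A non-3n (-20 nt) junction rescues 3n+1 deletions but not the +1
    insertion; canonical splicing truncates every frameshifted allele."""

    def test_all_truth_verdicts(self, wda1_fx):
        for (vn, iname), expected in wda1_fx.truth.items():
            call = call_rescue(wda1_fx.model, wda1_fx.variants[vn],
                               wda1_fx.isoforms[iname])
            assert call.verdict == expected, (vn, iname)

    def test_rescue_net_delta(self, wda1_fx):
        call = call_rescue(wda1_fx.model, wda1_fx.variants["del1"],
                           wda1_fx.isoforms["B"])
        assert call.junction_delta == -20
        assert call.net_delta_mod3 == 0
        assert call.canonical_stop_used

    def test_insertion_not_rescued(self, wda1_fx):
        call = call_rescue(wda1_fx.model, wda1_fx.variants["ins1"],
                           wda1_fx.isoforms["B"])
        assert call.net_delta_mod3 != 0
        assert call.verdict == "no_rescue"

    def test_form_class_indel_retained_non3n(self, wda1_fx):
        call = call_rescue(wda1_fx.model, wda1_fx.variants["del4"],
                           wda1_fx.isoforms["B"])
        assert call.form_class == "A_non3n_other"
        assert call.variant_retained

    def test_ptc_mode_compensated_same_exon(self, wda1_fx):
        """Indel and its PTC share exon 3; the novel junction compensates
        the frame without excising the PTC bases (mode C)."""
        call = call_rescue(wda1_fx.model, wda1_fx.variants["del1"],
                           wda1_fx.isoforms["B"])
        assert call.ptc_mode == "C"


class TestBc10LikeCalls:
    def test_skip_rescues_all_deletions(self, bc10_fx):
        for vn in bc10_fx.variants:
            call = call_rescue(bc10_fx.model, bc10_fx.variants[vn],
                               bc10_fx.isoforms["skip7"])
            assert call.verdict == "rescue"
            assert call.form_class == "A1_3n_exon_skip"
            assert not call.variant_retained

    def test_canonical_chain_truncates(self, bc10_fx):
        for vn in bc10_fx.variants:
            call = call_rescue(bc10_fx.model, bc10_fx.variants[vn],
                               bc10_fx.isoforms["A"])
            assert call.verdict == "no_rescue"
            assert call.ptc_status == "premature"

    def test_ptc_mode_upstream_exon_skip(self, bc10_fx):
        """The PTC sits in exon 8; rescue skips exon 7, the exon before it
        (mode H: different exons, PTC retained, upstream skip)."""
        call = call_rescue(bc10_fx.model, bc10_fx.variants["del22"],
                           bc10_fx.isoforms["skip7"])
        assert call.ptc_mode == "H"


class TestNonsenseSnv:
    def test_snv_rescued_by_exon_skip(self, snv_fx):
        call = call_rescue(snv_fx.model, snv_fx.variants["ptc_snv"],
                           snv_fx.isoforms["skip3"])
        assert call.verdict == "rescue"
        assert call.ptc_mode == "A"

    def test_snv_not_applicable_without_ptc(self, snv_fx):
        """A synonymous-style SNV (no stop created) is not a rescue subject."""
        m = snv_fx.model
        v = snv_fx.variants["ptc_snv"]
        benign = VariantSpec(m.chrom, v.pos, 1, 1, "G", "snv")
        call = call_rescue(m, benign, snv_fx.isoforms["skip3"])
        assert call.verdict == "not_applicable"


def test_3n_deletion_not_applicable(wda1_fx):
    m = wda1_fx.model
    v = VariantSpec(m.chrom, wda1_fx.variants["del1"].pos, 3, 0)
    call = call_rescue(m, v, wda1_fx.isoforms["A"])
    assert call.verdict == "not_applicable"


def test_variant_outside_gene_not_applicable(wda1_fx):
    m = wda1_fx.model
    v = VariantSpec(m.chrom, m.span[1] + 50, 1, 0)
    call = call_rescue(m, v, wda1_fx.isoforms["A"])
    assert call.verdict == "not_applicable"
    assert "variant-outside-gene" in call.flags


class TestDistanceToSpliceSite:
    def test_bc10_distances(self, bc10_fx):
        m = bc10_fx.model
        assert indel_distance_to_splice_site(bc10_fx.variants["del5"], m) == 14
        assert indel_distance_to_splice_site(bc10_fx.variants["del22"], m) == 6

    def test_indel_abutting_exon_start(self, bc10_fx):
        m = bc10_fx.model
        v = VariantSpec(m.chrom, m.exons[6][0], 2, 0)
        assert indel_distance_to_splice_site(v, m) == 0

    def test_intronic_variant_raises(self, bc10_fx):
        m = bc10_fx.model
        v = VariantSpec(m.chrom, m.introns[0][0] + 5, 1, 0)
        with pytest.raises(ValueError):
            indel_distance_to_splice_site(v, m)


def _random_cases(seed, n_cases):
    """Randomized (model, variant, isoform) triples over synthetic genes."""
    cfg = sim.SyntheticConfig(seed=seed, n_genes=10,
                              intron_length_range=(67, 250),
                              exon_count_range=(3, 8),
                              indel_sizes=(-1, -2, -4, -22, +1, +2, -5, -7))
    ds = sim.generate_gene_models(cfg)
    models = {m.gene_id: m for m in ds.models}
    rng = np.random.default_rng(seed + 1)
    variants = dict(sim.inject_variants(ds.models, cfg, rng))
    catalogue = sim.generate_noisy_junctions(ds.models, cfg, rng,
                                             n_per_gene=max(4, n_cases // 10))
    cases = []
    for gene_id, j in catalogue:
        if gene_id not in variants:
            continue
        m = models[gene_id]
        cases.append((m, variants[gene_id], single_novel_isoform(m, j)))
        if len(cases) >= n_cases:
            break
    return cases


def test_verdict_matches_translation_oracle():
    """Modular-arithmetic verdicts equal brute-force translation verdicts
    over randomized synthetic triples."""
    cases = _random_cases(seed=23, n_cases=300)
    assert len(cases) >= 300
    for m, v, iso in cases:
        call = call_rescue(m, v, iso)
        if call.verdict == "not_applicable":
            continue
        assert call.verdict == naive_verdict(m, v, iso), (m.gene_id, v)


def test_phase_asymmetry_exact_on_tfree_gene():
    """On a stop-free CDS, a fixed non-3n donor-shift junction rescues
    exactly one of the two frameshift phases at a retained site."""
    ds = sim.tfree_gene(seed=2)
    m = ds.models[0]
    site = m.exons[3][0] + 30  # retained exon 4 site, downstream of junction
    for d in (1, 2, 4, 5, 7, 8, 10, 11):
        s, e = m.introns[1]
        j = SpliceJunction(m.chrom, s - d, e)  # removes d exonic nt
        iso = single_novel_isoform(m, j)
        verdicts = {}
        for phase, del_len in (("3n+1", 1), ("3n+2", 2)):
            v = VariantSpec(m.chrom, site, del_len, 0)
            verdicts[phase] = call_rescue(m, v, iso).verdict
        rescued = [p for p, verdict in verdicts.items() if verdict == "rescue"]
        expected = "3n+1" if (d + 1) % 3 == 0 else "3n+2"
        assert rescued == [expected], (d, verdicts)


def test_rescue_requires_canonical_stop(wda1_fx):
    """A chain that excises the canonical stop cannot rescue."""
    m = wda1_fx.model
    # junction excising the stop codon region in the last exon
    last = m.exons[-1]
    j = SpliceJunction(m.chrom, m.stop_codon_first_base - 40,
                       m.stop_codon_first_base + 40)
    iso = single_novel_isoform(m, j)
    # pick a deletion size making the net delta 0 mod 3
    net80 = (-80) % 3
    del_len = (3 - net80) % 3 or 3
    v = VariantSpec(m.chrom, wda1_fx.variants["del1"].pos, del_len + 3, 0)
    call = call_rescue(m, v, iso)
    assert not call.canonical_stop_used
    assert call.verdict in ("no_rescue", "not_applicable")


def test_rescue_report_round_trip(tmp_path, wda1_fx):
    from splicerescue.rescue import write_rescue_report
    import pandas as pd

    calls = [
        call_rescue(wda1_fx.model, wda1_fx.variants[vn], wda1_fx.isoforms[iname])
        for vn, iname in wda1_fx.truth
    ]
    path = tmp_path / "calls.tsv"
    write_rescue_report(calls, path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == len(calls)
    assert set(df["verdict"]) == {"rescue", "no_rescue"}
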