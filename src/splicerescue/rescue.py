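"""Frame-restoration ("rescue") calling.

The central question: given a gene, a frameshifting (non-3n) indel or a
nonsense SNV, and a candidate isoform (a chain of splice junctions), does the
isoform restore the annotated reading frame so that translation terminates at
the canonical stop codon, with no premature in-frame stop?

The verdict combines modular arithmetic -- the isoform's net exonic-length
change plus the retained portion of the variant must be congruent to 0 mod 3
-- with a codon scan of the mature transcript that the isoform actually
produces, to confirm that the first in-frame stop is the canonical one.
Rescue calls carry a four-way form class (3n vs non-3n junction chain,
crossed with whether the whole indel-bearing exon is skipped) and, when the
variant would create a premature termination codon (PTC) under canonical
splicing, an eight-way PTC mode describing how the isoform disposes of that
PTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .annotation import GeneModel, SpliceJunction, STOP_CODONS
from .catalog import (
    chain_exonic_intervals,
    chain_exonic_length,
    single_junction_chain,
    _overlaps,
    _subtract,
)

FORM_CLASSES = (
    "A1_3n_exon_skip", "A_3n_other", "A6_non3n_exon_skip", "A_non3n_other",
    "not_applicable",
)


@dataclass(frozen=True)
class VariantSpec:
    """A frameshifting indel or SNV.

    ``pos`` is the 0-based genomic start of the replaced reference stretch;
    ``ref_len`` bases starting there are replaced by ``alt_seq`` (plus-strand
    orientation, length ``alt_len``).  A pure deletion has ``alt_len = 0``, a
    pure insertion ``ref_len = 0`` (inserted before ``pos``).
    """

    chrom: str
    pos: int
    ref_len: int
    alt_len: int
    alt_seq: str = ""
    kind: str = "indel"  # "indel" or "snv"

    def __post_init__(self) -> None:
        if len(self.alt_seq) not in (0, self.alt_len):
            raise ValueError("alt_seq length disagrees with alt_len")
        if self.kind == "snv" and (self.ref_len != 1 or self.alt_len != 1):
            raise ValueError("snv must replace exactly one base")

    @property
    def delta_nt(self) -> int:
        return self.alt_len - self.ref_len

    @property
    def is_frameshift(self) -> bool:
        return self.kind == "indel" and self.delta_nt % 3 != 0

    @property
    def end(self) -> int:
        return self.pos + self.ref_len


@dataclass(frozen=True)
class IsoformModel:
    """A full isoform given as its ordered chain of excised introns."""

    gene_id: str
    junctions: tuple[SpliceJunction, ...]
    name: str = ""

    def __post_init__(self) -> None:
        ivs = sorted(j.interval for j in self.junctions)
        for a, b in zip(ivs, ivs[1:]):
            if b[0] < a[1]:
                raise ValueError(f"{self.gene_id}: overlapping junctions in chain")

    @property
    def intron_chain(self) -> list[tuple[int, int]]:
        return sorted(j.interval for j in self.junctions)


def canonical_isoform(model: GeneModel) -> IsoformModel:
    return IsoformModel(
        model.gene_id,
        tuple(SpliceJunction(model.chrom, s, e, model.strand)
              for s, e in model.introns),
        name="canonical",
    )


def single_novel_isoform(model: GeneModel, j: SpliceJunction) -> IsoformModel:
    """All-canonical chain except one novel junction replacing whatever
    canonical introns it overlaps."""
    chain = single_junction_chain(model, j)
    return IsoformModel(
        model.gene_id,
        tuple(SpliceJunction(model.chrom, s, e, model.strand) for s, e in chain),
        name="single-novel",
    )


@dataclass
class MatureTranscript:
    """A spliced transcript with a per-base transcript->genome map.

    ``coords[i]`` is the plus-strand genomic coordinate of transcript base
    ``i`` (transcript orientation), or -1 for bases inserted by a variant.
    """

    seq: str
    coords: list[int]
    strand: str
    flags: tuple[str, ...]
    variant_retained: bool
    retained_variant_delta: int
    cds_start_tx: int | None
    canonical_stop_tx: int | None
    canonical_stop_excised: bool

    def tx_index_of(self, genomic_pos: int) -> int | None:
        try:
            return self.coords.index(genomic_pos)
        except ValueError:
            return None


def build_mature_transcript(model: GeneModel, isoform: IsoformModel,
                            variant: VariantSpec | None = None) -> MatureTranscript:
    """Splice the genome per ``isoform`` and apply ``variant`` where retained.

    The variant's deletion applies only to bases that survive splicing; its
    inserted sequence is applied when the replacement anchor position is
    itself retained.  A deletion straddling an exon/intron boundary of the
    isoform is flagged "boundary-spanning" and applied to the retained bases
    only.
    """
    flags: list[str] = []
    chrom_seq = model.chrom_seq()
    exonic = chain_exonic_intervals(model, isoform.intron_chain)
    bases: list[str] = []
    coords: list[int] = []
    for s, e in exonic:
        bases.extend(chrom_seq[s:e])
        coords.extend(range(s, e))

    retained = True if variant is None else False
    retained_delta = 0
    if variant is not None:
        if variant.kind == "snv":
            idx = _index_of(coords, variant.pos)
            if idx is not None:
                bases[idx] = variant.alt_seq or bases[idx]
                retained = True
            else:
                flags.append("variant-not-retained")
        else:
            lo = _bisect(coords, variant.pos)
            hi = _bisect(coords, variant.end)
            n_del_exonic = hi - lo
            anchor_retained = (
                _index_of(coords, variant.pos) is not None
                if variant.ref_len > 0
                else _index_of(coords, variant.pos) is not None
            )
            apply_alt = False
            if variant.ref_len > 0:
                if n_del_exonic > 0:
                    retained = True
                    apply_alt = variant.alt_len > 0
                    if n_del_exonic < variant.ref_len:
                        flags.append("boundary-spanning")
                else:
                    flags.append("variant-not-retained")
            else:  # pure insertion before pos
                if anchor_retained:
                    retained = True
                    apply_alt = variant.alt_len > 0
                else:
                    flags.append("variant-not-retained")
            if retained:
                alt = list(variant.alt_seq) if apply_alt else []
                bases[lo:hi] = alt
                coords[lo:hi] = [-1] * len(alt)
                retained_delta = len(alt) - n_del_exonic

    seq = "".join(bases)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        coords = coords[::-1]

    cds_start_tx = _index_of(coords, model.start_codon_first_base)
    if cds_start_tx is None:
        flags.append("start-lost")
    stop_first = model.stop_codon_first_base
    canonical_stop_tx = _index_of(coords, stop_first)
    excised = canonical_stop_tx is None
    if excised:
        flags.append("canonical-stop-excised")
        canonical_stop_tx = _insertion_index(coords, stop_first, model.strand)
    return MatureTranscript(
        seq, coords, model.strand, tuple(flags), retained, retained_delta,
        cds_start_tx, canonical_stop_tx, excised,
    )


def _index_of(coords: list[int], pos: int) -> int | None:
    try:
        return coords.index(pos)
    except ValueError:
        return None


def _bisect(coords: list[int], pos: int) -> int:
    """First index whose genomic coordinate is >= pos, over the plus-strand
    ordered portion of ``coords`` (called before any strand flip; inserted
    bases carry -1 and sort low, which is harmless for disjoint ranges)."""
    import bisect as _b

    return _b.bisect_left(coords, pos)


def _insertion_index(coords: list[int], pos: int, strand: str) -> int:
    """Transcript index where ``pos`` would fall if it had been retained."""
    retained = [(c, i) for i, c in enumerate(coords) if c >= 0]
    if strand == "+":
        for c, i in retained:
            if c >= pos:
                return i
    else:
        for c, i in retained:
            if c <= pos:
                return i
    return len(coords)


@dataclass(frozen=True)
class OrfScan:
    first_stop_pos: int | None
    canonical_stop_used: bool
    ptc_status: str  # "none", "premature", "posterior_to_canonical", "canonical"
    flags: tuple[str, ...] = ()


def scan_orf(transcript: str, cds_start_tx: int,
             canonical_stop_tx: int | None,
             canonical_stop_present: bool = True) -> OrfScan:
    """Codon-by-codon scan from the annotated start.

    The first in-frame stop is compared against the (mapped) canonical stop
    position.  With no in-frame stop before the transcript end the scan is
    flagged "non-stop".
    """
    first_stop = None
    for i in range(cds_start_tx, len(transcript) - 2, 3):
        if transcript[i : i + 3].upper() in STOP_CODONS:
            first_stop = i
            break
    if first_stop is None:
        return OrfScan(None, False, "none", ("non-stop",))
    if canonical_stop_tx is None:
        return OrfScan(first_stop, False, "premature", ("no-canonical-stop",))
    used = canonical_stop_present and first_stop == canonical_stop_tx
    if used:
        status = "canonical"
    elif first_stop < canonical_stop_tx:
        status = "premature"
    else:
        status = "posterior_to_canonical"
    return OrfScan(first_stop, used, status)


@dataclass
class RescueCall:
    """The verdict of the frame-restoration algorithm for one
    (variant, isoform) pair."""

    variant: VariantSpec
    isoform: IsoformModel
    junction_delta: int
    variant_retained: bool
    net_delta_mod3: int
    canonical_stop_used: bool
    first_stop_pos: int | None
    ptc_status: str
    verdict: str  # "rescue", "no_rescue", "not_applicable"
    form_class: str = "not_applicable"
    ptc_mode: str = "not_applicable"
    indel_to_splice_site_bp: int | None = None
    flags: tuple[str, ...] = ()


def call_rescue(model: GeneModel, variant: VariantSpec,
                isoform: IsoformModel) -> RescueCall:
    """Decide whether ``isoform`` rescues ``variant`` on ``model``.

    Rescue requires: net frame change (junction chain + retained variant)
    congruent 0 mod 3, the canonical stop codon used, and no premature stop.
    3n indels and non-PTC SNVs are labelled not_applicable.  For a nonsense
    SNV the PTC base must be excised (otherwise the scan finds it).
    """
    if not model.coding:
        raise ValueError(f"{model.gene_id} is non-coding")
    span = model.span
    if variant.end < span[0] or variant.pos >= span[1]:
        return RescueCall(
            variant, isoform, 0, False, variant.delta_nt % 3, False, None,
            "none", "not_applicable", flags=("variant-outside-gene",),
        )

    canonical_chain = list(model.introns)
    canonical_mt = build_mature_transcript(model, canonical_isoform(model), variant)
    canonical_scan = _scan(canonical_mt)

    applicable = variant.is_frameshift or (
        variant.kind == "snv" and canonical_scan.ptc_status == "premature"
    )

    junction_delta = (
        chain_exonic_length(model, isoform.intron_chain)
        - chain_exonic_length(model, canonical_chain)
    )
    mt = build_mature_transcript(model, isoform, variant)
    scan = _scan(mt)
    net = junction_delta + mt.retained_variant_delta
    net_mod3 = net % 3

    try:
        dist = indel_distance_to_splice_site(variant, model)
    except ValueError:
        dist = None

    if not applicable:
        return RescueCall(
            variant, isoform, junction_delta, mt.variant_retained, net_mod3,
            scan.canonical_stop_used, scan.first_stop_pos, scan.ptc_status,
            "not_applicable", indel_to_splice_site_bp=dist,
            flags=mt.flags + scan.flags,
        )

    rescue = (
        net_mod3 == 0
        and scan.canonical_stop_used
        and scan.ptc_status != "premature"
    )
    verdict = "rescue" if rescue else "no_rescue"
    call = RescueCall(
        variant, isoform, junction_delta, mt.variant_retained, net_mod3,
        scan.canonical_stop_used, scan.first_stop_pos, scan.ptc_status,
        verdict, indel_to_splice_site_bp=dist, flags=mt.flags + scan.flags,
    )
    if rescue:
        call.form_class = classify_form(call, model)
        if canonical_scan.ptc_status == "premature":
            call.ptc_mode = classify_ptc_mode(call, model, canonical_mt,
                                              canonical_scan)
        elif canonical_scan.ptc_status == "posterior_to_canonical":
            call.ptc_mode = "posterior_stop"
    return call


def _scan(mt: MatureTranscript) -> OrfScan:
    if mt.cds_start_tx is None:
        return OrfScan(None, False, "none", ("start-lost",))
    return scan_orf(mt.seq, mt.cds_start_tx, mt.canonical_stop_tx,
                    canonical_stop_present=not mt.canonical_stop_excised)


def classify_form(call: RescueCall, model: GeneModel) -> str:
    """Four-way rescue form: (3n vs non-3n junction chain) x (whole
    indel-bearing annotated exon skipped vs not)."""
    if call.verdict != "rescue":
        return "not_applicable"
    chain_3n = call.junction_delta % 3 == 0
    exon_idx = model.exon_index_at(call.variant.pos)
    skipped = False
    if exon_idx is not None:
        exon = model.exons[exon_idx]
        skipped = any(
            s <= exon[0] and exon[1] <= e for s, e in call.isoform.intron_chain
        )
    if chain_3n:
        return "A1_3n_exon_skip" if skipped else "A_3n_other"
    return "A6_non3n_exon_skip" if skipped else "A_non3n_other"


def classify_ptc_mode(call: RescueCall, model: GeneModel,
                      canonical_mt: MatureTranscript,
                      canonical_scan: OrfScan) -> str:
    """Eight-way mode for a rescue of a variant that creates a PTC under
    canonical splicing.

    Letters A-D apply when indel and PTC share an annotated exon, E-H when
    they do not:

    * A/E -- PTC excluded by skipping the whole PTC-bearing exon
    * B/F -- PTC excluded by a junction without whole-exon skipping
    * C/G -- PTC retained; frame compensated by novel junction(s)
    * D/H -- PTC retained; compensation involves skipping an exon 5' of it
    """
    if canonical_scan.first_stop_pos is None:
        return "not_applicable"
    i = canonical_scan.first_stop_pos
    ptc_coords = [
        c for c in canonical_mt.coords[i : i + 3] if c >= 0
    ]
    indel_exon = model.exon_index_at(call.variant.pos)
    ptc_exon = model.exon_index_at(ptc_coords[0]) if ptc_coords else indel_exon
    same_exon = indel_exon is not None and ptc_exon == indel_exon

    chain = call.isoform.intron_chain
    excluded = any(
        any(s <= c < e for s, e in chain) for c in ptc_coords
    ) or not ptc_coords
    whole_exon_skipped = False
    if ptc_exon is not None:
        ex = model.exons[ptc_exon]
        whole_exon_skipped = any(s <= ex[0] and ex[1] <= e for s, e in chain)

    if excluded:
        letter = "A" if whole_exon_skipped else "B"
    else:
        # PTC bases survive in the transcript but are never read in frame.
        upstream_skip = False
        if ptc_coords:
            ref = ptc_coords[0]
            for idx, (s, e) in enumerate(model.exons):
                if model.strand == "+" and e <= ref or \
                   model.strand == "-" and s > ref:
                    if any(cs <= s and e <= ce for cs, ce in chain):
                        upstream_skip = True
                        break
        letter = "D" if upstream_skip else "C"
    if not same_exon:
        letter = {"A": "E", "B": "F", "C": "G", "D": "H"}[letter]
    return letter


def indel_distance_to_splice_site(variant: VariantSpec,
                                  model: GeneModel) -> int:
    """Minimum distance (bp) from either indel boundary to the nearest end of
    its annotated exon.  Ties resolve to the 5' boundary (same value)."""
    exon_idx = model.exon_index_at(variant.pos)
    if exon_idx is None:
        raise ValueError("variant is not exonic")
    s, e = model.exons[exon_idx]
    d_left = variant.pos - s
    d_right = e - variant.end
    if model.strand == "+":
        d5, d3 = d_left, d_right
    else:
        d5, d3 = d_right, d_left
    return min(d5, d3)


# ---------------------------------------------------------------------------
# VCF input and report output
# ---------------------------------------------------------------------------

def read_variants(path) -> list[VariantSpec]:
    """Read indels/SNVs from a (plain-text, single-sample) VCF via pysam.

    VCF indel records use an anchor base; it is stripped when REF and ALT
    share their first base, so a VCF deletion ``pos=10 REF=AT ALT=A`` becomes
    ``VariantSpec(pos=10, ref_len=1, alt_len=0)`` in 0-based coordinates.
    Only the first ALT allele of each record is used.
    """
    import pysam

    out: list[VariantSpec] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else ""
            pos = rec.pos - 1
            if ref and alt and ref[0] == alt[0] and \
                    (len(ref) > 1 or len(alt) > 1):
                pos += 1
                ref, alt = ref[1:], alt[1:]
            kind = "snv" if len(ref) == 1 and len(alt) == 1 else "indel"
            out.append(VariantSpec(rec.chrom, pos, len(ref), len(alt), alt,
                                   kind))
    return out


RESCUE_REPORT_COLUMNS = [
    "gene_id", "chrom", "variant_pos", "variant_delta", "variant_kind",
    "isoform", "junction_delta", "variant_retained", "net_delta_mod3",
    "canonical_stop_used", "first_stop_pos", "ptc_status", "verdict",
    "form_class", "ptc_mode", "indel_to_splice_site_bp", "flags",
]


def write_rescue_report(calls, target) -> None:
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({
            "gene_id": c.isoform.gene_id,
            "chrom": c.variant.chrom,
            "variant_pos": c.variant.pos,
            "variant_delta": c.variant.delta_nt,
            "variant_kind": c.variant.kind,
            "isoform": c.isoform.name or "chain",
            "junction_delta": c.junction_delta,
            "variant_retained": c.variant_retained,
            "net_delta_mod3": c.net_delta_mod3,
            "canonical_stop_used": c.canonical_stop_used,
            "first_stop_pos": c.first_stop_pos,
            "ptc_status": c.ptc_status,
            "verdict": c.verdict,
            "form_class": c.form_class,
            "ptc_mode": c.ptc_mode,
            "indel_to_splice_site_bp": c.indel_to_splice_site_bp,
            "flags": ";".join(c.flags),
        })
    pd.DataFrame(rows, columns=RESCUE_REPORT_COLUMNS).to_csv(
        target, sep="\t", index=False
    )
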