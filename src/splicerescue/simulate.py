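"""Synthetic inputs with the statistical structure the analysis assumes.

Everything here is deterministic under a seed: gene models with in-frame
CDS, noisy non-canonical junction catalogues (uniform splice boundaries, so
two thirds of junctions break frame under the null), CRISPR-style indel
panels, multinomial junction read counts at chosen isoform proportions, and
aligned haplotype panels with controlled per-class diversity.

The engineered rescue fixtures exploit the fact that every stop codon (TAA,
TAG, TGA) starts with T: drawing a CDS stretch from the T-free alphabet
{A, C, G} guarantees no stop codon in *any* reading frame across that
stretch, so premature stops exist exactly where the builder plants them, at
a chosen codon phase.  Rescue truth labels for the fixtures are therefore
guaranteed by construction, not by running the caller.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotation import (
    GeneModel,
    SpliceJunction,
    write_fasta,
    write_gff3,
)
from .catalog import JunctionEvidence
from .regions import SUBSTITUTION_CLASSES, _CLASS_OF
from .rescue import IsoformModel, VariantSpec, single_novel_isoform

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
TFREE = tuple("ACG")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of every generator; same seed implies byte-identical outputs."""

    seed: int = 0
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (2, 11)
    exon_length_median: float = 150.0
    exon_length_sigma: float = 0.45
    min_exon_length: int = 30
    intron_length_range: tuple[int, int] = (67, 3608)
    utr5_length: int = 60
    utr3_length: int = 60
    spacer_length: int = 300
    chrom: str = "chr1"
    noisy_junctions_per_gene: int = 20
    read_depth: int = 10000
    isoform_proportions: tuple[float, ...] = (0.95, 0.05)
    indel_sizes: tuple[int, ...] = (-1, -4, -22, +1, -5, -3)
    n_groups: int = 3
    group_size: int = 20
    panel_region_length: int = 1000
    class_mutation_rate: float = 0.002

    def __post_init__(self) -> None:
        lo, hi = self.intron_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("bad intron length range")
        if abs(sum(self.isoform_proportions) - 1.0) > 1e-9:
            raise ValueError("isoform proportions must sum to 1")
        if self.exon_count_range[0] < 1:
            raise ValueError("need at least one exon")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    models: list[GeneModel]

    def fasta_text(self) -> str:
        buf = io.StringIO()
        write_fasta(self.genome, buf)
        return buf.getvalue()

    def gff3_text(self) -> str:
        buf = io.StringIO()
        write_gff3(self.models, buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in codons) + stop


def _random_bases(rng: np.random.Generator, n: int,
                  alphabet: Sequence[str] = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.choice(len(alphabet), size=n))


def _random_intron(rng: np.random.Generator, length: int) -> str:
    return "GT" + _random_bases(rng, length - 4) + "AG"


@dataclass
class _GeneLayout:
    """Transcript-oriented parts of one gene before genomic placement."""

    exon_seqs: list[str]
    intron_seqs: list[str]
    cds_start_tx: int  # exonic (spliced) coordinate of the start codon
    cds_len: int


def _assemble(layout: _GeneLayout, gene_id: str, chrom: str, strand: str,
              offset: int, genome_parts: list[str],
              genome: Mapping[str, str]) -> tuple[GeneModel, int]:
    """Place a transcript-oriented layout on the plus strand at ``offset``."""
    blocks: list[tuple[str, str]] = []
    for i, ex in enumerate(layout.exon_seqs):
        blocks.append(("exon", ex))
        if i < len(layout.intron_seqs):
            blocks.append(("intron", layout.intron_seqs[i]))
    gene_seq = "".join(seq for _, seq in blocks)
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        gene_seq = gene_seq.translate(comp)[::-1]
        blocks = [(k, s.translate(comp)[::-1]) for k, s in reversed(blocks)]
    genome_parts.append(gene_seq)

    exons = []
    pos = offset
    for kind, seq in blocks:
        if kind == "exon":
            exons.append((pos, pos + len(seq)))
        pos += len(seq)
    exons.sort()

    # map spliced tx coordinate -> genomic
    def tx2gen(t: int) -> int:
        walk = exons if strand == "+" else list(reversed(exons))
        for s, e in walk:
            n = e - s
            if t < n:
                return s + t if strand == "+" else e - 1 - t
            t -= n
        raise IndexError(t)

    g1 = tx2gen(layout.cds_start_tx)
    g2 = tx2gen(layout.cds_start_tx + layout.cds_len - 1)
    cds_start, cds_end = min(g1, g2), max(g1, g2) + 1
    model = GeneModel(gene_id, chrom, strand, tuple(exons), cds_start,
                      cds_end, genome)
    return model, offset + len(gene_seq)


def generate_gene_models(cfg: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Random multi-exon coding genes on one synthetic chromosome.

    Exon lengths are lognormal around the configured median, introns uniform
    within the configured bounds, CDS built from sense codons with a single
    terminal stop; both strands are used.
    """
    rng = cfg.rng() if rng is None else rng
    genome: dict[str, str] = {}
    parts: list[str] = []
    models: list[GeneModel] = []
    offset = 0
    lo, hi = cfg.intron_length_range
    for g in range(cfg.n_genes):
        spacer = _random_bases(rng, cfg.spacer_length)
        parts.append(spacer)
        offset += len(spacer)
        n_exons = int(rng.integers(cfg.exon_count_range[0],
                                   cfg.exon_count_range[1] + 1))
        lengths = [
            max(cfg.min_exon_length,
                int(round(rng.lognormal(np.log(cfg.exon_length_median),
                                        cfg.exon_length_sigma))))
            for _ in range(n_exons)
        ]
        total = sum(lengths)
        utr5 = min(cfg.utr5_length, lengths[0] - 3)
        utr3 = min(cfg.utr3_length, lengths[-1] - 3)
        cds_len = total - utr5 - utr3
        utr3 += cds_len % 3
        cds_len -= cds_len % 3
        cds = _random_cds(rng, cds_len // 3)
        tx = _random_bases(rng, utr5) + cds + _random_bases(rng, utr3)
        exon_seqs, at = [], 0
        for L in lengths:
            exon_seqs.append(tx[at : at + L])
            at += L
        introns = [
            _random_intron(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(n_exons - 1)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        layout = _GeneLayout(exon_seqs, introns, utr5, cds_len)
        model, offset = _assemble(layout, f"gene{g + 1:03d}", cfg.chrom,
                                  strand, offset, parts, genome)
        models.append(model)
    tail = _random_bases(rng, cfg.spacer_length)
    parts.append(tail)
    genome[cfg.chrom] = "".join(parts)
    return SyntheticDataset(genome, models)


# ---------------------------------------------------------------------------
# engineered rescue fixtures
# ---------------------------------------------------------------------------

def _tfree_cds(rng: np.random.Generator, n: int) -> list[str]:
    """ATG + T-free interior + TAA; interior has no stop in any frame."""
    if n % 3:
        raise ValueError("CDS length must be 3n")
    interior = list(_random_bases(rng, n - 6, TFREE))
    # base right after ATG must not be A (ATG|A.. would give TGA at offset 1)
    if interior and interior[0] == "A":
        interior[0] = "C"
    return list("ATG") + interior + list("TAA")


def _plant_phase_stop(cds: list[str], at_or_after: int, phase: int) -> int:
    """Overwrite 'TAA' at the first CDS offset >= at_or_after with the given
    codon phase; the surrounding T-free context keeps frame 0 stop-free."""
    x = at_or_after
    while x % 3 != phase:
        x += 1
    cds[x : x + 3] = list("TAA")
    return x


@dataclass
class RescueFixture:
    """A gene plus variants, candidate isoforms and true verdicts."""

    dataset: SyntheticDataset
    model: GeneModel
    variants: dict[str, VariantSpec]
    isoforms: dict[str, IsoformModel]
    truth: dict[tuple[str, str], str]  # (variant, isoform) -> expected verdict


def _fixture_layout(exon_lengths: Sequence[int], utr5: int, utr3: int,
                    rng: np.random.Generator,
                    intron_length: int = 120) -> tuple[_GeneLayout, list[str], list[int]]:
    """T-free-CDS layout; returns (layout, mutable cds list, exon cds offsets).

    ``exon cds offsets[i]`` is the CDS coordinate of exon i's first base
    (negative inside the 5' UTR).
    """
    total = sum(exon_lengths)
    cds_len = total - utr5 - utr3
    cds = _tfree_cds(rng, cds_len)
    # T-free intron interiors: junctions retaining intronic tails cannot
    # introduce unplanned stop codons either
    introns = ["GT" + _random_bases(rng, intron_length - 4, TFREE) + "AG"
               for _ in range(len(exon_lengths) - 1)]
    offsets, at = [], 0
    for L in exon_lengths:
        offsets.append(at - utr5)
        at += L
    layout = _GeneLayout([""] * len(exon_lengths), introns, utr5, cds_len)
    return layout, cds, offsets


def _finish_fixture(layout: _GeneLayout, cds: list[str],
                    exon_lengths: Sequence[int], utr5: int, utr3: int,
                    rng: np.random.Generator, gene_id: str,
                    chrom: str) -> SyntheticDataset:
    tx = _random_bases(rng, utr5) + "".join(cds) + _random_bases(rng, utr3)
    at = 0
    for i, L in enumerate(exon_lengths):
        layout.exon_seqs[i] = tx[at : at + L]
        at += L
    genome: dict[str, str] = {}
    parts: list[str] = []
    lead = _random_bases(rng, 200)
    parts.append(lead)
    model, _ = _assemble(layout, gene_id, chrom, "+", len(lead), parts, genome)
    parts.append(_random_bases(rng, 200))
    genome[chrom] = "".join(parts)
    return SyntheticDataset(genome, [model])


def wda1_fixture(seed: int = 0) -> RescueFixture:
    """A five-exon gene with an alternative donor 20 nt inside exon 2.

    The -20 nt junction is non-3n; combined with any 3n+1 deletion in exon 3
    it restores frame and re-enables the canonical stop codon, while a +1
    insertion is not rescued.  Premature stops are planted downstream of
    the variant site at the two shifted codon phases so that canonical
    splicing of any frameshifted allele truncates.
    """
    rng = np.random.default_rng(seed)
    exon_lengths = [200, 180, 260, 150, 221]
    utr5, utr3 = 60, 60
    layout, cds, off = _fixture_layout(exon_lengths, utr5, utr3, rng)
    vpos_cds = off[2] + 60  # variant site: 60 nt into exon 3
    _plant_phase_stop(cds, vpos_cds + 40, phase=1)  # read when net shift is 3n+1 del
    _plant_phase_stop(cds, vpos_cds + 60, phase=2)  # read when net shift is +1 ins
    ds = _finish_fixture(layout, cds, exon_lengths, utr5, utr3, rng,
                         "WDA1like", "chrW")
    model = ds.models[0]
    i2s, i2e = model.introns[1]
    j_b = SpliceJunction(model.chrom, i2s - 20, i2e, "+")
    iso_b = single_novel_isoform(model, j_b)
    iso_b = IsoformModel(model.gene_id, iso_b.junctions, name="B")
    from .rescue import canonical_isoform

    iso_a = IsoformModel(model.gene_id, canonical_isoform(model).junctions,
                         name="A")
    vg = model.exons[2][0] + 60  # genomic variant position
    variants = {
        "del1": VariantSpec(model.chrom, vg, 1, 0),
        "del4": VariantSpec(model.chrom, vg, 4, 0),
        "del22": VariantSpec(model.chrom, vg, 22, 0),
        "ins1": VariantSpec(model.chrom, vg, 0, 1, "G"),
    }
    truth = {}
    for name in ("del1", "del4", "del22", "ins1"):
        truth[(name, "A")] = "no_rescue"
        truth[(name, "B")] = "rescue" if name != "ins1" else "no_rescue"
    return RescueFixture(ds, model, variants, {"A": iso_a, "B": iso_b}, truth)


def bc10_fixture(seed: int = 0) -> RescueFixture:
    """An eleven-exon gene whose 45 bp seventh exon carries the indels.

    Skipping exon 7 (a multiple of three long) excises any indel inside it
    and preserves frame, so the skip isoform rescues all three deletions;
    planted stops in exon 8 make canonical splicing of the frameshifted
    alleles truncate.
    """
    rng = np.random.default_rng(seed)
    exon_lengths = [160, 150, 140, 160, 150, 140, 45, 170, 150, 140, 182]
    utr5, utr3 = 60, 60
    layout, cds, off = _fixture_layout(exon_lengths, utr5, utr3, rng)
    _plant_phase_stop(cds, off[7] + 30, phase=1)
    _plant_phase_stop(cds, off[7] + 45, phase=2)
    ds = _finish_fixture(layout, cds, exon_lengths, utr5, utr3, rng,
                         "BC10like", "chrB")
    model = ds.models[0]
    e7 = model.exons[6]
    assert e7[1] - e7[0] == 45
    j_skip = SpliceJunction(model.chrom, model.introns[5][0],
                            model.introns[6][1], "+")
    iso_skip = IsoformModel(model.gene_id,
                            single_novel_isoform(model, j_skip).junctions,
                            name="skip7")
    from .rescue import canonical_isoform

    iso_a = IsoformModel(model.gene_id, canonical_isoform(model).junctions,
                         name="A")
    variants = {
        "del5": VariantSpec(model.chrom, e7[0] + 14, 5, 0),
        "del1": VariantSpec(model.chrom, e7[0] + 17, 1, 0),
        "del22": VariantSpec(model.chrom, e7[0] + 17, 22, 0),
    }
    truth = {}
    for name in variants:
        truth[(name, "A")] = "no_rescue"
        truth[(name, "skip7")] = "rescue"
    return RescueFixture(ds, model, variants,
                         {"A": iso_a, "skip7": iso_skip}, truth)


def tfree_gene(seed: int, exon_lengths: Sequence[int] | None = None,
               utr5: int = 60, utr3: int = 60) -> SyntheticDataset:
    """One plus-strand gene whose CDS interior is T-free (stop-free in every
    reading frame), with no planted stops.

    On such a gene any junction chain that keeps the start and canonical
    stop rescues a variant exactly when the net frame change is 0 mod 3,
    which makes frame-phase properties exactly testable.
    """
    rng = np.random.default_rng(seed)
    if exon_lengths is None:
        exon_lengths = [200, 180, 260, 150, 221]
    total = sum(exon_lengths)
    if (total - utr5 - utr3) % 3:
        raise ValueError("exon lengths minus UTRs must give a 3n CDS")
    layout, cds, _ = _fixture_layout(exon_lengths, utr5, utr3, rng)
    return _finish_fixture(layout, cds, exon_lengths, utr5, utr3, rng,
                           "TFREE", "chrF")


def nonsense_snv_fixture(seed: int = 0) -> RescueFixture:
    """A nonsense SNV inside a skippable 3n exon, rescued by exon skipping."""
    rng = np.random.default_rng(seed)
    exon_lengths = [180, 150, 120, 160, 200]
    utr5, utr3 = 60, 60
    layout, cds, off = _fixture_layout(exon_lengths, utr5, utr3, rng)
    # in-frame CAA codon 30 nt into exon 3; C->T makes it TAA
    x = off[2] + 30
    while x % 3:
        x += 1
    cds[x : x + 3] = list("CAA")
    ds = _finish_fixture(layout, cds, exon_lengths, utr5, utr3, rng,
                         "SNVlike", "chrS")
    model = ds.models[0]
    snv_g = model.exons[2][0] + (x - off[2])
    j_skip = SpliceJunction(model.chrom, model.introns[1][0],
                            model.introns[2][1], "+")
    iso_skip = IsoformModel(model.gene_id,
                            single_novel_isoform(model, j_skip).junctions,
                            name="skip3")
    from .rescue import canonical_isoform

    iso_a = IsoformModel(model.gene_id, canonical_isoform(model).junctions,
                         name="A")
    variants = {"ptc_snv": VariantSpec(model.chrom, snv_g, 1, 1, "T", "snv")}
    truth = {("ptc_snv", "A"): "no_rescue", ("ptc_snv", "skip3"): "rescue"}
    return RescueFixture(ds, model, variants,
                         {"A": iso_a, "skip3": iso_skip}, truth)


# ---------------------------------------------------------------------------
# noisy junctions and variants
# ---------------------------------------------------------------------------

def generate_noisy_junctions(
    models: Sequence[GeneModel],
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_per_gene: int | None = None,
) -> list[tuple[str, SpliceJunction]]:
    """Uniformly placed novel junctions within gene bodies.

    Donor and acceptor positions are uniform subject to the intron length
    bounds; under this null the structural frame delta is uniform mod 3, so
    an expected two thirds of the catalogue is non-3n.
    """
    rng = cfg.rng() if rng is None else rng
    n_per_gene = cfg.noisy_junctions_per_gene if n_per_gene is None else n_per_gene
    lo, hi = cfg.intron_length_range
    out: list[tuple[str, SpliceJunction]] = []
    canonical = {m.gene_id: set(m.introns) for m in models}
    for m in models:
        s, e = m.span
        made = 0
        while made < n_per_gene:
            start = int(rng.integers(s, e - lo))
            max_len = min(hi, e - start)
            if max_len < lo:
                continue
            length = int(rng.integers(lo, max_len + 1))
            iv = (start, start + length)
            if iv in canonical[m.gene_id]:
                continue
            out.append((m.gene_id,
                        SpliceJunction(m.chrom, iv[0], iv[1], m.strand)))
            made += 1
    return out


def inject_variants(
    models: Sequence[GeneModel],
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, VariantSpec]]:
    """One CRISPR-style variant per gene, cycling through the configured
    size mixture (negative = deletion, positive = insertion); positions are
    uniform over interior CDS codons."""
    rng = cfg.rng() if rng is None else rng
    out: list[tuple[str, VariantSpec]] = []
    for i, m in enumerate(models):
        size = cfg.indel_sizes[i % len(cfg.indel_sizes)]
        # pick an exonic CDS position away from start/stop codons
        candidates = []
        for s, e in m.exons:
            s2, e2 = max(s, m.cds_start + 6), min(e, m.cds_end - 6)
            if size < 0:
                e2 -= -size
            if s2 < e2:
                candidates.append((s2, e2))
        if not candidates:
            continue
        s2, e2 = candidates[int(rng.integers(len(candidates)))]
        pos = int(rng.integers(s2, e2))
        if size < 0:
            v = VariantSpec(m.chrom, pos, -size, 0)
        else:
            v = VariantSpec(m.chrom, pos, 0, size, _random_bases(rng, size))
        out.append((m.gene_id, v))
    return out


def apply_variants_to_genome(genome: Mapping[str, str],
                             variants: Sequence[VariantSpec]) -> dict[str, str]:
    """Mutated copy of the genome with all variants applied (right to left)."""
    out = {k: v for k, v in genome.items()}
    for v in sorted(variants, key=lambda v: -v.pos):
        s = out[v.chrom]
        out[v.chrom] = s[: v.pos] + (v.alt_seq or "") + s[v.end :]
    return out


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    junctions: Sequence[SpliceJunction],
    proportions: Sequence[float],
    depth: int,
    sample_id: str,
    condition: str,
    rng: np.random.Generator,
) -> list[JunctionEvidence]:
    """Multinomial junction reads for one junction region at given isoform
    proportions."""
    if len(junctions) != len(proportions):
        raise ValueError("one proportion per junction")
    if depth == 0:
        return []
    counts = rng.multinomial(depth, np.asarray(proportions, dtype=float))
    return [
        JunctionEvidence(j, sample_id, condition, int(c))
        for j, c in zip(junctions, counts)
    ]


# ---------------------------------------------------------------------------
# haplotype panels
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    ancestral: str
    groups: dict[str, list[str]]
    #: (group, substitution class) -> true within-group pi of the generated
    #: panel (from segregating-site derived-allele frequencies)
    true_pi: dict[tuple[str, str], float]

    def fasta_text(self) -> str:
        lines = [f">ancestral\n{self.ancestral}"]
        for g, seqs in self.groups.items():
            for i, s in enumerate(seqs, 1):
                lines.append(f">{g}_{i:02d}\n{s}")
        return "\n".join(lines) + "\n"

    def sidecar_text(self) -> str:
        lines = ["haplotype_id\tgroup\tfrequency\tancestral"]
        lines.append(f"ancestral\t-\t0\t1")
        for g, seqs in self.groups.items():
            for i in range(len(seqs)):
                lines.append(f"{g}_{i + 1:02d}\t{g}\t{1 / len(seqs):.6g}\t0")
        return "\n".join(lines) + "\n"


def simulate_haplotype_panel(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    rates: Mapping[str, float] | None = None,
) -> HaplotypePanel:
    """Groups x size aligned haplotypes over a random ancestral sequence.

    Each substitution class mutates eligible sites (ancestral base on the
    class's ancestral side) at the configured per-site rate; every
    segregating site carries one derived allele at a uniform carrier count,
    so the true per-class pi is sum over sites of 2 p (1 - p) / L.
    """
    rng = cfg.rng() if rng is None else rng
    L = cfg.panel_region_length
    rates = (
        {c: cfg.class_mutation_rate for c in SUBSTITUTION_CLASSES}
        if rates is None else dict(rates)
    )
    ancestral = _random_bases(rng, L)
    derived_of = {}
    for (anc, der), cls in _CLASS_OF.items():
        derived_of.setdefault(cls, {})[anc] = der
    groups: dict[str, list[str]] = {}
    true_pi: dict[tuple[str, str], float] = {}
    n = cfg.group_size
    for g in range(cfg.n_groups):
        name = f"group{g + 1}"
        seqs = [list(ancestral) for _ in range(n)]
        used: set[int] = set()
        for cls in SUBSTITUTION_CLASSES:
            pi = 0.0
            n_sites = rng.poisson(rates.get(cls, 0.0) * L)
            eligible = [
                i for i in range(L)
                if i not in used and ancestral[i] in derived_of[cls]
            ]
            take = min(int(n_sites), len(eligible))
            if take:
                for i in rng.choice(len(eligible), size=take, replace=False):
                    site = eligible[int(i)]
                    used.add(site)
                    m = int(rng.integers(1, n))
                    carriers = rng.choice(n, size=m, replace=False)
                    der = derived_of[cls][ancestral[site]]
                    for c in carriers:
                        seqs[int(c)][site] = der
                    p = m / n
                    pi += 2 * p * (1 - p) / L
            true_pi[(name, cls)] = pi
        groups[name] = ["".join(s) for s in seqs]
    return HaplotypePanel(ancestral, groups, true_pi)


# ---------------------------------------------------------------------------
# fixture directory writer
# ---------------------------------------------------------------------------

def write_fixture_dir(cfg: SyntheticConfig, outdir) -> None:
    """Write a full synthetic input set (FASTA, GFF3, junction table, VCF,
    haplotype panel) into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = cfg.rng()
    ds = generate_gene_models(cfg, rng)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        fh.write(ds.fasta_text())
    with open(os.path.join(outdir, "annotation.gff3"), "w") as fh:
        fh.write(ds.gff3_text())
    catalogue = generate_noisy_junctions(ds.models, cfg, rng)
    with open(os.path.join(outdir, "junctions.tsv"), "w") as fh:
        fh.write("chrom\tintron_start\tintron_end\tstrand\tsample_id\t"
                 "condition\tread_count\n")
        for gene_id, j in catalogue:
            fh.write(f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t"
                     f"{j.strand}\tS1\tWT\t1\n")
    variants = inject_variants(ds.models, cfg, rng)
    with open(os.path.join(outdir, "variants.vcf"), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for gene_id, v in variants:
            chrom_seq = ds.genome[v.chrom]
            anchor = chrom_seq[v.pos - 1]
            ref = anchor + chrom_seq[v.pos : v.end]
            alt = anchor + (v.alt_seq or "")
            fh.write(f"{v.chrom}\t{v.pos}\t{gene_id}\t{ref}\t{alt}\t.\t.\t.\n")
    panel = simulate_haplotype_panel(cfg, rng)
    with open(os.path.join(outdir, "panel.fa"), "w") as fh:
        fh.write(panel.fasta_text())
    with open(os.path.join(outdir, "panel_groups.tsv"), "w") as fh:
        fh.write(panel.sidecar_text())
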