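"""Gene models and canonical splice junctions.

A :class:`GeneModel` holds the exon/CDS structure of one representative
transcript of an annotated gene, together with an accessor to the chromosome
sequence.  All coordinates are 0-based, half-open, on the plus strand of the
genome; transcript-orientation views are derived on demand.  The canonical
splice junctions of a gene are simply its annotated introns.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

#: Intron length bounds used throughout (bp).  Junctions whose implied intron
#: falls outside these bounds are rejected by the validating constructors.
MIN_INTRON = 67
MAX_INTRON = 3608

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AnnotationError(ValueError):
    """Raised for malformed gene annotations."""


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """A donor-acceptor pair, stored as the excised intron interval.

    ``intron_start``/``intron_end`` delimit the removed intron, 0-based
    half-open on the plus strand regardless of gene strand.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise AnnotationError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                "intron_end must exceed intron_start"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.intron_start, self.intron_end)

    def within_length_bounds(self, min_intron: int = MIN_INTRON,
                             max_intron: int = MAX_INTRON) -> bool:
        return min_intron <= self.length <= max_intron


@dataclass
class GeneModel:
    """Exon/CDS structure of one representative transcript.

    ``exons`` are genomic intervals in ascending genomic order (use
    :attr:`exons_tx` for transcript 5'->3' order).  ``cds_start``/``cds_end``
    are the genomic left/right bounds of the coding span, half-open, so the
    start codon begins at ``cds_start`` on '+' genes and at ``cds_end - 1``
    (reading leftwards) on '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    genome: Mapping[str, str]
    coding: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        self.exons = exons
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise AnnotationError(f"{self.gene_id}: empty exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if self.coding:
            if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
                raise AnnotationError(f"{self.gene_id}: CDS outside exon span")

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exons_tx(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Annotated introns, ascending genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_index_at(self, pos: int) -> int | None:
        """Index (genomic order) of the exon containing ``pos``, else None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        return None

    def intron_index_at(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.introns):
            if s <= pos < e:
                return i
        return None

    # -- sequence -----------------------------------------------------------

    def chrom_seq(self) -> str:
        return str(self.genome[self.chrom])

    def spliced_sequence(self) -> str:
        """Mature (canonical) transcript sequence in transcript orientation."""
        chrom = self.chrom_seq()
        seq = "".join(chrom[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def spliced_cds(self) -> str:
        """Canonical CDS sequence (start codon through stop codon)."""
        if not self.coding:
            raise AnnotationError(f"{self.gene_id} is non-coding")
        chrom = self.chrom_seq()
        parts = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                parts.append(chrom[s2:e2])
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def protein(self) -> str:
        """Translate the canonical CDS (stop codon excluded)."""
        cds = self.spliced_cds()
        return str(Seq(cds[: len(cds) - len(cds) % 3]).translate()).rstrip("*")

    def validate(self) -> None:
        """Check the coding-gene invariants: 3n CDS ending in a single stop."""
        cds = self.spliced_cds()
        if len(cds) % 3:
            raise AnnotationError(f"{self.gene_id}: CDS length {len(cds)} not 3n")
        if cds[-3:] not in STOP_CODONS:
            raise AnnotationError(f"{self.gene_id}: CDS does not end in a stop")
        aa = str(Seq(cds).translate())
        if "*" in aa[:-1]:
            raise AnnotationError(f"{self.gene_id}: internal stop codon")

    # -- frame anchors (genomic positions of start / stop codons) -----------

    @property
    def start_codon_first_base(self) -> int:
        """Genomic coordinate of the first transcribed base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end - 1

    @property
    def stop_codon_first_base(self) -> int:
        """Genomic coordinate of the first transcribed base of the stop codon.

        Assumes the stop codon is contained within the terminal CDS exon,
        which holds for the models this package builds and loads.
        """
        return self.cds_end - 3 if self.strand == "+" else self.cds_start + 2


def enumerate_canonical_junctions(model: GeneModel) -> list[SpliceJunction]:
    """The annotated introns of ``model`` as splice junctions (n_exons - 1)."""
    return [
        SpliceJunction(model.chrom, s, e, model.strand) for s, e in model.introns
    ]


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(source) -> dict[str, str]:
    """Read a FASTA file (path or handle) into a chrom -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def write_fasta(genome: Mapping[str, str], handle) -> None:
    close = False
    if isinstance(handle, (str, os.PathLike)):
        handle = open(handle, "w")
        close = True
    try:
        for name in genome:
            handle.write(f">{name}\n")
            seq = str(genome[name])
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")
    finally:
        if close:
            handle.close()


def load_gene_models(annotation, genome: Mapping[str, str],
                     issues: list[str] | None = None) -> list[GeneModel]:
    """Parse a GFF3 annotation into one :class:`GeneModel` per gene.

    ``annotation`` may be a path or GFF3 text.  One representative transcript
    is kept per gene (the first mRNA); extra transcripts are skipped with a
    warning.  Genes without CDS features are flagged non-coding and excluded.
    Malformed genes (e.g. overlapping exons) are reported via ``issues`` /
    warnings rather than silently dropped.
    """
    if issues is None:
        issues = []
    text = annotation
    if isinstance(annotation, (str, os.PathLike)) and os.path.exists(str(annotation)):
        with open(annotation) as fh:
            text = fh.read()
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as tmp:
        tmp.write(text)
        tmp_path = tmp.name
    try:
        db = gffutils.create_db(
            tmp_path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        models: list[GeneModel] = []
        for gene in db.features_of_type("gene"):
            mrnas = list(db.children(gene, featuretype="mRNA"))
            if not mrnas:
                issues.append(f"{gene.id}: no mRNA feature")
                continue
            if len(mrnas) > 1:
                issues.append(
                    f"{gene.id}: {len(mrnas)} transcripts, keeping {mrnas[0].id}"
                )
            mrna = mrnas[0]
            # GFF3 is 1-based closed; convert to 0-based half-open.
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            if not exons:
                issues.append(f"{gene.id}: no exons, rejected")
                continue
            try:
                if not cds:
                    issues.append(f"{gene.id}: no CDS, flagged non-coding")
                    model = GeneModel(
                        gene.id, gene.seqid, gene.strand, tuple(exons),
                        exons[0][0], exons[0][0], genome, coding=False,
                        flags=("non-coding",),
                    )
                else:
                    model = GeneModel(
                        gene.id, gene.seqid, gene.strand, tuple(exons),
                        cds[0][0], cds[-1][1], genome,
                    )
                models.append(model)
            except AnnotationError as exc:
                issues.append(f"{gene.id}: rejected ({exc})")
        for msg in issues:
            warnings.warn(msg, stacklevel=2)
        return models
    finally:
        os.unlink(tmp_path)


def write_gff3(models: Iterable[GeneModel], handle) -> None:
    """Write gene models back to GFF3 (1-based closed coordinates)."""
    close = False
    if isinstance(handle, (str, os.PathLike)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            handle.write(
                f"{m.chrom}\tsplicerescue\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}.1"
            handle.write(
                f"{m.chrom}\tsplicerescue\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(m.exons, 1):
                handle.write(
                    f"{m.chrom}\tsplicerescue\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            if m.coding:
                for xs, xe in m.exons:
                    cs, ce = max(xs, m.cds_start), min(xe, m.cds_end)
                    if cs < ce:
                        handle.write(
                            f"{m.chrom}\tsplicerescue\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{m.strand}\t0\tParent={tid}\n"
                        )
    finally:
        if close:
            handle.close()


def write_junction_bed(junctions: Sequence[tuple[SpliceJunction, int]], handle) -> None:
    """Write (junction, count) pairs as 6-column BED."""
    close = False
    if isinstance(handle, (str, os.PathLike)):
        handle = open(handle, "w")
        close = True
    try:
        for i, (j, count) in enumerate(junctions, 1):
            handle.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\tJ{i}\t{count}\t{j.strand}\n"
            )
    finally:
        if close:
            handle.close()
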