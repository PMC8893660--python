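"""Classification of observed splice junctions against the annotation.

A junction is *canonical* when it coincides exactly with an annotated intron
and *non-canonical* otherwise.  Every non-canonical junction is assigned a
frame delta -- the change in mature-transcript exonic length it implies
relative to the canonical structure -- and an alternative-splicing event
label (exon skipping, 5'/3' extension or shortening, or "other").

The frame delta is computed structurally, by set arithmetic on the gene's
exonic bases, never by string alignment: replacing the canonical introns the
junction overlaps by the junction's own intron, and differencing exonic
lengths.  A delta that is not a multiple of three marks a *non-3n* junction,
one whose usage on its own would break the annotated reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel, SpliceJunction

AS_EVENTS = (
    "SE_single", "SE_multi", "A5E", "A5S", "A3E", "A3S", "MXE", "other",
)


@dataclass(frozen=True)
class JunctionEvidence:
    """Read support for one junction in one sample."""

    junction: SpliceJunction
    sample_id: str
    condition: str = "WT"  # "WT" or "mutant"
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass(frozen=True)
class FrameDelta:
    """Signed change in exonic length (nt) and the implied frame class."""

    delta_nt: int

    @property
    def frame_class(self) -> str:
        return "3n" if self.delta_nt % 3 == 0 else "non-3n"


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _subtract(interval: tuple[int, int],
              holes: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Subtract sorted, disjoint ``holes`` from ``interval``."""
    out = []
    cur = interval[0]
    for s, e in holes:
        s, e = max(s, interval[0]), min(e, interval[1])
        if e <= s:
            continue
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < interval[1]:
        out.append((cur, interval[1]))
    return out


def single_junction_chain(model: GeneModel,
                          j: SpliceJunction) -> list[tuple[int, int]]:
    """Intron chain of the isoform using ``j`` plus all compatible canonical
    introns (those not overlapping ``j``)."""
    chain = [iv for iv in model.introns if not _overlaps(iv, j.interval)]
    chain.append(j.interval)
    chain.sort()
    return chain


def chain_exonic_intervals(model: GeneModel,
                           chain: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Mature exonic intervals implied by an intron chain, clamped to the
    annotated gene span."""
    return _subtract(model.span, sorted(chain))


def chain_exonic_length(model: GeneModel, chain: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in chain_exonic_intervals(model, chain))


def classify_canonical(j: SpliceJunction,
                       model: GeneModel) -> tuple[str, tuple[str, ...]]:
    """Return ("canonical"|"non-canonical", flags).

    Canonical means exact coordinate identity with an annotated intron.  A
    junction not fully inside the gene span is non-canonical with an
    "intergenic-overlap" flag.
    """
    if j.chrom != model.chrom or j.strand != model.strand:
        raise ValueError("junction and model on different chrom/strand")
    flags: list[str] = []
    s, e = model.span
    if j.intron_start < s or j.intron_end > e:
        flags.append("intergenic-overlap")
    label = "canonical" if j.interval in model.introns else "non-canonical"
    return label, tuple(flags)


def junction_frame_delta(j: SpliceJunction, model: GeneModel) -> FrameDelta:
    """Structural frame delta of ``j`` relative to the canonical model.

    Equals -(canonical-exonic nt excised by j) + (canonical-intronic nt
    retained as exonic), obtained by differencing the exonic length of the
    single-novel-junction isoform against the canonical isoform.
    """
    canonical = chain_exonic_length(model, model.introns)
    with_j = chain_exonic_length(model, single_junction_chain(model, j))
    return FrameDelta(with_j - canonical)


def differential_node(j: SpliceJunction,
                      model: GeneModel) -> list[tuple[int, int]]:
    """Exonic segments whose inclusion differs between the canonical isoform
    and the isoform using ``j`` (the "differential exon node")."""
    canon = set()
    for s, e in chain_exonic_intervals(model, model.introns):
        canon.update(range(s, e))
    alt = set()
    for s, e in chain_exonic_intervals(model, single_junction_chain(model, j)):
        alt.update(range(s, e))
    diff = sorted(canon ^ alt)
    out: list[tuple[int, int]] = []
    for p in diff:
        if out and out[-1][1] == p:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def _position_kind(model: GeneModel, pos: int) -> tuple[str, int | None]:
    i = model.exon_index_at(pos)
    if i is not None:
        return "exon", i
    i = model.intron_index_at(pos)
    if i is not None:
        return "intron", i
    return "outside", None


def classify_as_event(j: SpliceJunction, model: GeneModel,
                      partner: SpliceJunction | None = None) -> str:
    """Assign one alternative-splicing event label to a non-canonical junction.

    A5*/A3* labels name the transcript side (5' = donor) that deviates from
    the annotated splice sites; E = exon extension into the intron, S = exon
    shortening.  SE requires both junction ends at annotated sites with whole
    annotated exon(s) inside.  MXE is only called for a pair of single-exon
    skips of distinct adjacent exons (``partner`` supplied).  Everything else,
    including junctions lying entirely within one exon or one intron, is
    "other".
    """
    label, _ = classify_canonical(j, model)
    if label == "canonical":
        raise ValueError("classify_as_event requires a non-canonical junction")

    introns = model.introns
    left_anchor = next(
        (i for i, iv in enumerate(introns) if iv[0] == j.intron_start), None
    )
    right_anchor = next(
        (i for i, iv in enumerate(introns) if iv[1] == j.intron_end), None
    )

    if partner is not None:
        mine = _skipped_exons(j, model)
        theirs = _skipped_exons(partner, model)
        if (
            mine is not None and theirs is not None
            and len(mine) == len(theirs) == 1
            and abs(mine[0] - theirs[0]) == 1
        ):
            return "MXE"

    if left_anchor is not None and right_anchor is not None:
        n_skipped = right_anchor - left_anchor
        if n_skipped == 1:
            return "SE_single"
        if n_skipped > 1:
            return "SE_multi"
        return "other"

    # helper mapping deviating genomic side -> transcript side label
    def side_label(genomic_side: str, mode: str) -> str:
        five_prime = (genomic_side == "left") == (model.strand == "+")
        return ("A5" if five_prime else "A3") + mode

    if left_anchor is not None:
        s, e = introns[left_anchor]
        kind, idx = _position_kind(model, j.intron_end - 1)
        if kind == "intron" and idx == left_anchor:
            return side_label("right", "E")
        if kind == "exon" and idx == left_anchor + 1:
            return side_label("right", "S")
        return "other"
    if right_anchor is not None:
        kind, idx = _position_kind(model, j.intron_start)
        if kind == "intron" and idx == right_anchor:
            return side_label("left", "E")
        if kind == "exon" and idx == right_anchor:
            return side_label("left", "S")
        return "other"
    return "other"


def _skipped_exons(j: SpliceJunction, model: GeneModel) -> list[int] | None:
    """Indices of annotated exons fully inside j's intron, if both j ends sit
    at annotated splice sites; else None."""
    starts = {iv[0] for iv in model.introns}
    ends = {iv[1] for iv in model.introns}
    if j.intron_start not in starts or j.intron_end not in ends:
        return None
    return [
        i for i, (s, e) in enumerate(model.exons)
        if j.intron_start <= s and e <= j.intron_end
    ]


def replication_filter(evidence: Iterable[JunctionEvidence],
                       k: int) -> set[SpliceJunction]:
    """Junctions observed (read_count > 0) in at least ``k`` distinct samples."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seen: dict[SpliceJunction, set[str]] = {}
    for ev in evidence:
        if ev.read_count > 0:
            seen.setdefault(ev.junction, set()).add(ev.sample_id)
    return {j for j, samples in seen.items() if len(samples) >= k}


# ---------------------------------------------------------------------------
# Junction-table I/O
# ---------------------------------------------------------------------------

JUNCTION_TABLE_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand",
    "sample_id", "condition", "read_count",
]


def read_junction_table(source) -> list[JunctionEvidence]:
    """Read a TSV junction table (see :data:`JUNCTION_TABLE_COLUMNS`)."""
    df = pd.read_csv(source, sep="\t")
    missing = set(JUNCTION_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table missing columns: {sorted(missing)}")
    return [
        JunctionEvidence(
            SpliceJunction(r.chrom, int(r.intron_start), int(r.intron_end),
                           r.strand),
            str(r.sample_id), str(r.condition), int(r.read_count),
        )
        for r in df.itertuples()
    ]


def write_junction_table(evidence: Iterable[JunctionEvidence], target) -> None:
    rows = [
        {
            "chrom": ev.junction.chrom,
            "intron_start": ev.junction.intron_start,
            "intron_end": ev.junction.intron_end,
            "strand": ev.junction.strand,
            "sample_id": ev.sample_id,
            "condition": ev.condition,
            "read_count": ev.read_count,
        }
        for ev in evidence
    ]
    pd.DataFrame(rows, columns=JUNCTION_TABLE_COLUMNS).to_csv(
        target, sep="\t", index=False
    )
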