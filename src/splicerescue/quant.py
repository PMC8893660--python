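"""Junction-level abundance statistics.

Relative level of a junction = its reads / "junction region depth", the
summed reads of all junctions whose introns overlap its own (itself
included).  R_mw is the ratio of a rescue junction's relative level in the
mutant to that in the wild type; when the junction is unseen in the wild
type (R_w = 0) but present in the mutant, R_mw is infinite.  PSI of a
junction is the inclusion proportion of the exonic segment whose presence
the junction toggles (its differential node), computed from junction reads
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import GeneModel, SpliceJunction
from .catalog import JunctionEvidence, differential_node

#: serialized form of the infinite R_mw sentinel
INF_LITERAL = "Inf"


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def junction_region_depth(j: SpliceJunction,
                          evidence: Sequence[JunctionEvidence]) -> int:
    """Summed reads of all junctions overlapping j's intron (j included).

    ``evidence`` should already be restricted to one sample and gene.
    """
    return sum(
        ev.read_count for ev in evidence
        if ev.junction.chrom == j.chrom
        and _overlaps(ev.junction.interval, j.interval)
    )


def relative_level(j: SpliceJunction,
                   evidence: Sequence[JunctionEvidence]) -> float | None:
    """Reads of j / junction region depth, or None when the region has no
    reads (undefined)."""
    depth = junction_region_depth(j, evidence)
    if depth == 0:
        return None
    reads = sum(
        ev.read_count for ev in evidence if ev.junction == j
    )
    return reads / depth


@dataclass(frozen=True)
class RmwResult:
    r_m: float
    r_w: float
    r_mw: float  # math.inf when r_w == 0 < r_m
    flags: tuple[str, ...] = ()

    @property
    def increased(self) -> bool:
        return self.r_mw > 1

    def r_mw_str(self) -> str:
        return INF_LITERAL if math.isinf(self.r_mw) else f"{self.r_mw:g}"


def compute_rmw(r_m: float, r_w: float) -> RmwResult:
    """Mutant/WT ratio of relative levels; infinite when absent in WT."""
    if r_m < 0 or r_w < 0:
        raise ValueError("relative levels must be non-negative")
    if r_w == 0 and r_m == 0:
        return RmwResult(r_m, r_w, float("nan"), ("not-observed",))
    if r_w == 0:
        return RmwResult(r_m, r_w, math.inf)
    return RmwResult(r_m, r_w, r_m / r_w)


def compute_psi(j: SpliceJunction, model: GeneModel,
                evidence: Sequence[JunctionEvidence]) -> tuple[float, tuple[str, ...]]:
    """Percent-spliced-in of the differential exon node induced by ``j``.

    Inclusion reads come from junctions in the local region whose introns
    avoid the node; exclusion reads from junctions whose introns remove any
    node base.  Returns (PSI, flags); PSI = 1 with a "low-confidence" flag
    when no exclusion evidence exists.
    """
    node = differential_node(j, model)
    if not node:
        raise ValueError("junction induces no differential node")
    hull = (min(j.intron_start, node[0][0]), max(j.intron_end, node[-1][1]))
    inclusion = exclusion = 0
    for ev in evidence:
        if ev.junction.chrom != j.chrom:
            continue
        iv = ev.junction.interval
        if not _overlaps(iv, hull):
            continue
        if any(_overlaps(iv, seg) for seg in node):
            exclusion += ev.read_count
        else:
            inclusion += ev.read_count
    if exclusion == 0:
        return 1.0, ("low-confidence",)
    return inclusion / (inclusion + exclusion), ()


def prevalence_vs_threshold(gene_max_reads: Mapping[str, int],
                            thresholds: Sequence[int]) -> list[tuple[int, float]]:
    """Proportion of genes whose best rescue junction has >= threshold reads.

    ``gene_max_reads`` maps every assayed gene to the read count of its most
    supported rescue junction (0 when none).  A threshold of 0 counts genes
    with any observed rescue junction (>= 1 read).  The curve is monotone
    non-increasing by construction; the proportion at the largest threshold
    serves as the asymptote estimate.
    """
    if not gene_max_reads:
        raise ValueError("empty gene set")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    n = len(gene_max_reads)
    out = []
    for t in thresholds:
        eff = max(t, 1)
        k = sum(1 for v in gene_max_reads.values() if v >= eff)
        out.append((t, k / n))
    for (_, a), (_, b) in zip(out, out[1:]):
        assert b <= a + 1e-12, "prevalence curve must be non-increasing"
    return out


def noncanonical_to_canonical_ratio(
    evidence: Sequence[JunctionEvidence],
    canonical: set[SpliceJunction],
    rescue: set[SpliceJunction] | None = None,
) -> tuple[float | None, float | None]:
    """Per-gene (max non-canonical depth / canonical depth, rescue variant).

    The numerator follows the maximum-read-depth convention for non-canonical
    junctions; the optional second value uses the best *rescue* junction
    instead.  Canonical depth is the maximum read depth among canonical
    junctions.  Returns (ratio, rescue_ratio); None when canonical depth is 0.
    """
    by_junction: dict[SpliceJunction, int] = {}
    for ev in evidence:
        by_junction[ev.junction] = by_junction.get(ev.junction, 0) + ev.read_count
    canon_depth = max(
        (v for j, v in by_junction.items() if j in canonical), default=0
    )
    if canon_depth == 0:
        return None, None
    max_nc = max(
        (v for j, v in by_junction.items() if j not in canonical), default=0
    )
    ratio = max_nc / canon_depth
    rescue_ratio = None
    if rescue is not None:
        max_rescue = max(
            (v for j, v in by_junction.items() if j in rescue), default=0
        )
        rescue_ratio = max_rescue / canon_depth
    return ratio, rescue_ratio


QUANT_REPORT_COLUMNS = [
    "gene_id", "chrom", "intron_start", "intron_end", "strand", "condition",
    "reads", "region_depth", "relative_level",
]


def quant_report(gene_id: str, evidence: Sequence[JunctionEvidence]):
    """Per-(junction, condition) quantification table for one gene/sample
    group, as a DataFrame."""
    import pandas as pd

    rows = []
    by_condition: dict[str, list[JunctionEvidence]] = {}
    for ev in evidence:
        by_condition.setdefault(ev.condition, []).append(ev)
    for condition, evs in by_condition.items():
        junctions = sorted({ev.junction for ev in evs})
        for j in junctions:
            reads = sum(e.read_count for e in evs if e.junction == j)
            depth = junction_region_depth(j, evs)
            rows.append({
                "gene_id": gene_id,
                "chrom": j.chrom,
                "intron_start": j.intron_start,
                "intron_end": j.intron_end,
                "strand": j.strand,
                "condition": condition,
                "reads": reads,
                "region_depth": depth,
                "relative_level": reads / depth if depth else float("nan"),
            })
    return pd.DataFrame(rows, columns=QUANT_REPORT_COLUMNS)
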