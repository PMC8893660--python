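"""Splice-region typing, Nei-Li nucleotide diversity and methylation summaries.

Gene regions are typed by how alternative splicing treats them: canonical
exons untouched by any non-canonical junction (CE), unaffected parts of
affected exons (UE), skipped exons (SE), alternative 5'/3' exon shortenings
inside canonical exons (A5S/A3S), extensions inside canonical introns
(A5E/A3E), and the unaffected intronic remainder of event-bearing introns
(UI).  When events overlap, the more specific label wins (SE > A5S/A3S > UE
for exonic bases; A5E/A3E > UI for intronic bases) and the conflict is
logged.

Nucleotide diversity follows Nei & Li: pi = sum_ij x_i x_j pi_ij with
haplotype frequencies x and per-covered-site pairwise differences pi_ij,
optionally restricted to one of six ancestral-state-oriented substitution
classes and corrected by the regional GC (for C:G -> *) or AT content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, SpliceJunction
from .catalog import differential_node

REGION_CLASSES = ("CE", "UE", "SE", "A5E", "A5S", "A3E", "A3S", "UI")

SUBSTITUTION_CLASSES = (
    "C:G->A:T", "C:G->T:A", "C:G->G:C", "A:T->C:G", "A:T->G:C", "A:T->T:A",
)

# (ancestral, derived) base pair -> substitution class
_CLASS_OF = {
    ("C", "A"): "C:G->A:T", ("G", "T"): "C:G->A:T",
    ("C", "T"): "C:G->T:A", ("G", "A"): "C:G->T:A",
    ("C", "G"): "C:G->G:C", ("G", "C"): "C:G->G:C",
    ("A", "C"): "A:T->C:G", ("T", "G"): "A:T->C:G",
    ("A", "G"): "A:T->G:C", ("T", "C"): "A:T->G:C",
    ("A", "T"): "A:T->T:A", ("T", "A"): "A:T->T:A",
}


@dataclass(frozen=True)
class RegionAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    region_class: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def type_regions(
    model: GeneModel,
    events: Sequence[tuple[SpliceJunction, str]],
    conflicts: list[str] | None = None,
) -> list[RegionAnnotation]:
    """Partition the gene span into splice-behaviour region classes.

    ``events`` pairs each non-canonical junction with its AS event label
    (from :func:`splicerescue.catalog.classify_as_event`); "other"/"MXE"
    junctions contribute no region.  Every exonic base receives exactly one
    of CE/UE/SE/A5S/A3S; extension segments and the unaffected remainder of
    introns hosting events receive A5E/A3E/UI.
    """
    if conflicts is None:
        conflicts = []
    span_s, span_e = model.span
    n = span_e - span_s
    # per-base labels, "" = unassigned; precedence ranks
    labels = np.empty(n, dtype=object)
    labels[:] = ""
    rank = {"": 0, "UE": 1, "UI": 1, "A5S": 2, "A3S": 2, "A5E": 2, "A3E": 2,
            "SE": 3, "CE": 1}

    exonic = np.zeros(n, dtype=bool)
    for s, e in model.exons:
        exonic[s - span_s : e - span_s] = True

    touched_exons: set[int] = set()
    touched_introns: set[int] = set()

    def paint(seg: tuple[int, int], label: str) -> None:
        s = max(seg[0], span_s) - span_s
        e = min(seg[1], span_e) - span_s
        for i in range(s, e):
            old = labels[i]
            if old and old != label:
                if rank[label] > rank[old]:
                    conflicts.append(
                        f"{model.gene_id}:{i + span_s} {old}->{label}"
                    )
                    labels[i] = label
                else:
                    conflicts.append(
                        f"{model.gene_id}:{i + span_s} kept {old} over {label}"
                    )
            else:
                labels[i] = label

    for j, event in events:
        if event in ("SE_single", "SE_multi"):
            for idx, (s, e) in enumerate(model.exons):
                if j.intron_start <= s and e <= j.intron_end:
                    paint((s, e), "SE")
                    touched_exons.add(idx)
            for idx, iv in enumerate(model.introns):
                if iv[0] < j.intron_end and j.intron_start < iv[1]:
                    touched_introns.add(idx)
        elif event in ("A5S", "A3S", "A5E", "A3E"):
            for seg in differential_node(j, model):
                paint(seg, event)
                idx = model.exon_index_at(seg[0])
                if idx is not None:
                    touched_exons.add(idx)
                idx = model.intron_index_at(seg[0])
                if idx is not None:
                    touched_introns.add(idx)
                # an intronic extension marks its abutting exon as affected
                for k, (xs, xe) in enumerate(model.exons):
                    if xe == seg[0] or xs == seg[1]:
                        touched_exons.add(k)
            # the anchored canonical intron also hosts the event
            for idx, iv in enumerate(model.introns):
                if iv[0] < j.intron_end and j.intron_start < iv[1]:
                    touched_introns.add(idx)
        # "other"/"MXE" events contribute no region

    # fill remaining exonic bases
    for idx, (s, e) in enumerate(model.exons):
        sl = slice(s - span_s, e - span_s)
        seg_labels = labels[sl]
        affected = idx in touched_exons or any(l != "" for l in seg_labels)
        fill = "UE" if affected else "CE"
        for i in range(sl.start, sl.stop):
            if labels[i] == "":
                labels[i] = fill
    # fill intronic remainder of event-bearing introns
    for idx in touched_introns:
        s, e = model.introns[idx]
        for i in range(s - span_s, e - span_s):
            if labels[i] == "":
                labels[i] = "UI"

    # collapse runs into intervals
    out: list[RegionAnnotation] = []
    i = 0
    while i < n:
        lab = labels[i]
        k = i
        while k < n and labels[k] == lab:
            k += 1
        if lab:
            out.append(RegionAnnotation(model.gene_id, model.chrom,
                                        i + span_s, k + span_s, lab))
        i = k
    return out


# ---------------------------------------------------------------------------
# Nei-Li diversity
# ---------------------------------------------------------------------------

_VALID = frozenset("ACGT")


def _covered_sites(seqs: Sequence[str], ancestral: str | None) -> np.ndarray:
    arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs]
    if ancestral is not None:
        arrs.append(np.frombuffer(ancestral.upper().encode(), dtype="S1"))
    stack = np.vstack(arrs)
    valid = np.isin(stack, np.array([b"A", b"C", b"G", b"T"]))
    return valid.all(axis=0)


def _pair_diffs(s1: str, s2: str, covered: np.ndarray,
                ancestral: str | None,
                substitution_class: str | None) -> float:
    """Number of (class-restricted) differences per covered site."""
    a1 = np.frombuffer(s1.upper().encode(), dtype="S1")
    a2 = np.frombuffer(s2.upper().encode(), dtype="S1")
    diff = (a1 != a2) & covered
    n_cov = int(covered.sum())
    if n_cov == 0:
        return 0.0
    if substitution_class is None:
        return int(diff.sum()) / n_cov
    anc = np.frombuffer(ancestral.upper().encode(), dtype="S1")
    count = 0
    for i in np.nonzero(diff)[0]:
        b1, b2, ba = a1[i].decode(), a2[i].decode(), anc[i].decode()
        if b1 == ba:
            derived = b2
        elif b2 == ba:
            derived = b1
        else:
            continue  # neither allele ancestral: unorientable
        if _CLASS_OF.get((ba, derived)) == substitution_class:
            count += 1
    return count / n_cov


def nei_li_pi(
    seqs: Sequence[str],
    freqs: Sequence[float] | None = None,
    *,
    seqs2: Sequence[str] | None = None,
    freqs2: Sequence[float] | None = None,
    substitution_class: str | None = None,
    ancestral: str | None = None,
) -> float:
    """Frequency-weighted mean pairwise diversity, pi = sum_ij x_i x_j pi_ij.

    Within one group the sum runs over all ordered pairs (self-pairs
    contribute 0); with ``seqs2``/``freqs2`` given, only cross-group ordered
    pairs are used (between-group diversity).  ``substitution_class``
    restricts counted differences to one ancestral-oriented class and then
    requires ``ancestral``.  Sites not covered (non-ACGT in any sequence,
    ancestral included) are excluded; pi_ij is per covered site.
    """
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    all_seqs = list(seqs) + (list(seqs2) if seqs2 else [])
    if any(len(s) != L for s in all_seqs) or \
            (ancestral is not None and len(ancestral) != L):
        raise ValueError("sequences must be aligned to equal length")
    if substitution_class is not None:
        if substitution_class not in SUBSTITUTION_CLASSES:
            raise ValueError(f"unknown class {substitution_class}")
        if ancestral is None:
            raise ValueError("substitution classes need an ancestral sequence")

    def norm(fr, k):
        if fr is None:
            return np.full(k, 1.0 / k)
        fr = np.asarray(fr, dtype=float)
        if not np.isclose(fr.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        return fr

    covered = _covered_sites(all_seqs, ancestral)
    x1 = norm(freqs, len(seqs))
    if seqs2 is None:
        total = 0.0
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                pij = _pair_diffs(seqs[i], seqs[j], covered, ancestral,
                                  substitution_class)
                total += 2 * x1[i] * x1[j] * pij
        return total
    x2 = norm(freqs2, len(seqs2))
    total = 0.0
    for i, si in enumerate(seqs):
        for j, sj in enumerate(seqs2):
            pij = _pair_diffs(si, sj, covered, ancestral, substitution_class)
            total += x1[i] * x2[j] * pij
    return total


@dataclass(frozen=True)
class DiversityResult:
    region_class: str
    substitution_class: str
    pi: float
    content: float
    pi_corrected: float | None
    flags: tuple[str, ...] = ()


def corrected_pi(pi: float, region_seq: str,
                 substitution_class: str) -> DiversityResult:
    """Divide class-restricted pi by the regional GC content (C:G -> *
    classes) or AT content (A:T -> * classes)."""
    if substitution_class not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown class {substitution_class}")
    seq = region_seq.upper()
    n = sum(1 for b in seq if b in _VALID)
    if n == 0:
        return DiversityResult("", substitution_class, pi, 0.0, None,
                               ("no-sequence",))
    if substitution_class.startswith("C:G"):
        content = sum(1 for b in seq if b in "CG") / n
    else:
        content = sum(1 for b in seq if b in "AT") / n
    if content == 0:
        return DiversityResult("", substitution_class, pi, 0.0, None,
                               ("zero-content",))
    return DiversityResult("", substitution_class, pi, content, pi / content)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

CONTEXTS = ("CpG", "CHG", "CHH")

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "context", "count_methylated",
    "count_unmethylated",
]


def read_cytosine_report(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = set(CYTOSINE_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cytosine report missing columns: {sorted(missing)}")
    return df


def methylation_by_region(
    calls: pd.DataFrame | Sequence[pd.DataFrame],
    regions: Sequence[RegionAnnotation],
    min_depth: int = 4,
    min_coverage: float = 0.7,
) -> pd.DataFrame:
    """Mean methylation level per region per context.

    Per-site level = methylated / (methylated + unmethylated); sites with
    depth < ``min_depth`` are dropped; a region/context is discarded (NaN)
    when the covered fraction of its cytosines falls below ``min_coverage``
    or it has no cytosines.  With several samples given, region levels are
    averaged across samples after per-sample filtering.
    """
    samples = [calls] if isinstance(calls, pd.DataFrame) else list(calls)
    rows = []
    for region in regions:
        for context in CONTEXTS:
            levels = []
            for df in samples:
                sub = df[
                    (df["chrom"] == region.chrom)
                    & (df["pos"] >= region.start)
                    & (df["pos"] < region.end)
                    & (df["context"] == context)
                ]
                if len(sub) == 0:
                    continue
                depth = sub["count_methylated"] + sub["count_unmethylated"]
                covered = sub[depth >= min_depth]
                if len(covered) / len(sub) < min_coverage:
                    continue
                d = covered["count_methylated"] + covered["count_unmethylated"]
                levels.append(float((covered["count_methylated"] / d).mean()))
            rows.append({
                "gene_id": region.gene_id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "region_class": region.region_class,
                "context": context,
                "level": float(np.mean(levels)) if levels else float("nan"),
                "n_samples": len(levels),
            })
    return pd.DataFrame(rows)


def bonferroni_ttests(groups: Mapping[str, Sequence[float]]):
    """Two-sample t-tests between all class pairs with Bonferroni-corrected
    p-values (plain reporting utility)."""
    from itertools import combinations

    from scipy import stats as sps

    names = list(groups)
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b])
        rows.append({"a": a, "b": b, "t": float(t), "p": float(p),
                     "p_bonferroni": min(1.0, float(p) * len(pairs))})
    return pd.DataFrame(rows)
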