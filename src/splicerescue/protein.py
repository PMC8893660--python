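"""Protein-level consequences of frame-restoring isoforms.

A frame-restoring isoform is *rescue competent* when the protein it encodes
preserves every annotated domain of the wild-type protein and shares > 90 %
overall identity with it under a global alignment (match 1, mismatch 0,
gap -1, end gaps penalised).  Both the identity threshold and the in-domain
mismatch tolerance are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Seq import Seq

from .annotation import GeneModel
from .rescue import IsoformModel, VariantSpec, build_mature_transcript

DEFAULT_MIN_IDENTITY = 90.0


def translate_isoform(model: GeneModel, isoform: IsoformModel,
                      variant: VariantSpec | None = None) -> tuple[str, tuple[str, ...]]:
    """Amino-acid sequence of the isoform from the annotated start to the
    first stop; a transcript with no stop is translated to its end and
    flagged "non-stop"."""
    mt = build_mature_transcript(model, isoform, variant)
    if mt.cds_start_tx is None:
        return "", ("start-lost",)
    coding = mt.seq[mt.cds_start_tx:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    if "*" in aa:
        return aa.split("*", 1)[0], mt.flags
    return aa, mt.flags + ("non-stop",)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def _aligned_columns(p1: str, p2: str) -> list[tuple[str, str]]:
    """Columns of the optimal global alignment as (residue_or_-, ...)."""
    aln = _aligner().align(p1, p2)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    return list(zip(s1, s2))


def global_identity(p1: str, p2: str) -> float:
    """Percent identical columns in a global alignment of two proteins.

    Symmetric; 100 iff the sequences are identical; 0 (flagged by the
    caller) for an empty input.
    """
    if not p1 or not p2:
        return 0.0
    cols = _aligned_columns(p1, p2)
    matches = sum(1 for a, b in cols if a == b and a != "-")
    return 100.0 * matches / len(cols)


@dataclass
class ProteinImpact:
    wt_protein: str
    iso_protein: str
    identity_pct: float
    domains_preserved: bool
    rescue_competent: bool
    flags: tuple[str, ...] = ()


def assess_rescue_competence(
    wt_protein: str,
    iso_protein: str,
    domain_intervals: Sequence[tuple[int, int]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    domain_mismatch_tolerance: int = 0,
) -> ProteinImpact:
    """Score an isoform protein against the wild type.

    ``domain_intervals`` are 1-based closed amino-acid intervals on the
    wild-type protein.  Each domain is mapped through the global alignment;
    it is preserved when the mapped span contains no gap column and at most
    ``domain_mismatch_tolerance`` mismatch columns.  With no domains supplied
    the check is vacuously true and flagged "no-domain".
    """
    flags: list[str] = []
    if not wt_protein or not iso_protein:
        return ProteinImpact(wt_protein, iso_protein, 0.0, False, False,
                             ("empty-sequence",))
    cols = _aligned_columns(wt_protein, iso_protein)
    matches = sum(1 for a, b in cols if a == b and a != "-")
    identity = 100.0 * matches / len(cols)

    if not domain_intervals:
        domains_ok = True
        flags.append("no-domain")
    else:
        # map wt residue number (1-based) -> alignment column
        wt_col: dict[int, int] = {}
        r = 0
        for ci, (a, _) in enumerate(cols):
            if a != "-":
                r += 1
                wt_col[r] = ci
        domains_ok = True
        for start, end in domain_intervals:
            if not (1 <= start <= end <= len(wt_protein)):
                raise ValueError(f"domain {start}-{end} outside wt protein")
            span = cols[wt_col[start] : wt_col[end] + 1]
            gaps = sum(1 for a, b in span if a == "-" or b == "-")
            mism = sum(1 for a, b in span if a != "-" and b != "-" and a != b)
            if gaps > 0 or mism > domain_mismatch_tolerance:
                domains_ok = False
                break
    competent = domains_ok and identity > min_identity
    return ProteinImpact(wt_protein, iso_protein, identity, domains_ok,
                         competent, tuple(flags))


def read_domain_table(source) -> dict[str, list[tuple[int, int]]]:
    """Read a domain interval TSV (gene_id, domain_name, aa_start, aa_end;
    1-based closed) into gene_id -> interval list."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    out: dict[str, list[tuple[int, int]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.gene_id), []).append((int(r.aa_start), int(r.aa_end)))
    return out
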