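"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available --
exhaustive enumeration, naive string construction, closed forms -- sharing
no code path with the implementation it checks.
"""

from __future__ import annotations

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def naive_verdict(model, variant, isoform) -> str:
    """Translation-based rescue verdict.

    Builds the mature transcript by filtering chromosome positions through
    the intron chain (per-position membership tests, no interval maps),
    applies the variant, and translates codon by codon: rescue iff the first
    in-frame stop begins exactly at the annotated stop codon's genomic
    position.
    """
    chrom = model.chrom_seq()
    span_s, span_e = model.span
    intronic: set[int] = set()
    for s, e in isoform.intron_chain:
        intronic.update(range(max(s, span_s), min(e, span_e)))
    kept = [(p, chrom[p]) for p in range(span_s, span_e) if p not in intronic]

    if variant is not None:
        if variant.kind == "snv":
            kept = [
                (p, variant.alt_seq if p == variant.pos else b)
                for p, b in kept
            ]
        else:
            out = []
            inserted = False
            for p, b in kept:
                if variant.pos <= p < variant.end:
                    if not inserted:
                        out.extend((-1, c) for c in (variant.alt_seq or ""))
                        inserted = True
                    continue
                if variant.ref_len == 0 and p == variant.pos:
                    out.extend((-1, c) for c in (variant.alt_seq or ""))
                out.append((p, b))
            kept = out

    if model.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        kept = [(p, comp[b]) for p, b in reversed(kept)]

    start_g = model.start_codon_first_base
    stop_g = model.stop_codon_first_base
    positions = [p for p, _ in kept]
    if start_g not in positions:
        return "no_rescue"
    i = positions.index(start_g)
    seq = "".join(b for _, b in kept)
    while i + 3 <= len(seq):
        if seq[i : i + 3] in STOPS:
            return "rescue" if positions[i] == stop_g else "no_rescue"
        i += 3
    return "no_rescue"


def naive_protein(model, isoform, variant=None) -> str:
    """Direct string-spliced translation to the first stop (Biopython)."""
    chrom = model.chrom_seq()
    span_s, span_e = model.span
    intronic: set[int] = set()
    for s, e in isoform.intron_chain:
        intronic.update(range(max(s, span_s), min(e, span_e)))
    kept = [(p, chrom[p]) for p in range(span_s, span_e) if p not in intronic]
    if variant is not None and variant.kind == "indel":
        out, inserted = [], False
        for p, b in kept:
            if variant.pos <= p < variant.end:
                if not inserted:
                    out.extend((-1, c) for c in (variant.alt_seq or ""))
                    inserted = True
                continue
            out.append((p, b))
        kept = out
    seq = "".join(b for _, b in kept)
    positions = [p for p, _ in kept]
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        positions = positions[::-1]
    i = positions.index(model.start_codon_first_base)
    coding = seq[i:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate()).split("*", 1)[0]


def brute_region_depth(j, evidence) -> int:
    """All-pairs interval-overlap sum."""
    total = 0
    for ev in evidence:
        a, b = ev.junction.interval
        c, d = j.interval
        if max(a, c) < min(b, d) and ev.junction.chrom == j.chrom:
            total += ev.read_count
    return total


def brute_nei_li(seqs, freqs, seqs2=None, freqs2=None) -> float:
    """Exhaustive ordered-pair sum of per-site differences (no class logic)."""
    L = len(seqs[0])

    def pij(a, b):
        return sum(1 for x, y in zip(a, b) if x != y) / L

    if seqs2 is None:
        return sum(
            freqs[i] * freqs[j] * pij(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(len(seqs))
        )
    return sum(
        freqs[i] * freqs2[j] * pij(seqs[i], seqs2[j])
        for i in range(len(seqs))
        for j in range(len(seqs2))
    )


def closed_form_chi2_2x2(a, b, c, d) -> float:
    """n (ad - bc)^2 / (r1 r2 c1 c2), the uncorrected Pearson statistic."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
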