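import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from splicerescue import simulate as sim


@pytest.fixture(scope="session")
def wda1_fx():
    return sim.wda1_fixture(seed=0)


@pytest.fixture(scope="session")
def bc10_fx():
    return sim.bc10_fixture(seed=0)


@pytest.fixture(scope="session")
def snv_fx():
    return sim.nonsense_snv_fixture(seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A handful of random coding genes with short introns (fast oracles)."""
    cfg = sim.SyntheticConfig(seed=11, n_genes=8, intron_length_range=(67, 300))
    return cfg, sim.generate_gene_models(cfg)


def make_toy_model(exon_seqs, intron_seqs, utr5, strand="+", gene_id="toy",
                   chrom="chrT", lead=17):
    """Hand-assembled single-gene model from explicit exon/intron sequences.

    The CDS runs from ``utr5`` (spliced coordinate) to the end of the spliced
    transcript; callers control the content.
    """
    from splicerescue.annotation import GeneModel

    tx_len = sum(len(s) for s in exon_seqs)
    cds_len = tx_len - utr5
    blocks = []
    for i, ex in enumerate(exon_seqs):
        blocks.append(("exon", ex))
        if i < len(intron_seqs):
            blocks.append(("intron", intron_seqs[i]))
    gene_seq = "".join(s for _, s in blocks)
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        gene_seq = gene_seq.translate(comp)[::-1]
        blocks = [(k, s.translate(comp)[::-1]) for k, s in reversed(blocks)]
    genome = {chrom: "G" * lead + gene_seq + "C" * lead}
    exons, pos = [], lead
    for kind, s in blocks:
        if kind == "exon":
            exons.append((pos, pos + len(s)))
        pos += len(s)
    exons.sort()

    def tx2gen(t):
        walk = exons if strand == "+" else list(reversed(exons))
        for s, e in walk:
            if t < e - s:
                return s + t if strand == "+" else e - 1 - t
            t -= e - s
        raise IndexError(t)

    g1, g2 = tx2gen(utr5), tx2gen(utr5 + cds_len - 1)
    return GeneModel(gene_id, chrom, strand, tuple(exons),
                     min(g1, g2), max(g1, g2) + 1, genome)
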