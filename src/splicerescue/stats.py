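"""Hypothesis tests against the noisy-splicing null, and catalogue summaries.

Under a uniform null in which novel splice boundaries land at random
positions, two thirds of non-canonical junctions should change the reading
frame (be non-3n).  ``chi2_gof_two_thirds`` tests an observed non-3n count
against that 2/3 : 1/3 expectation (Pearson goodness of fit, df = 1, no
continuity correction); ``chi2_2x2`` compares two such proportions (Yates
correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float

    def p_str(self) -> str:
        if self.p < P_FLOOR:
            return "< 2.2e-16"
        return f"{self.p:.2g}"


def chi2_gof_two_thirds(k_non3n: int, n: int) -> GofResult:
    """Pearson goodness of fit of (k, n-k) against expected (2n/3, n/3)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k_non3n <= n:
        raise ValueError("k out of range")
    expected = np.array([2 * n / 3, n / 3])
    observed = np.array([k_non3n, n - k_non3n])
    chi2, p = sps.chisquare(observed, f_exp=expected)
    return GofResult(float(chi2), 1, float(p))


def chi2_2x2(a: int, b: int, c: int, d: int,
             continuity: bool = True) -> GofResult:
    """Pearson 2x2 test of [[a, b], [c, d]]; Yates correction by default."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=continuity)
    return GofResult(float(chi2), int(df), float(p))


def summarize_catalog(
    classified: Iterable[tuple[str, str, str]],
    n_genes_annotated: int,
    n_annotated_junctions: int,
) -> dict[str, float]:
    """Summary counts over a classified catalogue.

    ``classified`` yields (gene_id, canonical_label, frame_class) triples,
    one per observed junction.  Returns junction totals, genes with
    junctions, alternatively spliced genes (>= 1 non-canonical junction),
    non-3n counts and the derived per-gene and fold-over-annotation ratios.
    """
    n_junctions = 0
    n_noncanonical = 0
    n_non3n = 0
    genes: set[str] = set()
    alt_genes: set[str] = set()
    for gene_id, canon, frame in classified:
        n_junctions += 1
        genes.add(gene_id)
        if canon == "non-canonical":
            n_noncanonical += 1
            alt_genes.add(gene_id)
            if frame == "non-3n":
                n_non3n += 1
    return {
        "n_junctions": n_junctions,
        "n_canonical": n_junctions - n_noncanonical,
        "n_noncanonical": n_noncanonical,
        "n_non3n_noncanonical": n_non3n,
        "genes_with_junctions": len(genes),
        "alt_spliced_genes": len(alt_genes),
        "junctions_per_gene": (
            n_junctions / n_genes_annotated if n_genes_annotated else float("nan")
        ),
        "fold_over_annotation": (
            n_junctions / n_annotated_junctions
            if n_annotated_junctions else float("nan")
        ),
    }
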