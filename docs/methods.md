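# Methods

This note records the models, conventions and deliberate design choices
behind `splicerescue`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and gene models

All internal coordinates are 0-based, half-open, on the plus strand of the
genome; GFF3 input (1-based closed) is converted on load and written back
on export. Transcript-orientation views (exon order, donor/acceptor roles)
are derived from the strand where needed; this keeps all frame arithmetic
in a single, unambiguous coordinate system.

One representative transcript is kept per gene; additional annotated
transcripts are skipped with a warning. Genes without CDS features are
flagged non-coding and excluded from frame analysis; structurally malformed
genes (overlapping exons, CDS outside exons) are reported and rejected,
never silently dropped. A coding model's invariants — spliced CDS a
multiple of three, a single terminal stop — are checked by
`GeneModel.validate()`.

Splice junctions are stored as their excised intron interval. The default
intron length bounds, 67–3608 bp, describe the rice-like regime the
synthetic generator emulates; they are constructor arguments, not
hard-coded policy.

## Frame deltas and event labels

The frame delta of a junction is computed *structurally*: the isoform
implied by "all compatible canonical introns plus this junction" is built,
its exonic length differenced against the canonical isoform, both clamped
to the annotated gene span. This equals −(canonical-exonic nt excised) +
(canonical-intronic nt retained) and is exactly checkable by set
arithmetic, which is why no string alignment is used anywhere in the frame
logic. A junction is non-3n iff its delta is not ≡ 0 (mod 3).

Event labels follow the usual taxonomy. Both junction ends at annotated
sites with whole exon(s) inside → SE (single/multi); one end anchored and
the other inside the anchored intron → extension (A5E/A3E), inside the
adjacent exon → shortening (A5S/A3S); the 5′/3′ assignment is made in
transcript orientation. Junctions with both ends inside canonical introns
would imply a novel internal exon; they are labelled `other` and excluded
from frame arithmetic unless supplied as part of an explicit chain, since
one junction alone does not determine the implied exon. MXE is only called
for a supplied pair of single-exon skips of distinct adjacent exons; a
single junction is never MXE. Intron retention is deliberately out of
scope: retained introns cannot be resolved unambiguously from junction
evidence.

## The rescue caller

A rescue call asks whether an isoform (an explicit chain of junctions)
restores the reading frame of a variant. The verdict combines:

1. **Modular arithmetic** — net delta = chain exonic-length change + the
   *retained* portion of the variant's length change; rescue requires
   net ≡ 0 (mod 3).
2. **A codon scan** of the mature transcript the isoform actually produces
   (spliced genome sequence, variant applied where retained) from the
   annotated start: the first in-frame stop must be the canonical stop
   codon, located by its genomic position through the transcript→genome
   map. Stops upstream are premature; stops downstream are reported as
   `posterior_to_canonical` and are *not* rescue, mirroring the separate
   treatment of frameshift stops that land behind the original stop.

Partially excised indels contribute only their retained delta; a fully
excised indel contributes zero, so skipping the indel-bearing exon is the
cleanest rescue route. A deletion straddling an exon boundary of the
isoform is flagged `boundary-spanning` and applied to retained bases only.
Insertions apply when their anchor position survives splicing. For
nonsense SNVs, rescue additionally requires that the PTC never appears:
either its bases are excised or the test fails at the scan stage, since a
retained in-frame stop is found by translation.

"PTC" is defined operationally as the first in-frame stop under canonical
splicing with the variant applied, strictly upstream of the canonical
stop. No 50-nt NMD rule is applied anywhere: NMD efficiency is not
modelled, only emulated in read counts (below). The annotated start codon
is taken as given; re-initiation and alternative starts are out of scope.

Rescue calls carry two classifications:

* **Form class** — (chain 3n vs non-3n) × (whole indel-bearing exon
  skipped vs not), giving `A1_3n_exon_skip`, `A_3n_other`,
  `A6_non3n_exon_skip`, `A_non3n_other`. The finer subtypes within the
  "other" buckets are not distinguished.
* **PTC mode** — letters A–H: (indel and PTC in the same annotated exon vs
  different exons) × (PTC excluded by whole-exon skip / excluded by a
  non-skip junction / retained but frame-compensated / retained with a
  whole exon 5′ of the PTC skipped).

The test suite holds the caller to a brute-force oracle — naive per-position
splicing of the chromosome string followed by translation, sharing no code
with the implementation — over ≥ 1000 randomized (gene, variant, isoform)
triples, and to the phase-asymmetry property that a fixed non-3n chain
rescues exactly one of the 3n+1/3n+2 phases.

## Quantification conventions

The "junction region" of a junction is its intron interval; region depth
is the summed reads of all junctions whose introns overlap it, itself
included. Exon-body (non-junction) coverage is excluded: quantification is
junction-only, and output metadata should be read with that convention in
mind. Relative level = junction reads / region depth; R_mw is the
mutant/WT ratio of relative levels, `Inf` (serialized literally) when the
junction is unseen in WT but present in the mutant, and flagged
`not-observed` when absent in both.

PSI of a junction is the inclusion proportion of its *differential node* —
the exonic segment whose presence the junction toggles relative to the
canonical structure. Junctions in the local region whose introns avoid the
node count as inclusion; those removing any node base count as exclusion;
with no exclusion evidence PSI is 1 with a `low-confidence` flag. This is
a junction-read-only PSI; no body reads enter.

Prevalence curves count, per threshold t, the genes whose best rescue
junction has ≥ t reads (t = 0 means "any observed junction", i.e. ≥ 1
read); the curve is monotone non-increasing by construction and the value
at the largest threshold serves as the asymptote estimate. The
non-canonical/canonical ratio uses the *maximum* read depth among
non-canonical junctions over the maximum canonical depth, with a variant
that substitutes the best rescue junction for the numerator.

## Protein competence

Similarity is global-alignment identity (match 1, mismatch 0, gap −1, end
gaps penalised; Biopython's PairwiseAligner): matching columns over
alignment length × 100. No specific aligner convention is canonical for
this task, so the scoring is fixed and documented rather than
configurable. Domains are inputs (1-based closed amino-acid intervals on
the wild-type protein), mapped through the alignment; a domain is
preserved when its mapped span contains no gap column and at most a
configurable number of mismatch columns (default 0). Rescue competence =
all domains preserved ∧ identity > 90 % (the threshold is a parameter,
`min_identity`). With no domains supplied the domain check passes
vacuously and is flagged `no-domain`.

## Region typing and diversity

Region classes: CE (exon with no non-canonical splice site at either
end), UE (unaffected part of an affected exon — including exons whose
boundary hosts an extension event), SE, A5S/A3S (shortened exonic
segments), A5E/A3E (intronic extension segments), UI (remaining intronic
bases of event-bearing introns). When events overlap, the more specific
label wins — SE > shortenings > UE exonically, extensions > UI
intronically — and each conflict is logged. Exonic bases always partition
exactly once; this is asserted in tests.

Nei–Li diversity is the frequency-weighted ordered-pair sum
π = Σᵢⱼ xᵢxⱼ πᵢⱼ, with πᵢⱼ the pairwise differences *per covered site*
(sites non-ACGT in any haplotype, ancestral included, are excluded — a
deliberate choice over per-region-length normalisation, recorded in output
metadata). Between-group mode uses cross-group ordered pairs only.
Substitution classes (C:G→A:T and the other five) are oriented by a
supplied ancestral sequence; a difference where neither allele matches the
ancestral base is unorientable and excluded from class-restricted counts,
so per-class values sum to the unrestricted total exactly on biallelic
panels (asserted in tests). Ancestral states are inputs, never inferred
here. Corrected π divides by the regional GC content for C:G→* classes
and AT content for A:T→* classes.

Methylation levels are per-site methylated/(methylated+unmethylated),
sites below depth 4 dropped, a region/context discarded when covered
cytosines fall below 70 %, then averaged across sites and finally across
samples. Group contrasts are plain two-sample t-tests with Bonferroni
correction, provided as a reporting utility only.

## Null-model statistics

Under uniform placement of novel splice boundaries, two thirds of
junctions change the frame. Goodness-of-fit tests of an observed non-3n
count against (2n/3, n/3) use the Pearson statistic with df = 1 and *no*
continuity correction; 2×2 comparisons of two proportions default to the
Yates correction. This asymmetric convention is what reproduces all four
published worked-example statistics from their printed counts, and both
choices are explicit arguments.

## The synthetic generators

All generators draw from a single `numpy` `Generator` seeded by
`SyntheticConfig.seed`; identical configs produce byte-identical FASTA,
GFF3 and TSV outputs (asserted in tests). Defaults describe the study
regime: introns uniform in [67, 3608] bp, exon lengths lognormal with
median 150 nt (echoing typical exon sizes in intron-rich plant genomes),
2–11 exons, both strands, CDS assembled from sense codons with one
terminal stop. Noisy junctions place donor and acceptor uniformly within
the gene body subject to the intron bounds, which yields the 2/3 non-3n
null; variant panels cycle a −1/−4/−22/+1/−5/−3 size mixture through
interior CDS positions; junction reads are multinomial at configured
isoform proportions and depth (NMD emulation, where wanted, is a simple
depletion of an isoform's proportion, not a mechanistic 50-nt rule);
haplotype panels (default 3 groups × 20) mutate class-eligible sites at a
per-site rate with one derived allele per segregating site, so the true
per-class π is known in closed form and emitted as an answer key.

The engineered rescue fixtures rely on one construction device: every
stop codon begins with T, so a CDS stretch drawn from {A, C, G} contains
no stop in *any* reading frame. Fixture CDSs (and fixture intron
interiors) are T-free except for deliberately planted TAA codons at chosen
codon phases, which makes each fixture's truth table — which variants are
rescued by which isoform — a construction guarantee rather than an output
of the caller under test. The `wda1`-like fixture (alternative donor
−20 nt into exon 2, variants −1/−4/−22/+1 in exon 3) and the `bc10`-like
fixture (11 exons, a 45-bp seventh exon whose skipping rescues −5/−1/−22
deletions) mirror the two canonical rescue routes; a third fixture covers
nonsense-SNV rescue by 3n exon skipping.

What the generators do *not* emulate: read-level sequences and aligner
artefacts, junction anchor/overhang filtering (counts are taken at face
value), amplification bias, intron retention, multi-isoform reference
annotations, or genuine evolutionary site-frequency spectra (derived
allele counts are uniform, not neutral-expectation shaped). Passing tests
therefore demonstrate correctness of the arithmetic and the calling logic
under the stated model, not robustness to alignment noise in real data.

## Problem sizes

The default test suite and the acceptance script run at desk scale: ~1000
randomized rescue triples against the translation oracle, 30,000 noisy
junctions for the 2/3 null, panels of ≤ 60 haplotypes × ≤ 4 kb for
diversity, depth 10,000 for read-count recovery. These sizes put the
binomial standard errors well below the tolerances being asserted while
keeping the whole suite in seconds.

## Known limitations

* Junction chains are accepted as explicit inputs (plus auto-built
  single-novel-junction chains); co-occurrence of multiple novel junctions
  on one molecule cannot be inferred from junction-level evidence alone.
* Junctions overlapping two genes are assigned by larger CDS overlap in
  the CLI layer; ties are not resolved, only flagged.
* The A2–A5 / A7–A10 fine subtypes of the rescue form taxonomy are
  reported only as their coarse buckets.
* `scan_orf` assumes the stop codon is contained in the terminal CDS exon
  of the annotated model, which holds for all models this package builds
  and loads but would mis-anchor a stop codon split across a splice
  junction.
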