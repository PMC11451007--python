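# Methods

## The analysis model

`isocollapse` treats a long-read RNA-seq experiment as a collection of
per-sample *transcript calls*: exon chains produced by an upstream caller
(TALON-style), each with a read count and caller novelty labels. The caller
is trusted for splice sites (long-read pipelines correct them against the
reference) but **not** for transcript termini, which wobble by a few bases
between samples, and not for gene assignment at loci entangled with a
readthrough gene. The pipeline's job is to turn these per-sample calls into
a stable cross-sample catalog with interpretable names, quantities and
evidence, in seven stages.

### Locus separation

Assignment is a pure interval predicate on the transcript's genomic span
(first to last exon): overlap ≥ 1 bp with both the target and the partner
locus on the same strand ⇒ readthrough gene; target only ⇒ target gene;
otherwise "neither". Overlap can be restricted to exonic bases
(`exonic_overlap=True`), but the default uses the span, matching the
range-based selection tools used in practice. The three labels partition
the input; "neither" transcripts are excluded from both genes but retained
(they still contribute their caller-labelled gene to the TPM denominator,
which is sample-wide by construction).

Before any quantification, calls labelled `Genomic` (unspliced read-through
of genomic DNA) and calls of `Antisense`/`Intergenic` genes are removed;
unknown labels are never grounds for removal.

### Gene-level TPM

Gene length is the union of exonic bases over the gene's *detected*
transcripts (in kb), not the annotated span — the denominators therefore
reflect the dataset being analysed, and the choice is recorded in the
output metadata. RPK = count/length; the per-sample scaling factor is
Σ RPK / 10⁶; TPM = RPK / scaling. ΣTPM = 10⁶ per sample is enforced to
1e-9 relative and property-tested over random tables. A sample whose total
RPK is zero has no defined TPM and raises rather than silently emitting
zeros.

### ORF and UTR decomposition

ORF scanning enumerates, per frame, every ATG whose first downstream
in-frame stop codon exists within the transcript; codons containing N match
nothing. Two reductions follow: *longest per stop* (nested starts sharing a
stop are redundant; the most upstream start wins) and *longest per
transcript*. ORFs lacking an in-frame stop before the transcript end are
discarded — the identity of an ORF is keyed on its stop codon. Length ties
break to the most 5' start, then to the lexicographic genomic block
structure, so selection and ID assignment are permutation-stable.

ORF distinctness for cataloguing is **genomic CDS block identity**: the
same protein reached through different genomic paths is a different ORF,
because the IDs attach to transcript structures. IDs are
`{gene}_{rank}_{len}aa` with ranks by descending product length; the
product length excludes the stop codon.

UTRs are the transcript regions flanking the selected CDS, projected to
genomic blocks; 5'UTR ∪ CDS ∪ 3'UTR tiles the exon chain exactly (property
tested). Each UTR record carries its *internal boundaries* (every block
edge except the distal transcript terminus) and its *distal end*. A
transcript with no ORF gets pseudo-UTR records carrying the full splice
structure (internal boundaries = all edges except the two termini), which
reduces non-coding merging to "identical intron chain, both ends within
tolerance".

NMD: a transcript is NMD-sensitive when the last base of its stop codon
lies **strictly more than 50 nt** (spliced coordinates) upstream of the
most downstream exon–exon junction; single-exon transcripts are never
flagged. The 49/50/51-nt boundary behaviour is pinned by tests.

### Merging and UTR clustering

Two calls merge iff their ORF IDs and both UTR IDs agree. UTR identity
within a side requires exact internal-boundary equality plus distal ends
within the tolerance (default 20 bp, inclusive) of the **cluster anchor**.
Anchoring, rather than single-linkage chaining, bounds every cluster's
radius: ends at 0/20/40 yield two clusters, never one 40-bp-wide cluster.
Anchors are chosen greedily over records ordered by read-count support then
coordinate, so the most supported terminus of each UTR family defines its
reference coordinate and numbering is deterministic under permutation. UTR
numbers are arbitrary per run but stable given fixed input; the id-mapping
tables make them interpretable across runs. Empty UTRs share the reserved
`{side}UTR_0`.

Merged transcripts detected in ≥ 3 samples are *valid*; the sub-threshold
remainder is returned as a *minor* set rather than dropped, because rare
isoforms (e.g. disease-associated ones detected once or twice) are
reportable findings.

### Usage, tissue specificity, novelty, taxonomy

Usage is compositional within each sample over the locus's merged
transcripts; samples with zero locus reads are undefined (NaN), not zero.
Median usage is taken over detection-positive samples only — a transcript
seen in 22 of 99 samples has its median over those 22 (an all-samples
median is a one-line switch). ORF usage sums transcript usage per ORF and
also sums to 1 per expressed sample.

The per-tissue summary statistic for specificity is the **mean** usage over
the tissue's locus-positive samples, and the ≥ 2× comparison against every
other tissue is inclusive; a transcript expressed in a single tissue only
is specific to it. Fewer than two tissues ⇒ warning, nothing flagged.

Novelty is structural, with the reference annotation pushed through the
same ORF/UTR engine: an ORF is known iff its CDS block set equals a
reference ORF's; a UTR is known iff internal boundaries match exactly and
the distal end is within the merge tolerance of a reference UTR; a
transcript is known iff one reference model matches on all three components
jointly. Caller "Known" labels are carried through as corroborating
metadata but do not decide novelty. An empty reference makes everything
novel, with a warning.

The taxonomy is a total cascade, in order: NMD (→ `NMD_Known`/`NMD_Novel`
by transcript novelty), coding potential (< 150-aa product or no ORF →
`Non_coding_*`), whole-transcript novelty (known → `Coding_Known`), then
the ORF/UTR novelty combination (`Novel_3/5UTR_only`, `Novel_combination`,
`Novel_ORF_and_UTR`, `Novel_ORF_only`). NMD precedence means no NMD
transcript ever reaches a coding category.

### External validation

TSS and polyA validation measure the distance from the representative
transcript's terminus to the nearest same-strand atlas interval edge (0
inside) against a tolerance — 50 bp for TSS following standard practice;
the polyA tolerance is not standardised and defaults to 50 bp,
configurable and recorded in output metadata. Strandless atlas records
(`.`) match either strand. Junction validation is exact coordinate+strand
equality on distinct introns. All end flags are monotone in the tolerance
(property tested). Junction count matrices yield per-tissue detection rates
(fraction of samples with count > 0) and mean counts including zeros, with
global min/mean/max of tissue means.

Exon-identity screening reports byte-identical strand-aware exon sequence
pairs between two exon sets — the mechanism by which a readthrough gene
defeats unique short-read mapping. Isoform-unique peptides use tryptic
digestion (cleave after K/R except before P, zero missed cleavages,
minimum length 6 — the length chosen so that 7-mer junction peptides of
the kind reported in proteomics follow-ups are retained) and substring-scan
uniqueness against the background proteome; the MS search itself is out of
scope.

## The synthetic locus

The generator emulates an ENCODE-style study: per-sample GTF+quant pairs
from a caller with corrected splice sites, jittered termini, novelty
labels and occasional artifact calls, plus reference TSS/polyA/junction
sets — at desk scale, with every expected outcome known analytically.

**Sequence construction.** Gene-body filler is drawn from {A, C} only and
every ATG/TAA is planted explicitly (each planted ATG is followed by C so
no spurious out-of-frame TGA arises). Start and stop codons require T or G,
so the codon landscape is fully determined by the construction tables:
truth ORF lengths, NMD distances and categories are derived by coordinate
arithmetic, never by running the ORF scanner — the generator remains an
independent oracle for the analysis engine, and tests cross-check the two.
The restricted alphabet costs sequence realism (proteins over
{K,N,T,Q,H,P}, which still provides tryptic K sites) but buys exactness.

The minus-strand target gene has seven core exons (canonical product
240 aa); a 121-nt exon makes one skip frameshifting while a 150-nt exon
skips in frame; planted codons create an alternative start (190 aa), a
premature stop in the skip frame satisfying the 50-nt rule with a 56-nt
margin (170 aa), a short ORF (26 aa) and a retained-last-intron stop
(270 aa, the rank-1 product). The partner gene sits downstream (lower
coordinates) and a readthrough transcript splices three target exons onto
two partner exons — it spans both loci and, by construction, none of its
start codons reaches an in-frame stop, exercising the no-ORF path. The ten
valid target transcripts realise all nine taxonomy categories; three
reference-only or reference-included models (canonical, the known
frameshift, the known short form, plus a known ORF/long-3'UTR pairing)
define the novelty splits.

**Study conditions (defaults).** 50 samples over three tissues, ~5,000
locus reads per sample (Poisson), 20% per-transcript per-sample dropout,
and a 20-bp terminus spread. `utr_jitter_bp` is the maximum spread between
two jittered copies of an end (draws are uniform in [-j/2, +j/2]): the
spread, not the half-width, is what the anchored 20-bp merge criterion
compares, so the default jitter sits exactly at the merge tolerance and
must never split a transcript, while `forced_jitter` (drawing only the two
extremes) guarantees a controlled violation for any value above the
tolerance. Detected transcripts receive ≥ 1 read; remaining depth is
multinomial over the tissue's designed usage fractions renormalised to the
detected set. Designed per-tissue profiles keep non-specific transcripts
below 1.6× between tissues and specific ones at 3×, so multinomial noise
cannot flip the inclusive 2× rule at these sample sizes. Each sample also
carries one `Genomic` and one `Antisense` decoy for the artifact filter.

**Reference coverage for validation.** Transcripts sharing a distal end
cannot be covered independently at a 50-bp tolerance, so TSS/polyA
coverage fractions are resolved over distal-end equivalence classes with
an exact subset-sum (the catalog's end classes, sizes [4,1,1,1,1,1,1] on
both sides, make 0.5/0.7/0.9 of 10 exactly reachable; an unreachable
fraction raises). The ten distinct truth introns make junction fractions
exact trivially. End classes are separated by ≥ 100 bp so coverage of one
class never validates another even after jitter.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive throughout; BED converts at the
  boundary. Intervals validate `start ≤ end ≥ 1`; exon chains validate
  transcript-orientation ordering, non-overlap and ≥ 1-bp introns at
  construction, so invalid structures cannot propagate.
* All tie-breaks (ORF selection, rank assignment, cluster anchoring,
  representative choice) are total orders on content, making every stage
  byte-reproducible under input permutation; reruns are idempotent.
* Usage in zero-count samples is NaN, never 0; median usage of an
  undetected transcript raises.
* The tissue rule uses a 1e-12 slack on the inclusive ≥ comparison to
  absorb float division noise.
* Simulation draws come from a single seeded PCG64 generator per stage;
  coordinates are integer arithmetic end to end.

## Problem sizes

Tests and the acceptance script run the full study at 50 samples ×
~5,000 reads (≈ 600 transcript calls per run), 1,000-sequence ORF-oracle
sweeps, 1,000-seed generator invariance and 1,000 random TPM tables; the
whole suite completes in well under a minute on one core. These sizes were
chosen because every asserted property is already at its asymptote there
(e.g. usage recovery tolerances are dominated by multinomial noise at
depth 5,000, not by sample count).

## Known limitations

* Novelty and validation use the representative member's termini; a
  cluster whose members straddle a reference UTR's ±20 bp window can
  change novelty with the representative. In practice the representative
  is the highest-count member, the same choice the composite ID anchors.
* The 50-nt NMD rule is a heuristic; long 3'UTRs, uORFs and EJC-independent
  effects are out of scope, as are Kozak context and non-AUG starts.
* The generator does not model read-level errors, splice-site noise or
  intra-sample duplicate calls of one transcript; it emulates a caller
  that has already collapsed reads within each sample.
* Readthrough chains across more than two loci are not modelled.
* Fuzzy (sub-identity) exon similarity is out of scope; the exon screen is
  exact-match only.
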