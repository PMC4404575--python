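# Methods

This note documents the models, conventions and design choices behind
`recsplice`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Coordinate conventions

Genomic coordinates are 1-based inclusive (VCF/GFF convention) everywhere
inside the package; BED output alone is 0-based half-open.  Transcript
coordinates run 1-based along the mature mRNA in the direction of
transcription; CDS (`c.`) coordinates follow HGVS, with intronic positions
anchored to the nearest exonic base and a signed offset (negative =
upstream of an acceptor-side exonic base).  All sequence-level logic
(consequence codons, acceptor windows, cryptic-acceptor AG checks,
in-silico RT-PCR) is routed through a single strand-aware `GeneModel`, and
the packaged fixture is generated on the minus strand by default precisely
to keep every code path strand-exercised; a plus-strand mirror is
available and the test suite asserts both strands give identical results.

## Autozygosity mapping

A recessive case is homozygous identical-by-descent for the founder
segment carrying the mutation.  The segment finder returns the longest run
of consecutive markers at which every case is homozygous for one shared
allele, ties broken leftmost (deterministic output), boundaries reported
at the outermost qualifying markers.  Sharing is defined on unphased
homozygous genotypes: when all cases must be homozygous, phasing adds
nothing.  Missing calls are treated as compatible with homozygosity; in
the windowed scan a sample fails a window when more than 5% of its window
genotypes are missing.  The scan tests, per sliding window (default 20
markers), whether all cases are homozygous for one shared window
haplotype, and if so compares haplotype-homozygote counts in cases vs
controls with a one-sided Fisher exact test; the significance threshold is
Bonferroni-corrected over windows.  This is a deliberately transparent
substitute for generalized mixed-model haplotype association software: it
produces the same qualitative output (a single genome-wide-significant
peak over the shared segment) without variance components, so peak
p-values are not comparable to mixed-model scores and are not treated as a
reproduction target.

## Variant filter cascade

Five stages, applied to biallelic records (multi-allelic records are split
on read): inside the mapped interval; QUAL strictly greater than 100 (the
threshold is read as strict); homozygous-alternate in every sequenced
case; alternate allele absent from every control genotype (het or hom
counts as observed; a missing control genotype does not); not in the
known-variant catalog, matched by chrom+pos+ref+alt so a novel allele at a
known site is not masked.  Stages 2–5 are pure set predicates, hence the
final candidate set is invariant under their order (tested by
permutation).  Missing case genotypes fail the homozygosity stage: this is
stricter than a low-coverage real analysis, where a case might lack an
explicit call, and is documented as such.  Consequence classes are
missense / nonsense / synonymous (by codon substitution against the CDS),
canonical_splice_region (intronic, within 3 bp of a junction), intronic,
UTR, intergenic; indels fall outside this SNV taxonomy and are reported
distinctly.  Signed junction distance is negative on the intron side, and
the exonic base adjacent to a junction counts as +1.

## Splice-junction analysis

Only junction reads are used — no exon-body coverage — matching the kind
of evidence a genome browser shows as junction arcs.  A gapped alignment
contributes one junction per `N` operation whose flanking aligned blocks
are both at least `anchor_min` (default 8 nt).  For an internal exon,

    PSI = inclusion / (inclusion + skip)

with inclusion summarised as the average of the two flanking inclusion
junctions, rounded half-up: one transcript spans both junctions, so
averaging avoids double-counting it, and the worked 20-of-45 example is
reproduced exactly by supplying 25 on both flanks.  An exon-skip event is
called when PSI < 0.8 at ≥ 10 informative reads; a cryptic acceptor when
an unannotated junction shares a donor with an annotated one and its
acceptor is shifted ≤ 10 nt relative to an annotated exon start, with the
shifted acceptor checked for an immediately-upstream AG on the transcribed
strand.  Cryptic reads that also skip the intervening exon are folded into
that exon's skip support and reported as isoform fractions (skip-only vs
skip-plus-cryptic).  In-silico RT-PCR takes both primers 5'→3', requires a
perfect primer site on the spliced isoform, and returns the product
spanning the outer primer ends; a primer landing in a skipped exon yields
an explicit no-product result.

## Acceptor scoring

The acceptor window covers −20…+3 around the junction (+1 = first exonic
base, 23 nt, transcribed strand).  The score is the pyrimidine fraction
over tract positions −16…−5, multiplied by an indicator that the AG at
−2/−1 is intact; N counts as purine.  No trained weight matrix is used:
the published evidence for this class of variant is positional (a
conserved pyrimidine in the tract), and the transparent score makes the
effect of one tract substitution exact — a pyrimidine→purine flip costs
1/12 — and therefore directly testable.  A variant is flagged disruptive
when its score delta is ≤ −1/24 (half a tract position, so any real tract
loss trips it) or the AG is lost.  Window and tract bounds are frozen
conventions, configurable.  Cross-species conservation of a column is a
simple match count; alignment gaps are excluded from the denominator by
default (a flag counts them as mismatches).

## Prioritization and protein effect

Candidates within 50 bp of a splice site of an aberrantly spliced exon are
linked to that event; ranking is lexicographic — linked before unlinked,
acceptor-disrupting before not, then smaller distance, then genomic
position — a total, deterministic order.  No weighted score is used: the
published analyses of this kind resolve the causative variant by
inspection, and a lexicographic rule formalizes that inspection
transparently.

The protein effect of an exon skip maps the exon's CDS nucleotide span to
residues with explicit phase handling: a residue is deleted only when all
three of its nucleotides are removed; junction-spanning partial codons
recombine into a hybrid codon and count as retained.  Two CDS
parameterizations ship with the package.  The splice fixture (216-nt
exon 2 beginning at c.211, forced by the RT-PCR product arithmetic
593 − 377 = 216) removes codons 71–142 when skipped.  The published
protein annotation for the real gene — 188 residues, exon-2 skip removing
residues 61–130 (70 aa, 118 remaining) — implies a 210-nt CDS contribution
from that exon and is therefore not consistent with the 216-nt transcript
arithmetic; the package keeps a separate synthetic protein-annotation
model (`fixture_protein_model`) parameterized to reproduce the reported
61–130 range and the domain table (TM helices 38–55 and 60–78, N-terminal
1–37, C-terminal tail 79–188).  Both are exercised by tests; the
discrepancy between the two published coordinate systems is inherent to
the source data, not a modeling choice.

## Assay statistics

Concordance: every case must be homozygous for the risk allele, every
obligate-carrier parent heterozygous; missing genotypes are not counted as
checked.  Carrier frequency is the heterozygote fraction of the genotyped
population (homozygotes are not carriers).  The deficit-of-homozygotes
test is an exact binomial lower tail on the homozygote count with plug-in
allele frequency `q̂ = (het + 2·hom)/2n`: simple, stated, and reproducible;
a mid-p variant sits behind a flag.  The plug-in construction is slightly
conservative (the same data estimate q̂ and are then tested), which the
null-calibration test confirms: rejection at the 5% level stays below 5%.
At the study scale (n = 10,000, 6% carriers, zero homozygotes) the closed
form gives p = (1 − 0.03²)^10000 ≈ 1.2 × 10⁻⁴.

## The synthetic-data generator

The generator's defaults are the study conditions: 15 genotyped cases and
275 controls on a 324-marker panel; one founder haplotype carrying the
causal allele, transmitted through an elite sire mated to his own carrier
daughters so every case is homozygous IBD across the interval; controls
carrying the haplotype at 6% and never homozygous; 2,968 interval variants
of quality above 100, of which 31 (the causal variant plus 30 planted
non-coding decoys) survive the full cascade; junction depth of 45 reads
with 50% skipping in carriers, 100% in homozygotes, and a 75/25
skip-only / skip-plus-cryptic split; an assay population of 10,000 with
6% carriers and no homozygotes.

Scale choices made once: the simulated chromosome spans 1 Mb with a
0.22 Mb shared interval (the real mapped region scaled 1:10 — simulating a
full ~100 Mb bovine chromosome adds nothing to the logic under test), and
marker density matches the ~324-SNP regional panel of the study design.
Within the interval the founder haplotype is transmitted without
recombination; recombination breakpoints are drawn uniformly within a
one-marker-spacing zone at each interval boundary, so the configured
interval is the breakpoint-delimited shared segment, exactly as a mapped
region is delimited in real data.  Candidate decoys are kept a few marker
spacings clear of the interval edges (so the marker-delimited mapped
segment always contains them) and at least 200 bp from the gene (so none
can outrank the causal variant on RNA linkage).  All randomness flows from
one seed through independent per-component streams; identical
configurations give byte-identical outputs.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: realistic linkage disequilibrium and
allele-frequency spectra (marker frequencies are i.i.d. uniform),
recombination maps, genotyping or sequencing error, read-level alignment
artifacts, multi-gene annotation complexity, and population structure
beyond the single half-sib pedigree.  The SAM dialect is minimal: one
reference, one `N` gap per junction read.

## Numerical and degenerate-input conventions

Mb lengths are rounded half-up to one decimal.  Fisher p-values are floored
at 10⁻³⁰⁰ before −log10.  PSI of a zero-coverage exon is NaN (never a
fabricated 0 or 1).  An empty candidate list, an event-free sample, and a
no-qualifying-marker chromosome all return explicit empty results rather
than raising.  Poisson junction depths can produce zero reads; every
consumer gates on read support before calling events.

## Problem sizes used by the test suite

Brute-force oracles run on instances up to 200 markers × 20 samples;
calibration suites use 100 null-scan replicates, 50 PSI-recovery
simulations, and 20 end-to-end seeded studies.  These sizes make the whole
suite run in well under a minute while keeping every stochastic claim at
the stated replication counts.
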