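# Methods

`svdiverge` implements a complete workflow for cataloguing unbalanced
structural variants (SVs) between two chromosome-scale genome assemblies,
genotyping that reference catalogue in a panel of short-read resequenced
accessions, and testing SV allele frequencies for differentiation between
two population groups. This note describes the models and procedures, the
parameters that matter, the synthetic data the package is validated on, and
the numerical choices made where the design was genuinely open.

## Scope and assumptions

The workflow targets *unbalanced* variants — insertions, deletions,
substitutions, and repeat/tandem copy-number changes of >= 10 bp — between
two assemblies with high collinearity. Balanced rearrangements (inversions,
translocations) are out of scope, and between-anchor calling deliberately
considers only colinear, same-strand anchor pairs. Coordinates are 0-based
half-open everywhere internally; VCF output converts to 1-based with an
anchoring base.

Genome A is the coordinate anchor throughout ("A allele" = the sequence
genome A carries at a locus); every record also stores the homologous locus
on genome B, either directly from the alignment or projected through it.

## Discovery

**Inputs.** A whole-genome alignment of genome B (query) against genome A
(target) in PAF with base-level operations (`cs` or `cg` tags; minimap2
`-cx asm5 --cs` is the intended producer), plus the two FASTA assemblies.
Alignment blocks from secondary records or with mapping quality < 30 are
treated as non-unique and skipped with a warning.

**Within-alignment events.** Non-match operations (mismatch runs,
insertions, deletions) are clustered in two passes: ops separated by <= 10
matched bases always join; adjacent clusters closer than 50 bp join only if
each carries >= 5 variant bases. A cluster must contain >= `min_size`
(default 10) variant bases on at least one genome and >= 30% variant
content across its span. Without the content rules, isolated sequencing
errors in long reads masquerade as small "substitutions" and drag the
breakpoints of genuine events. Clusters are typed by their two span
lengths: one side < `min_size` gives a precise indel (pure deletions are
left-normalised through repeated sequence); both sides substantial gives a
substitution when the length ratio is within [0.1, 10] and the two
sequences are unrelated, otherwise a repeat expansion/contraction
(`precise=False`), the decision resting on a shared-k-mer probe between
the two gap sequences and a tandem-periodicity check.

**Between-anchor events.** For consecutive unique anchors on the same
chromosome pair, the signed gaps on the two genomes classify the
intervening event. Identical residue at the gap edges (anchors frequently
stop short of the true junction) is trimmed from both gaps first, which
both fixes typing (a substitution flanked by shared residue otherwise looks
"repeat-like") and restores exact breakpoints. Gap signatures: one side
~zero -> indel; anchor overlap on one genome -> tandem expansion/
contraction; both gaps substantial -> repeat class if repeat-like, else
substitution.

**Gap filtering.** Assembly gaps are runs of >= 10 Ns (configurable; no
published length convention exists). An SV is removed when its anchor or
mate interval spans a gap or lies closer than 50 bp to one, in either
genome.

**Flank validation.** The 5-kb sequences flanking each SV's anchor
interval are searched against the other genome with blastn (database built
once per run). A hit is reliable at alignment length > 50 bp, identity
> 90% and e-value < 1e-10. Both flanks must hit the same chromosome and
strand within 10x the SV size + 20 kb of each other, inner ends facing;
hit inner ends are projected through any unaligned query tail so that
local-alignment trimming does not bias the measured gap. The inter-hit gap
must match the expected allele length on the other genome: absolute
gap-or-overlap < 3 bp for deletions, relative deviation < 20% for
sequence-gaining events.

**Read-based refinement.** Simulated long reads (or any long-read set)
aligned to genome A contribute per-read indel events via the same cluster
machinery, reduced to net simple indels (balanced mismatch clusters are
alignment noise at sub-percent error rates and are dropped; copy-number
clusters reduce to their net length change, left-normalised). Events
co-locating within +/- 20 bp at +/- 20% size across >= 3 reads become one
precise call. A complex (copy-number) assembly call containing read indels
whose net sum explains its copy-number change (within 50%) is replaced by
those precise indels; otherwise it is kept unchanged as the primary
evidence — replacing a large expansion by one incidental 30-bp read call
would discard the event.

**Merging.** Calls merge at >= 50% reciprocal overlap within equivalent
types (expansions count as insertions, contractions as deletions), with
overlap computed on `[start, start + size)` so that point insertions and
copy-number records describing the same sequence can meet the criterion;
assembly coordinates are preferred on a merge. Merging is deterministic,
order-invariant and idempotent.

## Genotyping

Reads are deduplicated at the pair level before alignment: two pairs are
duplicates when both mates agree over the first 90 bp (100-bp reads) or
100 bp (150-bp reads). Alignments (bwa-mem to *both* genomes) are filtered
to <= 3% mismatches of the aligned length, computed as the edit distance
minus cigar indel bases so that a deletion op does not disqualify the very
reads that evidence it.

Evidence is interpreted cross-wise: an accession carrying the A allele
produces split reads on genome B — where its sequence disagrees with the
reference — and clean coverage on genome A. Per allele, the supporting
reads are:

* **split reads** on the genome *not* carrying the allele: reads clipped
  (>= 10 bp) or carrying an indel op (>= 8 bp) with the junction inside
  the locus, padded by the event size — in tandem arrays the aligner can
  place the junction anywhere within the array, so breakpoint placement is
  ambiguous at the event's own scale. Left/right breakpoint counts are
  reported (edge clips are side-specific, interior clips and indel ops
  evidence the whole junction), but the decision uses the number of
  *distinct* supporting reads, since the two per-side counts are not
  independent observations: a cigar indel op evidences both breakpoints at
  once, and junction smearing makes side assignment unreliable exactly
  where per-side thresholds would bite.
* **spanning reads** on the genome carrying the allele: alignments that
  cover the allele's full interval plus 10 bp on both sides with no clip,
  no indel op and <= 3% mismatches. No other allele can produce such a
  read, so spans are as diagnostic as splits; they are only available when
  the interval fits inside a read, and their absence is never treated as
  negative evidence. Span evidence roughly doubles the information per
  allele at heterozygous copy-number loci, where junction-crossing reads
  must traverse the retained array remnant and are scarce at half depth.

An allele is supported when splits + spans >= 3 (`min_split`). A
homozygous call additionally asserts the *absence* of the other allele:
when the unsupported allele still has two or more contrary junction/span
reads (below the support threshold), the genotype is reported undetermined
rather than homozygous — insufficient evidence for heterozygosity is not
evidence of homozygosity. When split support falls short, deletions
>= 50 bp fall back to the read-depth rule:
the allele absent from a genome is supported there when < 50% of the
deleted interval is covered at >= 2x per-base depth while > 50% of at least
one adjacent same-length flank is covered. Support for A only -> genotype
`A`; B only -> `B`; both -> `H`; neither -> `U` (undetermined). The logic
is symmetric: swapping the genome labels swaps A and B calls and fixes H/U.

Depth is deliberately not used for events < 50 bp (no reliable signal below
the read length) and cannot support heterozygotes (the covered haplotype
masks the deleted one).

## Population analyses

The genotype matrix (accessions x SVs, symbols A/B/H/U) feeds four
analyses:

* **Window thinning** for structure analyses: one randomly chosen SV per
  25-kb non-overlapping window, deterministic under the seed.
* **Genotype composition**: per accession, fractions of A/B/H among
  determined calls (U reported separately); group means over accessions.
* **Allele frequencies and differentiation**: SVs determined in >= 50% of
  accessions of both groups are tested. Frequencies count heterozygotes as
  one copy of each allele: freq_A = (2 n_A + n_H) / (2 (n_A + n_B + n_H)).
  Per SV, a 2x2 table of A/B allele counts in the two groups is tested
  with a two-sided Fisher's exact test implemented on exact integer
  hypergeometric weights under the probability-ordering rule — every table
  with the observed margins whose integer weight is <= the observed
  table's weight contributes — so tie handling involves no floating-point
  slack. Raw p-values are Bonferroni-corrected over the number of SVs
  actually tested; an SV is "highly differentiated" at q < 0.001 and
  frequency fold change >= 2, with zero frequencies floored at
  1/(2 x smaller group size) for the fold change.
* **Distance, PCA, tree**: allele-sharing distance is the mean absolute
  dosage difference (A=0, H=1, B=2) over pairwise-complete SVs, scaled to
  [0, 1]; PCA runs on the mean-imputed, centred dosage matrix via SVD with
  deterministic sign convention; a neighbour-joining tree over the
  distance matrix is exported as Newick.

## Annotation and LTR dating

Gene models come from GFF3. An SV hits a gene in category `CDS` when its
interval intersects a coding exon, `intron/UTR` when inside the gene span
otherwise, and `promoter` when inside the 2-kb strand-aware upstream
window (any overlap counts; the window length is a package default, there
being no universal convention). A gene is "affected" when any SV hits its
body or promoter. Genome/gene/CDS coverage fractions are computed on
interval unions, so duplicate calls never double-count.

LTR retrotransposon insertion ages follow T = S / (2 mu): the two long
terminal repeats are identical on insertion and diverge independently at
the per-site annual rate mu (default 1.5e-8), so an element whose LTRs
differ at rate S inserted T years ago.

## The synthetic data generator

All validation runs on synthetic genome pairs with planted events, because
every breakpoint and genotype is then known exactly. Genome A is i.i.d.
sequence at 38% GC; genome B applies the planted events left to right, so
the truth set carries exact breakpoints in both coordinate systems.
Placement uses rejection sampling with a minimum inter-event spacing (10 kb
by default, twice the flank length, so flank validation is unambiguous) and
an edge margin. Event construction per class: deletions/insertions
remove/add random sequence; substitutions replace a segment with unrelated
sequence at a 0.4-2.5x length ratio; tandem events write a 2-copy array of
a 10-60-bp unit into genome A and change the copy number in B; repeat
events use 30-300-bp units separated by 20-bp random spacers. Optional
background divergence (0.5% by default) applies point substitutions to
genome B outside planted loci, emulating independently evolved assemblies
without breaking alignability.

Accession genomes are mosaics on the genome-A backbone: at each planted
locus the allele dictated by a drawn genotype matrix is substituted (one
haplotype for heterozygous calls, both for homozygous). Genotypes are drawn
per locus with a heterozygote fraction (default 0.25) and group-structured
A-allele frequencies (two groups; 20% of loci contrasted at 0.9 vs 0.1 by
default). Paired-end reads are sampled uniformly per haplotype (fragments
N(500, 60), 150-bp mates, substitution errors at 0.5%), with per-read
provenance recorded; long reads are gamma-length single-end reads with the
same error model. Errors are substitution-only by design: the generator
emulates allele structure and coverage, not platform error profiles, so
passing tests demonstrate the logic of the workflow, not robustness to
indel-type sequencing errors, chimeric reads, or the repeat landscape of a
real ~600-Mb plant genome.

## Validation conditions and problem sizes

The package validates itself at desk scale, with all randomness derived
from single seeds:

* **Discovery:** a 2-Mb, 2-chromosome pair with 105 planted events (15 per
  class, 10 bp-10 kb, log-uniform sizes) and zero background divergence,
  aligned with minimap2; the full chain (call -> gap filter -> flank
  validation -> read-based refinement -> merge) is scored against truth.
  Targets: recall and precision >= 95%, breakpoint error <= 10 bp on
  precise events. A copy-number event has no defined breakpoints, so it is
  scored as recovered when the calls inside its array sum to the planted
  net length change.
* **Genotyping:** 12 accessions x 40 SVs on a 600-kb genome at 30x, 0.5%
  read error, 25% heterozygous genotypes (the genome size and 5-kb event
  spacing are package choices; the panel shape, depth and error rate are
  the study conditions). Targets: determined-call accuracy >= 95%, false
  genotype rate <= 1%.
* **Exact test:** the implementation is compared against a brute-force
  oracle (explicit table enumeration with rational arithmetic) over all
  635,376 tables with total <= 60; max |dp| < 1e-12.
* **Differentiation scan:** two groups of 50 with 50 contrasted SVs (0.9
  vs 0.1) among 450 null SVs under Hardy-Weinberg sampling; >= 90% of
  contrasts selected, <= 1 null selected.
* **Determinism:** the demonstration pipeline (250-kb genome, 14 events, 4
  accessions at 20x) is run twice with one seed; the manifests of content
  checksums must be identical. Checksums cover data outputs; BAM/SAM files
  are hashed on alignment records because their headers embed command
  lines with absolute paths, and the log/summary files carry wall-clock
  timers and are not data.

## Known limitations

* Inversions and translocations are not called; anchors on opposite
  strands are ignored.
* Flank validation requires blastn on PATH; whole-genome and read
  alignment require minimap2, bwa and samtools (all orchestrated through
  `svdiverge.pipeline`; the analysis stages consume their outputs).
* The depth rule inherits short-read limits: heterozygous large deletions
  rely entirely on junction evidence.
* Breakpoints inside long tandem arrays are reported left-normalised;
  their physical position within the array is not identifiable from
  alignment evidence.
* The e-value threshold in flank validation is whatever blastn reports for
  its database; with a different alignment backend supplying only identity
  and length, hits of >= 50 matched bases at >= 90% identity on multi-kb
  flanks dominate 1e-10 under any standard Karlin-Altschul
  parameterisation, and the clause is treated as satisfied.
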