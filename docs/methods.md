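# Methods

`mitotail` reimplements, as a tested library, the computational analysis of a
poly(A)-tail capture sequencing assay for mitochondrial mRNA 3' ends, together
with a synthetic amplicon simulator that encodes per-read ground truth.  This
note records the models, conventions, parameter choices and known limitations.

## The assay being modelled

In the wet-lab protocol, a DNA adaptor oligonucleotide is ligated to mRNA 3'
ends, cDNA is primed from an anti-adaptor primer, and PCR with a gene-specific
primer plus the anti-adaptor primer produces amplicons spanning
`gene body ... 3' end ... poly(A) tail ... adaptor`, which are sequenced as
Illumina paired-end reads.  Read 1 therefore runs from the gene-specific
primer toward the tail and carries the capture adaptor
(`ATGTGAGATCATGCACAGTCATA`) as a 3' adapter; read 2 starts at the anti-adaptor
primer (`TATGACTGTGCATGATCTCACAT`, the reverse complement of the capture
adaptor) and reads back across the tail, running into the library adapter
(`CTGTCTCTTATACACATCTGACGCTGCCGACGA`) when the insert is shorter than the
read length.  The pipeline mirrors the published processing chain: adapter
trimming, pair merging, extraction of merged reads with at least three
terminal A's (exact match), poly(A) trimming, alignment to the mitochondrial
reference, and per-position counting of 3'-terminal nucleotides scaled to
reads per 1000 mapped.

Biological context: mitochondrial mRNAs such as MT-ND3 end at a canonical
site whose final templated base is a U completed into a UAA stop codon by
polyadenylation; an alternate 3' end lacking the final three nucleotides
(including that U) cannot form a stop codon by polyadenylation, so the
canonical:alternate ratio and the tail-length distribution are the readouts
of interest when comparing genotypes.

## Simulator

* **Reference.** A uniform-random ACGT sequence (default 2 kb) standing in
  for the 16.5 kb mitochondrial genome; any FASTA can be substituted.  Genes
  are placed as non-overlapping bodies with a 0-based canonical-end
  coordinate on either strand; coordinates are 0-based half-open internally,
  converted only at file boundaries (SAM POS, bedGraph).
* **End-site guard.** By default the canonical terminal base is forced to
  T on the sense strand and the `alternate_offset + 7` sense bases upstream
  of the canonical end carry no A.  This guarantees that neither the exact
  nor the 10%-tolerant poly(A) trimmer can erode templated sequence for
  canonical or alternate-end reads with tails up to ~60 nt (a tolerant
  trimmer accepts a run starting `u` bases upstream only when
  `u - 1 <= 0.1 * (tail + u)` non-A bases fit the budget; with 10 guarded
  bases that requires tails near 90 nt).  Disabling the guard exposes the
  real ambiguity of terminal templated A's, which the tests assert as a
  known bias (called tails inflate and 3' ends shift upstream by exactly
  the templated run length) rather than hide.
* **End usage.** Per read i.i.d. categorical over canonical / alternate
  (default 3 nt upstream in transcript sense) / other (default 7 nt
  upstream), so replicate fractions carry binomial noise as real libraries
  would.
* **Tails.** Fixed, rounded-normal (clipped at `min_length`) or geometric
  length models.  The study-condition presets are wild type = 70% canonical
  with tails ~N(51, 8) and knockout-like = 35% canonical with tails
  ~N(25, 8), echoing the two in vitro constructs (51 nt and 25 nt tails)
  and the direction of the genotype effect (alternate ends up, tails down);
  minimum tail 5 nt so every simulated read is in principle capturable.
* **Errors.** Substitutions i.i.d. per base (default 0; the analysis drivers
  use 0.002, a MiSeq-like rate); an indel option exists but is off by
  default so truth alignment stays unambiguous.  Base qualities are constant
  Q40 — no quality-degradation model, no PCR-duplicate or ligation-bias
  model.

## Preprocessing

Adapter matching is semi-global with unit mismatch cost and no indels
(substitution-only error model; an admissible match needs overlap >= 3 and
mismatches <= floor(0.1 x overlap), the trimming-tool defaults), repeated
two rounds per read so read 2 loses both its 5' anti-adaptor primer and its
3' library-adapter read-through.  Best match = fewest mismatches, then
longest overlap, then leftmost.  A finite-round trimmer of this kind is not
strictly idempotent: a trimmed read ending in a coincidental >= 3-base
adapter prefix would be trimmed again by a further application; this is
inherent to short-overlap trimming and is asserted in the tests.

Merging scores every signed offset of reverse-complement(R2) against R1 by
mismatch count over the overlap (computed as a four-channel
cross-correlation).  A merge is accepted when overlap >= 12, mismatch
fraction <= 0.1, and the best candidate beats the runner-up by >= 2
mismatches (ambiguity guard); these values are conservative defaults chosen
because the published pipeline names no merge parameters.  Disagreements
resolve to the higher-quality base, ties to R1.  Overhangs incompatible
with the forward/reverse amplicon architecture — revcomp(R2) extending 5'
of R1's start, or R1 extending 3' of R2's anchored insert end — are 1–2 nt
adapter read-through relics below the trimmer's minimum overlap and are
clipped, as FR-aware mergers do; without this, tail lengths landing the
read end 1–2 nt inside an adapter would be called 1–2 nt long.

## Tail calling

Extraction requires the final three bases to be exactly `AAA` (zero-error,
matching the published extraction step).  The default trimmer removes the
maximal exact terminal A-run, which is exact on substitution-free tails and
keeps `body + A^tail == read` as an invariant.  The error-tolerant mode
(flag) takes the longest suffix that starts with an A and contains at most
10% non-A bases; it absorbs isolated substitutions inside long homopolymers
(without it, a substitution in the tail truncates the called tail and
leaves untemplated A's on the body, pushing the read's apparent 3' end
downstream).  The published pipeline's poly-A trimmer is likewise a
mismatch-tolerant heuristic whose exact internals are undocumented; the
exact-run default was chosen here because it is deterministic and provably
correct on the simulator's error-free output.

## Alignment

Reads are anchored by exact 16-mer seeds (every 4 positions plus the final
one) on both strands, seed diagonals are clustered within the band width,
and each candidate is scored by a banded affine-gap dynamic program (band
half-width 12) that aligns the whole read against a local reference window
(glocal; no soft clipping), with sentinel padding at reference edges so the
band stays centred.  Scoring: +2 match, -3 mismatch, -5 first gap base,
-2 per additional gap base; mapped means best score >= 0.6 x (2 x read
length).  Ties on score break to the leftmost reference start, then the
plus strand, and are flagged non-unique; non-unique alignments are excluded
from end mapping (conservative; a mitochondrial-sized non-repetitive
reference makes them rare).  If no 16-mer seed survives the read's errors,
an 8-mer rescue pass re-seeds before declaring the read unmapped.  The
tests hold this implementation equal, case by case, to an independent
exhaustive affine-gap DP over every reference offset (Biopython's
PairwiseAligner in fitting mode) on 1000+ randomized mutated reads.
Limitations: the reference is treated as linear (the assayed 3' ends are
internal, so origin-spanning reads do not arise), there is no soft-clipping
mode, and scoring ignores base qualities.

## End mapping

A read's 3'-terminal templated position is `ref_start + reference_span - 1`
on the plus strand and `ref_start` on the minus strand (the alignment's
left edge is the transcript's 3' terminus in reference coordinates — the
generalisation of the published offset-from-5' arithmetic to both strands).
`reference_span` sums M/D/N/=/X CIGAR lengths.  Each mapped, unique,
tail-trimmed read contributes one count at its 3' position; counts are
scaled by 1000 / total mapped reads of exactly that extracted subset, so
the track sums to 1000 whenever anything mapped.  bedGraph output is
0-based half-open with zero rows omitted.  Classification is exact
(tolerance 0 nt by default, configurable): canonical at the annotated end,
alternate at `alternate_offset` upstream in transcript sense, other
elsewhere; canonical wins if a positive tolerance makes the windows
overlap.

## Statistics

Per-replicate metrics (canonical/alternate/other fractions, tail mean /
median / mode / SD) feed a classic equal-variance two-sample Student's t
test, two-tailed, with pooled SD and n1 + n2 - 2 degrees of freedom
(Welch available via flag); with both groups constant and equal the
degenerate comparison reports t = 0, p = 1.  No multiple-testing
correction by default.  Tail mode ties break to the smallest length; SD
uses ddof = 1 (0 for a single read).

Calibration and power are checked at the truth-generator level (replicate
end-usage fractions drawn at n = 10,000 reads per replicate, triplicates):
the null rejection rate of the t test at alpha = 0.05 sits near 0.046 over
repeated three-vs-three comparisons, and the knockout-vs-wild-type presets
give correctly signed differences essentially always.  Running those 400+
repetitions through full read simulation would add nothing to the property
under test (the comparison machinery), so the read-level pipeline is
exercised by the recovery tests instead.

## Problem sizes

Test and driver workloads are sized for a single CPU: 300–10,000 read pairs
per simulated library, 2 kb toy references, 1000 randomized alignment
oracle cases, 400 null-calibration repetitions, and triplicate 2,000-pair
libraries in the analysis drivers.  All are the package's own defaults and
reproduce deterministically from fixed seeds.

## What passing tests do and do not show

The simulator emulates amplicon structure, end-site mixtures, tail-length
distributions and substitution noise; it does not model PCR duplicates,
ligation bias, quality decay, indels (by default), or templated-A ambiguity
(guarded by default, asserted as a bias when enabled).  Exact recovery on
error-free synthetic data and calibrated behaviour at MiSeq-like error
rates therefore validate the pipeline's logic and conventions, not its
robustness to every artefact of real libraries; with real data, the
canonical/alternate calls additionally depend on annotation correctness
and on the tolerant trimmer's behaviour at templated A runs.
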