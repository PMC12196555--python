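# Methods

## Coordinate conventions

CDS positions are 1-based inclusive with the A of the start codon at
position 1, so nucleotide *p* lies in codon ⌈*p*/3⌉ (position 692 → codon
231, position 524 → codon 175). Genomic intervals are 0-based half-open
internally; GFF3 input (1-based inclusive) and BED6 output (0-based
half-open) are converted at the I/O boundary. Distances to a CDS window
[s, e] are `s − p` upstream and `p − e` downstream, 0 inside.

Shared-exon queries require identical genomic intervals across every
predicted isoform, not mere overlap: an exon common to all transcripts is
the safe place to cut if the goal is disrupting every isoform. Soft-masked
(lowercase) genome bases are uppercased on read; masking is not tracked.

## ZFP assembly

A three-finger array is assembled as

```
N-terminus + [backbone_n + helix + backbone_c] x3 (joined by linker) + C-terminus
```

with constants `LEPGEKP`, `YKCPECGKSFS`, `HQRTH`, `TGEKP`, `TGKKTS`,
giving 7 + 3×23 + 2×5 + 6 = 92 aa. The constants are a frozen dataclass
and configurable only by explicit override.

Finger-to-triplet assignment is an explicit parameter because the two
conventions both occur in practice: `as_listed` assigns F1..F3 to the
half-site triplets 5′→3′; `antiparallel` assigns F1 to the 3′-most triplet,
the structural convention for Cys2His2 arrays (the N-terminal finger
contacts the 3′ end of its site). The published NF-YA8 arrays list the
left array 5′→3′ and the right array 3′→5′, so `design_pair` defaults to
`as_listed` for the left and `antiparallel` for the right, reproducing
both printed helix orders. The seeded helix table carries exactly the six
published triplet→helix entries; other triplets come from a user-supplied
table file, never from prediction.

The published figure gives a left binding sequence (5′-CCCATCTCG-3′,
bottom strand) that is not the reverse complement of the methods'
left half-site 5′-GCTCTACCC-3′; the methods values are taken as
authoritative for all design operations.

## Codon optimization

CAI follows Sharp & Li: the geometric mean of relative adaptiveness
*w* = frequency / max synonymous frequency, over informative codons only
(ATG, TGG and stops excluded; a terminal stop is permitted). Codons absent
from a usage table get a pseudo-count of 0.5 before *w* is computed, so
every *w* is strictly positive and the most-used codon of each family has
*w* = 1. CAI is invariant under rescaling the table, so per-thousand and
fractional tables behave identically.

Reverse translation is greedy (highest-*w* codon per residue, alphabetical
tie-break) followed by local repair: each forbidden-motif occurrence —
checked on both strands of the full flanked sequence, with the flanks
themselves exempt — triggers a search over synonymous codon combinations
in a window covering the occurrence (2 codons, widened to 4 when stuck),
tried in order of decreasing CAI contribution, accepting the first
combination that removes the violation without creating a new one nearby.
For proteins of ≤ 4 residues the widened window spans the whole protein,
so the result provably equals the exhaustive-search optimum (tested
against an independent enumeration oracle). Defaults mirror the published
construct: XbaI (`TCTAGA`) and BamHI (`GGATCC`) both as forbidden internal
motifs and as the 5′/3′ flanks. The published mRNA-half-life optimization
is represented only by the CAI criterion; no secondary-structure model is
attempted because no procedure is given.

## Off-target enumeration and scanning

A composite pattern is `9-mer + N^spacer + 9-mer`. The default arrangement
set enumerates every dimer geometry of the pair: the four tail-to-tail
composites `revcomp(A) + spacer + B` for ordered (A, B) ∈ {L, R}² — the
canonical FokI orientation, `Lrc-R` being the designed site — plus the
four head-to-head composites `A + spacer + revcomp(B)`. Each four-set is
closed under reverse complement, so a single-strand text scan still finds
bottom-strand sites; for distinct non-palindromic half-sites all eight are
distinct, giving 8 × 7 = 56 patterns over the default spacer range 4–10.
This scheme is a reconstruction: the published count (56) is printed
without its derivation, and both the arrangement set (a small grammar over
L, R, Lrc, Rrc with an `rc:` composite prefix) and the spacer range are
configurable if the original enumeration differed.

Scanning compares every pattern at every offset on both strands
(vectorized over offsets), counting mismatches only at the 18 half-site
positions; spacer Ns match anything, and an N in the genome never matches
a concrete pattern base (conservative screening). All matches within the
budget are reported, including overlapping ones — screening must be
exhaustive — sorted by (contig, start, strand, pattern id). Note that the
default pattern set is strand-closed, so a physical site is reported twice
(once per strand representation); hits carry their pattern id to make this
transparent. Variation is 100 × mismatches/18, the scale on which the
published off-target candidates span 11–44%.

Context extraction reports the upstream flank, match and downstream flank
separately (strand-oriented, clipping flagged) rather than a fixed 200-bp
block, removing the ambiguity of whether "200 bp" includes the match; the
headline number is the combined flank length 100 + 100 = 200 nt.

## Genotyping

Clones are globally aligned to the reference CDS with Biopython's
`PairwiseAligner` (match 2, mismatch −1, gap open −4, gap extend −1; a gap
of length L scores open + (L−1)·extend). These are conventional scores for
short, high-identity amplicons; ties among co-optimal alignments resolve
to the aligner's first traceback, which is deterministic for fixed inputs.

Maximal runs of difference columns become calls: a single substitution
column is an SNV; a pure gap run is an insertion or deletion, left-aligned
within homopolymer/repeat context (VCF-style, without crossing a previous
run); anything mixed — including adjacent substitutions, which cannot be a
single-base SNV — is complex. Insertions are anchored to the reference
position *after* which they occur (0 = before the first base), which makes
edit application exactly invertible: applying the calls to the reference
reconstructs the clone byte-for-byte (property-tested).

Consequences are computed by applying the edits and translating both
sequences in frame: frameshift iff the net indel length mod 3 ≠ 0; a stop
codon strictly before the mutant's own final codon is a premature stop
(loss of function) — a terminal stop that is merely earlier than the
reference's, as after an in-frame deletion, is not; otherwise in-frame
indel, missense (reported `231A>V` when one codon changes) or synonymous.

Spectrum summaries assign each clone one primary category with precedence
complex > indel > SNV (the published percentages sum over sequences); a
per-mutation tally is available behind the `counting` flag, since the
source phrasing is ambiguous between the two. Frameshift and LOF
percentages are overlapping per-clone annotations, not partition members.
Percent identity counts identical columns over all alignment columns
(gap columns in the denominator; configurable).

## Quantification utilities

Fold change is plain 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator;
no amplification-efficiency correction. The long-format helper averages
technical replicates before ΔCt. Percent change is (m − wt)/wt × 100 with
wt ≠ 0 enforced.

## Synthetic fixtures

`make_synthetic_genome` draws uniform-composition background (no GC
model — the simplest null, and chance matches to a ≥ 20-nt composite are
negligible at desk scale), fills planted spacers with random bases,
corrupts requested half-site positions with a different base, writes
minus-strand plants reverse-complemented, and emits a truth table of
intervals, strands and mismatch counts. Overlapping or out-of-bounds
plants are errors.

`make_mutant_clones` draws one primary edit per clone (multi-edit sets
behind a flag) from configured category proportions, at positions drawn
from configured CDS windows. Defaults emulate the published clone
analysis: 51.5% SNV / 39.4% indel / 9.1% complex; windows 689–713 (the
nuclease target site) and 873–935 (the downstream indel hotspot); indel
lengths (1, 2, 3, 6) with probabilities (0.4, 0.2, 0.3, 0.1), putting the
frameshift fraction of indels at 0.6, near the published ratio of
frameshift-inducing indels to all indels (24.2/39.4). Generated indels are
left-normalized so truth coordinates match downstream calls. Complex
events replace a 2-nt run with a 1- or 3-nt run whose bases are absent
from the 6-nt local context, drawn at positions free of adjacent repeats —
this guarantees the event re-aligns as one mixed run, so alignment-based
calls equal the generated truth exactly; if a narrow window offers no such
position the draw falls back to an unconstrained replacement. Truth
consequences are classified from the generated edits directly, a path
independent of the alignment-based calling being tested.

What passing fixture tests show — and do not show: the generators have no
sequencing error, chromatogram artifacts, heterozygous mixtures or
compositional bias, so they validate the calling/classification logic and
coordinate arithmetic, not robustness to noisy real amplicon data. The
published clone statistics (identity range 86.9–98.21%, the exact spectrum
over its > 90 clones) are not reproducible without the undeposited
sequences; they enter only as generator defaults and anchors.

## Problem sizes and determinism

All generators take explicit seeds and are bit-reproducible. The test
suite uses fixture genomes of 1–20 kb (scanner correctness is verified
against a brute-force all-offsets oracle at these sizes, 100 random
fixtures) and clone sets of up to 500 (spectrum recovery within ±4
percentage points, the binomial sampling bound at n = 500). These sizes
were chosen so the whole suite exercises every oracle comparison in well
under a minute each; the scanner itself handles chromosome-scale FASTA
linearly and has no fixed upper size.

## Known limitations

- No zinc-finger affinity or cleavage-likelihood model; helix coverage is
  table-driven, not predictive.
- No gapped (alignment-based) off-target search and no BLAST verification;
  hits carry flanking context for external tools.
- Genotyping assumes clean single-sequence clones (no mixed-trace
  deconvolution, no chromatogram base-calling).
- The spacer length of the published design (7 nt) is inferred from the
  25-nt target window (9 + 7 + 9), not stated explicitly; the spacer range
  is configurable everywhere it appears.
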