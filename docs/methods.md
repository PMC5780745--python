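# Methods

## Model and procedure

Plant phasiRNAs are produced when a miRNA-guided cut on a precursor
transcript defines a 5' end from which DCL enzymes dice double-stranded
RNA into consecutive 21-nt (DCL4) or 24-nt (DCL5) duplexes. The 5' ends
of the resulting small RNAs therefore fall on a lattice: they share a
residue class mod the cycle length *p* (the *register*) counted from the
cleavage position. Dicer duplexes carry 2-nt 3' overhangs, so the
antisense strand of each duplex starts two nucleotides to the left of its
sense partner; `phasfinder` folds both strands onto one lattice by
assigning every antisense read an *effective position* of `start + 2`.

The scan proceeds per transcript:

1. **Windows.** Candidate windows span *m* consecutive cycles (*p·m* nt;
   *m* = 10 by default, i.e. 210 or 240 nt) and are anchored at every
   distinct effective position of a length-*p* read whose window fits on
   the transcript. Anchoring only at read 5' ends is result-equivalent to
   anchoring at every nucleotide — a window whose anchor carries no
   in-register read has *k* = 0 and can never become significant — at a
   fraction of the cost.
2. **Phasing P-value.** Within a window, *n* is the number of distinct
   occupied effective positions of length-*p* reads and *k* the number of
   those in the anchor's register. Under the null that occupied positions
   are exchangeable across the *p·m* positions of which *m* are
   in-register, the P-value is the hypergeometric upper tail
   `P(X >= k) = sum_{x=k..min(m,n)} C(m,x) C((p-1)m, n-x) / C(pm, n)`,
   computed with `scipy.stats.hypergeom.sf` (the test suite checks it
   against an exact-rational enumeration to 1e-12 over a (k, n, p) grid).
   Counting *positions* rather than unique sequences keeps the model's
   domain coherent: a sense read and its antisense duplex partner occupy
   one phase position, so k can never exceed min(n, m). Reads of any
   other length are invisible to the statistic.
3. **Phase score.** For windows with at least `min_unique_phased` = 3
   occupied in-register positions,
   `score = (k - 2) * ln(1 + 10 * sum(P_i) / (1 + sum(U_i)))`, where
   `sum(P_i)` / `sum(U_i)` are the raw read-count abundances of
   in-register / off-register length-*p* placements in the window.
   Raw summed counts are used (per-library counts are carried for
   reporting only); below the gate the score is reported as 0.0, not
   missing, so thresholding is total. The score is monotone
   non-decreasing in k and in-register abundance and non-increasing in
   off-register abundance.
4. **Extension, merging, FDR, calling.** Windows with raw P < 0.05
   (`extend_p`) are widened by 100 nt (`extension`) on each side, clipped
   to the transcript, and transitively overlapping intervals are merged.
   Each merged region keeps its minimum raw P — taken as the region's
   test statistic — and the anchor of its maximum-score window, whose
   residue defines the locus register. Benjamini–Hochberg correction runs
   jointly over the merged regions of all transcripts. Regions with max
   score >= 5 (`min_phase_score`) and corrected P < 0.05 (`alpha`) become
   loci, named `P{p}_{transcript}_{serial}` with serials per transcript
   in coordinate order ('|' in transcript ids becomes '_'). The 21- and
   24-nt scans run independently; one transcript may host both kinds.
5. **phasiRNA extraction.** All length-*p* reads inside a locus whose
   effective position matches the locus register are reported as
   phasiRNAs, serial-named 5'→3' (`{locus}_siR{serial}`), sense before
   antisense at equal positions.

## Alignment and ingest

Small-RNA reads are collapsed to unique sequences with summed counts.
FASTQ reads containing any base below Q20 are dropped whole before
adapter handling; the 3' adapter is located as the leftmost exact match
of its first 8 nt and removed; reads outside 18–30 nt are discarded.
Collapsed-FASTA abundance suffixes `_x<INT>` and `-<INT>` are
auto-detected. Alignment to the transcriptome is exact, full-length and
ungapped on both strands, with multi-mapping reads counted in full at
every location (`--multimap unique` keeps one placement per read).
Mismatched or gapped alignments are excluded so the phasing register
stays well-defined; SAM import accordingly keeps only `NM:i:0`
single-`M` records, restoring antisense reads to their original
orientation. SAM carries no abundance field, so imported records count 1
unless the read name carries a collapsed-count suffix.

## Degradome, triggers and targets

Degradome (PARE) tags mark uncapped 5' ends of the sense strand. After
the same Q20/adapter QC, the 5'-most 20 nt of each tag (configurable) is
exact-matched to the transcriptome and its count tallied at every match
position. Candidate sites tie a small RNA to a transcript by ungapped
complementarity on either strand; small-RNA position *j* (1-based from
the 5' end) pairs transcript position `site_end - j`, mismatches are any
non-Watson-Crick pair, and G:U wobbles count 1 by default (0.5 via
`gu_weight`). A site's *valid reads* are the degradome counts opposite
small-RNA positions 9–11; the inferred cleavage position is opposite
position 10 (slicing occurs between 10 and 11). Antisense sites have no
defined degradome support (the assay sequences the polyadenylated
strand) and report 0 with a flag.

Trigger calling scans each miRNA against every PHAS transcript up to 6
mismatches and keeps sites with >= 1 valid read **or** < 4 mismatches
(conserved miRNA/target pairs are trusted on pairing alone). A trigger
site is flagged *register-consistent* when its inferred cleavage position
lies within 1 nt of the locus register lattice — the tolerance absorbs
the 10-vs-11 slicing convention while remaining discriminative (a
register offset is 1 in p-1 likely by chance). PhasiRNA target calling
uses the stricter conjunction: >= 1 valid read **and** < 4 mismatches,
with cis/trans assigned by whether the target transcript is the
phasiRNA's own precursor. Only these stated filters are implemented; no
gapped alignment or target-site scoring model beyond mismatch counting
is applied.

## Synthetic data

The simulator emulates the one-hit model: it implants a trigger-miRNA
complementary site (22 nt, 2 mismatches placed outside positions 9–11 by
default), sets the cleavage position opposite miRNA position 10, and
lays `duplexes_per_locus` = 6 duplexes head-to-tail downstream with
geometrically decaying abundance (top count 20, ratio 0.7) and antisense
partners present with probability 0.5 at the 2-nt overhang offset.
Background reads (2 per transcript, lengths drawn from {20, 21, 22, 24}
to exercise the length filter, half of them off-register inside locus
regions — noise:signal about 0.2) land uniformly; the degradome carries
a peak of 50 at the cleavage site over Poisson background with mean 5
per position (peak:background 10:1). Transcripts are i.i.d. random
sequences at GC 0.42. Given a fixed seed the emitted files are
byte-identical.

What the simulator does **not** model: expression structure, sequencing
error, RNA secondary structure, two-hit triggering, spreading of phasing
out of the diced region, or repetitive/paralogous sequence families.
Passing recovery tests therefore demonstrate correctness of the
statistics and bookkeeping on clean one-hit loci, not sensitivity on
real libraries, where multi-mapping, register drift and partial dicing
make calls harder.

## Problem sizes and numerical choices

The bundled recovery experiment uses 200 replicates of 5 transcripts
(0.8–2 kb) with one implanted 21-nt locus each; the null control places
50 random 21-mers on each of 500 2-kb transcripts and requires loci on
at most 1% of them. Both finish in well under a minute on one CPU.
P-values are floats from scipy's hypergeometric survival function; the
score uses `log1p` for stability. Ties for the best-scoring window in a
region break toward the leftmost anchor. Degenerate inputs are handled
explicitly: empty read sets yield empty results (exit 0 in the CLI), a
window that does not fit the transcript is never formed, and k = 0
returns P = 1 exactly.

## Known limitations

- Exact-match alignment only; SNP-bearing or edited reads are dropped,
  which on real data deflates abundances rather than shifting registers.
- The merged-region P-value is the minimum member-window P; no
  recalculation over the merged extent is attempted.
- Degradome support is single-nucleotide exact; smeared cleavage peaks
  spread across neighbouring positions only count within the 9–11
  window.
- cis/trans classification in the CLI compares sanitized transcript ids
  (the loci table cannot recover '|' characters lost in locus names).
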