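# Methods

## Model of the problem

Targeted sequencing QC asks, for every base of every target region, whether
enough *trustworthy* evidence exists to call a variant there. `panelqc`
treats the BAM pileup as the object of study and separates three failure
axes that raw depth conflates: depth of coverage (COV), base-calling
confidence (MEDBQ/FLBQ) and mapping confidence (MEDMQ/FLMQ). The composite
QCOV — reads that pass both Phred cutoffs at the position — is the quantity
clinical thresholds are set on, because a position can be deep and still
uncallable when its reads are ambiguously mapped or poorly base-called.

## Counting semantics

The decisions below fix every ambiguity in pileup counting; the test-suite
oracle re-derives all of them independently by exhaustive iteration.

* **Eligible reads**: mapped, primary (not secondary 0x100, not
  supplementary 0x800), not QC-fail (0x200). Duplicates (0x400) are
  included by default and excluded when `count_duplicates = false`;
  exclusion is exactly equivalent to physically removing duplicate records.
  QC-fail reads are excluded on the view that a vendor-failed read should
  not contribute clinical evidence.
* **Coverage**: aligned match/mismatch bases (CIGAR M/=/X) and spanning
  deletions (D) cover a position; soft clips, insertions and N skips do
  not. N is treated unlike D deliberately: N denotes absent sequence
  (splicing), D asserts a deletion allele whose flanking read still spans
  the locus.
* **Deletion-spanning reads** count toward COV, MEDMQ and FLMQ (the read
  covers the position) but contribute no base, so they are absent from
  MEDBQ/FLBQ and can never satisfy QCOV — QCOV requires a base passing the
  BQ test, and a deleted base has none.
* **Inclusive cutoffs**: BQ ≥ `bq_cutoff` and MQ ≥ `mq_cutoff` pass; "low"
  in FLBQ/FLMQ means strictly below. MQ 255 means *unavailable* per the SAM
  specification: it fails any positive `mq_cutoff` (an unknown quality must
  not silently pass a clinical threshold) and is counted in FLMQ's
  numerator, while its stored value still enters MEDMQ, which summarises
  the values as recorded.
* **FLMQ's denominator** is all covering reads, deletion-spanners included.
* **Overlapping mates** of one fragment count as two independent reads; no
  fragment-level deduplication is attempted.
* **Medians**: the median of an even-sized multiset is the arithmetic mean
  of the two middle values. The engine computes medians from per-position
  quality histograms (BQ 0–93, MQ 0–255), which makes them exact integers
  or half-integers; outputs round to one decimal.
* **Undefined values**: every ratio or median is undefined (NaN internally,
  `.` in outputs) exactly when its denominator is empty.
* **RC** (region read count) is an overlap count over the read list, not a
  profile reduction: a read whose reference span touches the region by one
  base counts even if (e.g. fully soft-clipped ends) it contributes no
  aligned base.

## Flagging

Any region summary metric can carry a minimum or maximum threshold. A
minimum bound fails when the metric is strictly below it; a maximum bound
when strictly above. Undefined values fail minimum bounds (no evidence of
sufficient coverage — conservative for clinical review) and pass maximum
bounds (no evidence of low quality). FLAG iff at least one criterion fails.
This makes flagging monotone: tightening a minimum can only convert PASS to
FLAG.

## Chromosome accounting

A read is on-target iff its reference span (alignment start to end,
including deletions and N skips) overlaps any target region on its
chromosome, tested against a per-chromosome interval tree; a read
overlapping several regions counts once. Only primary alignments are
counted, so each template end contributes exactly one count and RC cannot
be inflated by secondary records. Unmapped reads appear only in the
genome-wide totals row. Placed-but-unmapped mates are counted as unmapped,
not toward any chromosome's RC.

## Transcript coordinates

Poor-quality intervals (maximal runs with QCOV < `qcov_poor_cutoff`,
default 15) are annotated with simplified HGVS-like c. coordinates:
coding positions `c.N`, UTRs `c.-N`/`c.*N`, intronic positions anchored
`+k` to the upstream exon in the 5' half of the intron and `-k` to the
downstream exon in the 3' half, with the exact midpoint anchoring upstream.
This is coordinate localization only — no repeat/duplication normalisation
and no protein-level notation — which is sufficient to state whether an
interval hits coding sequence. When several transcripts overlap an
interval, all are reported. Without a transcript database the intervals are
still reported with genomic coordinates and empty annotations.

## Configuration defaults

| parameter | default | unit / meaning |
|---|---|---|
| `bq_cutoff` | 10 | Phred; P(wrong base) ≤ 10% passes |
| `mq_cutoff` | 20 | Phred; P(wrong locus) ≤ 1% passes |
| `qcov_poor_cutoff` | 15 | reads; minimum credible evidence for a call |
| `count_duplicates` | true | duplicates carry coverage signal for capture QC |
| `direction` | false | strand-split output doubles cost, off unless needed |
| `profiles` | all | per-base output can be restricted to flagged regions |

The BQ 10 / MQ 20 / QCOV 15 defaults mirror common clinical panel practice;
the worked example's MINQCOV ≥ 50 pass rule is a stricter laboratory
requirement layered on top via the flag criteria, not a built-in.

## Synthetic data

The fixture generator (`panelqc.fixtures`) writes real sorted, indexed BAM
files from declarative read specifications, because most bugs in this class
of tool live in flag and CIGAR semantics at the file boundary rather than
in arithmetic. Two generators are used:

* **Randomized fixtures**: up to 3 regions of 5–60 bp and up to 100 reads
  with CIGARs drawn from plain matches, match–deletion–match,
  match–insertion–match and soft-clip variants; MQ values straddle the
  cutoff and include 0 and 255; BQ values straddle 10; duplicate,
  secondary, supplementary and QC-fail flags appear at low rates. These
  sizes keep exhaustive brute-force verification exact and fast while
  exercising every counting rule.
* **The five-region panel** (seeded, deterministic): a deeply covered clean
  region (~130×), a pseudogene-style region (400 reads, 90% at MQ 0 — high
  COV, collapsed QCOV, FLMQ ≈ 0.9), a zero-coverage dropout, a
  forward-only region, and a region where half the covering reads carry a
  fixed 20 bp deletion; plus off-target and unmapped background reads. Read
  depths are set so that the intended PASS/FLAG outcome under MINQCOV ≥ 50
  holds with wide margin for any seed.

What the synthetic data does **not** emulate: sequencing error profiles,
GC/homopolymer context, fragment-size distributions, mate pairing, real
capture efficiency or reference bases (all reads carry a poly-A sequence —
the metrics never read the bases themselves, only their qualities). Passing
tests therefore demonstrate correct *counting semantics and file handling*,
not calibrated behaviour on any particular instrument's data.

## Verification strategy

The central acceptance property is exact equivalence between the engine and
an independent brute-force oracle (`panelqc.oracle`) that recomputes every
per-base and summary metric by nested iteration over reads × positions
using plain Python and `statistics.median`, sharing no code with the
engine. The suite checks this on 200 seeded random fixtures, alongside
conservation identities (QCOV ≤ COV, strand splits summing to the unsplit
profile, RCIN + RCOUT = RC, mapped + unmapped = total), monotonicity of
QCOV in both cutoffs and of flagging in thresholds, duplicate-toggle
equivalence against physically deduplicated BAMs, and exhaustive per-base
agreement of the c. coordinate mapper with enumeration tables on two toy
two-exon transcripts (one per strand, with UTRs). Agreement is asserted
exactly — integer counts, rational fractions and half-integer medians admit
no tolerance.

## Known limitations

* No CRAM input; no BAQ recalibration; no per-fragment overlap-aware
  counting (overlapping mates double-count, as in read-level pileups).
* Whole-BAM chromosome accounting streams the entire file once; per-base
  profiling cost scales with panel size × depth. The engine holds one
  region's quality histograms in memory at a time (length × 350 ints).
* c. coordinates assume coding transcripts with consistent exon/CDS
  annotation; non-coding transcripts (n. numbering) are not supported.
* Gene grouping of regions relies on the `GENE_EXON` naming convention
  (text before the last underscore); names without underscores group as
  themselves.
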