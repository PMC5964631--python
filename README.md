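# panelqc

Coverage, base-quality and mapping-quality QC for targeted NGS panels.

Clinical gene-panel sequencing needs more than average depth of coverage: a
variant call is only trustworthy where enough reads cover the position *and*
those reads are well mapped and well base-called. Insufficient depth drives
false negatives; regions of high homology (pseudogenes) produce deep but
ambiguously mapped pileups where calls cannot be trusted at any raw depth.
`panelqc` evaluates a coordinate-sorted, indexed BAM against a BED file of
target regions and reports quality metrics at three resolutions — per base,
per region, per chromosome — and flags every region that fails user-declared
quality requirements, so suboptimal data is surfaced for review
automatically instead of by ad-hoc inspection.

## Metrics

Per base (for every position of every target region):

| metric | definition |
|---|---|
| COV   | mapped reads covering the position |
| MEDBQ | median Phred base quality of read bases aligned to the position |
| FLBQ  | fraction of those bases with BQ below the BQ cutoff |
| MEDMQ | median mapping quality of covering reads |
| FLMQ  | fraction of covering reads with MQ below the MQ cutoff |
| QCOV  | "quality coverage": covering reads with MQ ≥ mq_cutoff contributing a base with BQ ≥ bq_cutoff |

Per region: RC (reads overlapping the region), MEDCOV, MINCOV, MEDQCOV,
MINQCOV (medians/minima of the COV and QCOV profiles), MAXFLMQ, MAXFLBQ
(worst positions). A minimum or maximum threshold may be set on any of these;
a region violating any threshold is tagged **FLAG**, otherwise **PASS**.
Defining such minimum requirements (e.g. *every base covered by ≥ 50 reads
with MQ ≥ 20 and BQ ≥ 10*, i.e. MINQCOV ≥ 50) is the basis of a Quality
Sequencing Minimum for clinical pipelines.

Per chromosome: total mapped reads (RC), on-target (RCIN) and off-target
(RCOUT) counts, plus genome-wide mapped/unmapped/total counts — quantifying
how much sequencing is useless for calling variants inside the panel.

Maximal runs of positions with QCOV below a cutoff (default 15) are reported
as *poor-quality intervals*, localized in simplified transcript coordinates
(`c.N`, `c.N+k`, `c.-N`, `c.*N`) against a user-supplied transcript database.

All profiles and region summaries can additionally be computed for forward
and reverse reads separately to expose strand-specific biases.

## Worked example

`examples/evaluate_panel.py` builds a small synthetic panel containing the
canonical failure modes and applies the MINQCOV ≥ 50 rule:

```
region          RC  MEDCOV  MINCOV  MINQCOV  MAXFLMQ  status
GOODGENE_1     400   138.0     123      123    0.000  PASS
PSEUDO_2       400   159.5     135       12    0.924  FLAG
EMPTY_3          0     0.0       0        0        .  FLAG
FWDONLY_4      300   123.0     114      114    0.000  PASS
DELGENE_5      180   117.0      34       34    0.000  FLAG

3 of 5 regions flagged.
```

`PSEUDO_2` is the instructive row: every base is covered by at least 135
reads (MINCOV=135), yet at the worst position only 12 reads are of good
quality (MINQCOV=12) because 92% of covering reads there fall below MQ 20
(MAXFLMQ=0.924) — the signature of pseudogene homology, where raw depth is
deceptively reassuring. `EMPTY_3` is a dropout, and `DELGENE_5` fails
because coverage thins at its edges and a common deletion removes aligned
bases from its core. The other examples print a per-base profile
(`examples/per_base_profile.py`) and poor-interval transcript annotation
(`examples/poor_intervals_and_transcripts.py`).

## Command line

```
panelqc --input sample.bam --bed panel.bed --config run.ini --output out/sample
```

writes four tab-separated files (`out/sample_summary.txt`, `_regions.txt`,
`_profiles.txt`, `_poor.txt`), each with a single `#` header line and `.`
for undefined values. The INI config (all sections optional):

```ini
[quality]
bq_cutoff = 10          ; Phred base-quality threshold (inclusive)
mq_cutoff = 20          ; Phred mapping-quality threshold (inclusive)
qcov_poor_cutoff = 15   ; QCOV below this defines poor intervals
count_duplicates = true ; include duplicate-flagged reads
direction = false       ; strand-split profiles and summaries

[flags]
MINQCOV_min = 50        ; <METRIC>_min / <METRIC>_max on any region metric
MAXFLBQ_max = 0.2

[outputs]
profiles = all          ; all | flagged | none
poor = true
transcript_db = transcripts.txt
```

BED input is 0-based half-open; all output coordinates are 1-based
inclusive. Chromosome naming ("chr7" vs "7") is never auto-reconciled — a
BED/BAM mismatch produces all-zero profiles with an explicit warning.

## Transcript database format

Tab-separated, one coding transcript per line:

```
id  gene  chrom  strand  coding_start  coding_end  exon_starts  exon_ends
```

`exon_starts`/`exon_ends` are comma-separated 0-based half-open genomic
coordinates in genomic order; `coding_start`/`coding_end` are the 0-based
genomic positions of the first and last coding base in transcript 5'→3'
order (so `coding_start > coding_end` on the minus strand).

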