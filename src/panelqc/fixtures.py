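"""Synthetic BAM/BED/transcript fixtures with fully known per-base truth.

Real (sorted, indexed) BAM files are generated from declarative
:class:`ReadSpec` lists so that flag handling, CIGAR walking and index I/O
are exercised end-to-end, not mocked — most coverage-QC bugs live in
pileup/flag semantics at the file boundary. Generation is pure in the seed.

The fixtures make no attempt at read-simulator realism (no error model, no
fragment-size distribution): they are exact, enumerable inputs for testing
counting semantics.
"""

from __future__ import annotations

import random
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pysam

from .regions import TargetRegion, write_bed

__all__ = [
    "ReadSpec",
    "build_bam",
    "random_fixture",
    "make_panel_fixture",
    "PanelFixture",
]

_CIGAR_RE = re.compile(r"^(\d+[MIDNSHP=X])+$")
_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")


@dataclass(frozen=True)
class ReadSpec:
    """Declarative description of one alignment record.

    ``start`` is 1-based (SAM convention). ``base_qualities`` must have one
    entry per sequence-consuming CIGAR base (M/I/S/=/X). Unmapped reads use
    ``chrom=None`` and ignore the CIGAR.
    """

    chrom: Optional[str]
    start: int
    cigar: str
    base_qualities: Tuple[int, ...]
    mapping_quality: int = 60
    reverse: bool = False
    duplicate: bool = False
    secondary: bool = False
    supplementary: bool = False
    qcfail: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_qualities", tuple(self.base_qualities))
        if self.chrom is None:
            return
        if not _CIGAR_RE.match(self.cigar):
            raise ValueError(f"invalid CIGAR {self.cigar!r}")
        if len(self.base_qualities) != self.query_length:
            raise ValueError(
                f"CIGAR {self.cigar} consumes {self.query_length} bases but "
                f"{len(self.base_qualities)} base qualities given"
            )

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def cigar_ops(self) -> List[Tuple[int, str]]:
        return [(int(n), op) for n, op in _CIGAR_OP_RE.findall(self.cigar)]

    @property
    def query_length(self) -> int:
        return sum(n for n, op in self.cigar_ops if op in _QUERY_OPS)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the reference span (M/D/N/=/X consume)."""
        return (self.start - 1) + sum(n for n, op in self.cigar_ops if op in "MDN=X")


def build_bam(
    reads: Sequence[ReadSpec],
    path: Union[str, Path],
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> Path:
    """Write specs to a coordinate-sorted, indexed BAM; returns the path.

    Header contigs follow ``chrom_lengths`` order when given, else order of
    first appearance among the mapped specs (lengths padded past the
    right-most alignment).
    """
    path = Path(path)
    if chrom_lengths is None:
        chrom_lengths = {}
        for spec in reads:
            if spec.is_mapped:
                needed = spec.reference_end + 1000
                chrom_lengths[spec.chrom] = max(chrom_lengths.get(spec.chrom, 0), needed)
    if not chrom_lengths:
        chrom_lengths = {"stub": 1000}  # header needs >=1 contig even if all unmapped
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length} for chrom, length in chrom_lengths.items()],
    }
    tids = {chrom: i for i, chrom in enumerate(chrom_lengths)}

    with tempfile.TemporaryDirectory() as tmp:
        unsorted = Path(tmp) / "unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
            for i, spec in enumerate(reads):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = spec.name or f"read{i:04d}"
                rec.flag = (
                    (0x4 if not spec.is_mapped else 0)
                    | (0x10 if spec.reverse else 0)
                    | (0x100 if spec.secondary else 0)
                    | (0x200 if spec.qcfail else 0)
                    | (0x400 if spec.duplicate else 0)
                    | (0x800 if spec.supplementary else 0)
                )
                if spec.is_mapped:
                    rec.reference_id = tids[spec.chrom]
                    rec.reference_start = spec.start - 1
                    rec.mapping_quality = spec.mapping_quality
                    rec.cigarstring = spec.cigar
                else:
                    rec.reference_id = -1
                    rec.reference_start = -1
                    rec.mapping_quality = 0
                qlen = len(spec.base_qualities)
                rec.query_sequence = "A" * qlen
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in spec.base_qualities)
                )
                out.write(rec)
        pysam.sort("-o", str(path), str(unsorted))
    pysam.index(str(path))
    return path


def random_fixture(
    rng: random.Random,
    max_reads: int = 100,
    max_regions: int = 3,
    chrom: str = "1",
) -> Tuple[List[TargetRegion], List[ReadSpec]]:
    """Randomized small fixture: <=``max_regions`` regions, <=``max_reads`` reads.

    CIGARs are drawn from plain matches, match-deletion-match,
    match-insertion-match and soft-clip variants; flags, strands, MQs
    (including 255) and BQs vary. Deterministic given ``rng``'s state.
    """
    n_regions = rng.randint(1, max_regions)
    regions = []
    cursor = rng.randint(100, 500)
    for i in range(n_regions):
        length = rng.randint(5, 60)
        regions.append(
            TargetRegion(name=f"G{i}_{i + 1}", chrom=chrom, start=cursor, end=cursor + length)
        )
        cursor += length + rng.randint(0, 80)

    reads: List[ReadSpec] = []
    for _ in range(rng.randint(0, max_reads)):
        start = rng.randint(max(1, regions[0].start - 60), regions[-1].end + 30)
        shape = rng.choice(("M", "MDM", "MIM", "SM", "MS", "SMS"))
        if shape == "M":
            m = rng.randint(5, 80)
            cigar = f"{m}M"
        elif shape == "MDM":
            a, d, b = rng.randint(3, 30), rng.randint(1, 10), rng.randint(3, 30)
            cigar = f"{a}M{d}D{b}M"
        elif shape == "MIM":
            a, ins, b = rng.randint(3, 30), rng.randint(1, 8), rng.randint(3, 30)
            cigar = f"{a}M{ins}I{b}M"
        elif shape == "SM":
            s, m = rng.randint(1, 10), rng.randint(5, 50)
            cigar = f"{s}S{m}M"
        elif shape == "MS":
            m, s = rng.randint(5, 50), rng.randint(1, 10)
            cigar = f"{m}M{s}S"
        else:
            s1, m, s2 = rng.randint(1, 8), rng.randint(5, 50), rng.randint(1, 8)
            cigar = f"{s1}S{m}M{s2}S"
        qlen = sum(int(n) for n, op in _CIGAR_OP_RE.findall(cigar) if op in _QUERY_OPS)
        reads.append(
            ReadSpec(
                chrom=chrom,
                start=start,
                cigar=cigar,
                base_qualities=tuple(rng.choice((2, 5, 9, 10, 11, 25, 40)) for _ in range(qlen)),
                mapping_quality=rng.choice((0, 5, 19, 20, 21, 60, 255)),
                reverse=rng.random() < 0.5,
                duplicate=rng.random() < 0.15,
                secondary=rng.random() < 0.05,
                supplementary=rng.random() < 0.05,
                qcfail=rng.random() < 0.05,
            )
        )
    return regions, reads


@dataclass
class PanelFixture:
    """A deterministic multi-region panel with known expected flag outcomes."""

    bam: Path
    bed: Path
    transcript_db: Path
    regions: List[TargetRegion]
    reads: List[ReadSpec]
    expected_status: Dict[str, str] = field(default_factory=dict)


def _tiled_reads(
    rng: random.Random,
    chrom: str,
    region_start: int,
    region_end: int,
    n_reads: int,
    read_len: int = 60,
    mq: int = 60,
    bq: int = 35,
    reverse_fraction: float = 0.5,
    cigar_of: Optional[str] = None,
) -> List[ReadSpec]:
    reads = []
    span = region_end - region_start
    for i in range(n_reads):
        offset = rng.randint(-read_len + 5, max(span - 5, 1))
        start0 = max(0, region_start + offset)
        cigar = cigar_of or f"{read_len}M"
        qlen = sum(int(n) for n, op in _CIGAR_OP_RE.findall(cigar) if op in _QUERY_OPS)
        reads.append(
            ReadSpec(
                chrom=chrom,
                start=start0 + 1,
                cigar=cigar,
                base_qualities=tuple(max(2, bq + rng.randint(-3, 3)) for _ in range(qlen)),
                mapping_quality=mq,
                reverse=rng.random() < reverse_fraction,
            )
        )
    return reads


def make_panel_fixture(seed: int, outdir: Union[str, Path]) -> PanelFixture:
    """Deterministic five-region panel covering the canonical failure modes.

    Regions (MINQCOV >= 50 is the intended pass rule):

    * ``GOODGENE_1``  deep, high-quality coverage            -> PASS
    * ``PSEUDO_2``    deep coverage, ~90% of reads MQ < 20
                      (pseudogene-style ambiguous mapping:
                      high COV, collapsed QCOV)              -> FLAG
    * ``EMPTY_3``     no reads at all                        -> FLAG
    * ``FWDONLY_4``   ample coverage, all forward strand     -> PASS
    * ``DELGENE_5``   half the reads delete the region core
                      (QCOV dips below 50 inside)            -> FLAG
    """
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = "1"

    spans = {
        "GOODGENE_1": (1000, 1120),
        "PSEUDO_2": (2000, 2100),
        "EMPTY_3": (3000, 3080),
        "FWDONLY_4": (4000, 4090),
        "DELGENE_5": (5000, 5100),
    }
    regions = [TargetRegion(name=n, chrom=chrom, start=s, end=e) for n, (s, e) in spans.items()]

    reads: List[ReadSpec] = []
    # deep clean coverage: every base covered by far more than 50 good reads
    reads += _tiled_reads(rng, chrom, *spans["GOODGENE_1"], n_reads=400)
    # pseudogene pattern: 90% of reads low-MQ -> COV high, QCOV ~10% of COV
    s, e = spans["PSEUDO_2"]
    reads += _tiled_reads(rng, chrom, s, e, n_reads=360, mq=0)
    reads += _tiled_reads(rng, chrom, s, e, n_reads=40, mq=60)
    # forward-strand-only region, still well covered
    reads += _tiled_reads(rng, chrom, *spans["FWDONLY_4"], n_reads=300, reverse_fraction=0.0)
    # deletion region: moderate clean coverage (~40x) plus 80 reads whose
    # 20 bp deletion always spans the region core, so COV stays high there
    # while QCOV (clean reads only) sits well below 50
    s, e = spans["DELGENE_5"]
    reads += _tiled_reads(rng, chrom, s, e, n_reads=100)
    for _ in range(80):
        reads.append(
            ReadSpec(
                chrom=chrom,
                start=s + 1,  # deletion fixed over positions s+40 .. s+59
                cigar="40M20D20M",
                base_qualities=tuple(35 for _ in range(60)),
                mapping_quality=60,
                reverse=rng.random() < 0.5,
            )
        )
    # off-target and unmapped background for the chromosome summary
    reads += _tiled_reads(rng, chrom, 8000, 8200, n_reads=30)
    for _ in range(10):
        reads.append(ReadSpec(chrom=None, start=0, cigar="", base_qualities=(30,) * 50))

    bam = build_bam(reads, outdir / "panel.bam", chrom_lengths={chrom: 20000})
    bed = outdir / "panel.bed"
    write_bed(regions, bed)

    # two-exon plus-strand transcript over the pseudogene-pattern region so
    # poor intervals get c. coordinates
    tx_db = outdir / "transcripts.txt"
    tx_db.write_text(
        "\t".join(
            (
                "TX_PSEUDO_1",
                "PSEUDO",
                chrom,
                "+",
                "1985",  # first coding base
                "2155",  # last coding base
                "1975,2060",
                "2040,2160",
            )
        )
        + "\n"
    )

    expected = {
        "GOODGENE_1": "PASS",
        "PSEUDO_2": "FLAG",
        "EMPTY_3": "FLAG",
        "FWDONLY_4": "PASS",
        "DELGENE_5": "FLAG",
    }
    return PanelFixture(
        bam=bam,
        bed=bed,
        transcript_db=tx_db,
        regions=regions,
        reads=reads,
        expected_status=expected,
    )
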