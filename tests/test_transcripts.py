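"""Poor-interval detection and simplified c.-coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelqc.pileup import PerBaseProfile, QualityConfig
from panelqc.regions import TargetRegion
from panelqc.transcripts import (
    OUT_OF_TRANSCRIPT,
    Transcript,
    annotate_poor_intervals,
    find_poor_intervals,
    genomic_to_transcript,
    load_transcript_db,
)

# Two toy two-exon transcripts with UTRs, one per strand. Coordinates are
# 0-based half-open exons; coding_start/coding_end are the first/last coding
# base in transcript 5'->3' order.
PLUS = Transcript(
    id="TXPLUS", gene="GP", chrom="1", strand="+",
    exons=((100, 120), (129, 149)), coding_start=105, coding_end=143,
)
MINUS = Transcript(
    id="TXMINUS", gene="GM", chrom="1", strand="-",
    exons=((200, 220), (230, 250)), coding_start=245, coding_end=204,
)

# hand-derived labels (1-based genomic position -> c. coordinate)
PLUS_TABLE = {
    101: "c.-5", 105: "c.-1", 106: "c.1", 120: "c.15",
    121: "c.15+1", 125: "c.15+5",   # 9-base intron, midpoint anchors upstream
    126: "c.16-4", 129: "c.16-1", 130: "c.16",
    144: "c.30", 145: "c.*1", 149: "c.*5",
}
MINUS_TABLE = {
    250: "c.-4", 246: "c.1", 231: "c.16",
    230: "c.16+1", 226: "c.16+5", 225: "c.17-5", 221: "c.17-1",
    220: "c.17", 205: "c.32", 204: "c.*1", 201: "c.*4",
}


def enumerate_expected(tx):
    """Independent full mapping table built by explicit enumeration.

    Lists the transcript's exonic bases in 5'->3' order, labels them from
    the CDS offsets, then labels each intron base from its distance to the
    two flanking exon edges.
    """
    ordered = []
    exon_iter = tx.exons if tx.strand == "+" else reversed(tx.exons)
    for start, end in exon_iter:
        ordered.extend(range(start, end) if tx.strand == "+" else range(end - 1, start - 1, -1))
    ci = ordered.index(tx.coding_start)
    cj = ordered.index(tx.coding_end)
    table = {}
    for t, g in enumerate(ordered):
        if t < ci:
            table[g] = f"c.-{ci - t}"
        elif t <= cj:
            table[g] = f"c.{t - ci + 1}"
        else:
            table[g] = f"c.*{t - cj}"
    for (_, left_end), (right_start, _) in zip(tx.exons, tx.exons[1:]):
        for g in range(left_end, right_start):
            if tx.strand == "+":
                k_up, k_down = g - (left_end - 1), right_start - g
                up_g, down_g = left_end - 1, right_start
            else:
                k_up, k_down = right_start - g, g - (left_end - 1)
                up_g, down_g = right_start, left_end - 1
            table[g] = (
                f"{table[up_g]}+{k_up}" if k_up <= k_down else f"{table[down_g]}-{k_down}"
            )
    return table


@pytest.mark.parametrize(
    "tx, table", [(PLUS, PLUS_TABLE), (MINUS, MINUS_TABLE)], ids=["plus", "minus"]
)
def test_hand_derived_spot_checks(tx, table):
    for pos, expected in table.items():
        assert genomic_to_transcript(pos, tx) == expected, f"pos {pos}"


@pytest.mark.parametrize("tx", [PLUS, MINUS], ids=["plus", "minus"])
def test_exhaustive_per_base_agreement(tx):
    """Every position across the transcript span matches the enumeration table."""
    expected = enumerate_expected(tx)
    span_start, span_end = tx.span
    for g in range(span_start, span_end):
        assert genomic_to_transcript(g + 1, tx) == expected[g], f"0-based pos {g}"


@pytest.mark.parametrize("tx", [PLUS, MINUS], ids=["plus", "minus"])
def test_out_of_span_positions_get_sentinel(tx):
    span_start, span_end = tx.span
    assert genomic_to_transcript(span_start, tx) == OUT_OF_TRANSCRIPT  # 1-based just before
    assert genomic_to_transcript(span_end + 1, tx) == OUT_OF_TRANSCRIPT


@pytest.mark.parametrize("tx", [PLUS, MINUS], ids=["plus", "minus"])
def test_injective_over_exonic_cds(tx):
    labels = [
        genomic_to_transcript(g + 1, tx)
        for g in range(*tx.span)
        if genomic_to_transcript(g + 1, tx).lstrip("c.").isdigit()
    ]
    assert len(labels) == len(set(labels))


def test_first_coding_base_is_c1():
    assert genomic_to_transcript(PLUS.coding_start + 1, PLUS) == "c.1"
    assert genomic_to_transcript(MINUS.coding_start + 1, MINUS) == "c.1"


def make_qcov_profile(qcov, start=1000):
    qcov = np.asarray(qcov, dtype=np.int64)
    n = len(qcov)
    region = TargetRegion("R_1", "1", start, start + n)
    nan = np.full(n, np.nan)
    return PerBaseProfile(
        region=region,
        positions=np.arange(start + 1, start + n + 1),
        cov=qcov + 5,
        qcov=qcov,
        medbq=nan, flbq=nan, medmq=nan, flmq=nan,
    )


class TestFindPoorIntervals:
    def test_two_runs(self):
        profile = make_qcov_profile([20, 3, 4, 20, 1])
        intervals = find_poor_intervals(profile, QualityConfig(qcov_poor_cutoff=15))
        assert [(iv.start, iv.end, iv.min_qcov) for iv in intervals] == [
            (1002, 1003, 3),
            (1005, 1005, 1),
        ]

    def test_all_good_gives_empty_list(self):
        profile = make_qcov_profile([15, 20, 100])
        assert find_poor_intervals(profile, QualityConfig(qcov_poor_cutoff=15)) == []

    def test_all_poor_spans_region(self):
        profile = make_qcov_profile([0, 1, 2])
        (iv,) = find_poor_intervals(profile, QualityConfig(qcov_poor_cutoff=15))
        assert (iv.start, iv.end) == (1001, 1003)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(qcov=st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=60))
    def test_intervals_tile_exactly_the_poor_positions(self, qcov):
        """Removing the poor intervals leaves exactly the QCOV >= cutoff positions."""
        cfg = QualityConfig(qcov_poor_cutoff=15)
        profile = make_qcov_profile(qcov)
        intervals = find_poor_intervals(profile, cfg)
        in_poor = set()
        for iv in intervals:
            assert iv.min_qcov == min(
                qcov[iv.start - 1001: iv.end - 1000]
            )
            in_poor.update(range(iv.start, iv.end + 1))
        expected = {1001 + i for i, q in enumerate(qcov) if q < 15}
        assert in_poor == expected


class TestTranscriptDb:
    def db_file(self, tmp_path, lines):
        path = tmp_path / "tx.txt"
        path.write_text("".join(line + "\n" for line in lines))
        return path

    def plus_line(self, tx_id="TXPLUS", gene="GP"):
        return f"{tx_id}\t{gene}\t1\t+\t105\t143\t100,129\t120,149"

    def test_single_transcript_lookup(self, tmp_path):
        db = load_transcript_db(self.db_file(tmp_path, [self.plus_line()]))
        hits = db.overlapping("1", 110, 111)
        assert [tx.id for tx in hits] == ["TXPLUS"]
        assert db.overlapping("1", 400, 410) == []
        assert db.overlapping("2", 110, 111) == []

    def test_overlapping_transcripts_both_returned(self, tmp_path):
        db = load_transcript_db(
            self.db_file(
                tmp_path,
                [self.plus_line(), self.plus_line(tx_id="TXPLUS2")],
            )
        )
        assert {tx.id for tx in db.overlapping("1", 110, 111)} == {"TXPLUS", "TXPLUS2"}

    def test_malformed_line_names_line_number(self, tmp_path):
        path = self.db_file(tmp_path, [self.plus_line(), "TX2\tG\t1\t+\tnotanumber"])
        with pytest.raises(ValueError, match=":2:"):
            load_transcript_db(path)

    def test_annotation_attaches_all_overlapping_transcripts(self, tmp_path):
        db = load_transcript_db(
            self.db_file(tmp_path, [self.plus_line(), self.plus_line(tx_id="TXPLUS2")])
        )
        profile = make_qcov_profile([0, 0, 0], start=105)  # positions 106-108
        intervals = annotate_poor_intervals(
            find_poor_intervals(profile, QualityConfig()), db
        )
        (iv,) = intervals
        assert {a[0] for a in iv.annotations} == {"TXPLUS", "TXPLUS2"}
        for _, c_start, c_end in iv.annotations:
            assert (c_start, c_end) == ("c.1", "c.3")

    def test_without_db_intervals_pass_through_unannotated(self):
        profile = make_qcov_profile([0, 0])
        intervals = annotate_poor_intervals(
            find_poor_intervals(profile, QualityConfig()), None
        )
        assert intervals[0].annotations == ()
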