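"""Per-base metric semantics: the hand-derived examples and edge rules."""

import math

import numpy as np
import pytest

from panelqc.fixtures import ReadSpec
from panelqc.pileup import (
    QualityConfig,
    compute_directional_profiles,
    compute_profile,
    count_overlapping_reads,
)
from panelqc.regions import TargetRegion

from conftest import simple_read


class TestThreeReadExample:
    """Three reads at one position, (MQ, BQ) = (60,30), (60,5), (0,30)."""

    @pytest.fixture
    def profile(self, bam_factory, one_base_region):
        reads = [
            simple_read(start=101, length=1, bq=30, mq=60),
            simple_read(start=101, length=1, bq=5, mq=60),
            simple_read(start=101, length=1, bq=30, mq=0),
        ]
        return compute_profile(one_base_region, bam_factory(reads), QualityConfig())

    def test_counts(self, profile):
        assert profile.cov[0] == 3
        assert profile.qcov[0] == 1  # only the MQ60/BQ30 read passes both cutoffs

    def test_fractions(self, profile):
        assert profile.flbq[0] == 1 / 3
        assert profile.flmq[0] == 1 / 3

    def test_medians(self, profile):
        assert profile.medbq[0] == 30.0
        assert profile.medmq[0] == 60.0


def test_uncovered_position_is_undefined(bam_factory, one_base_region):
    bam = bam_factory([simple_read(start=500)])  # read far away
    profile = compute_profile(one_base_region, bam, QualityConfig())
    assert profile.cov[0] == 0 and profile.qcov[0] == 0
    assert all(
        math.isnan(arr[0]) for arr in (profile.medbq, profile.flbq, profile.medmq, profile.flmq)
    )


def test_deletion_spanning_read_covers_but_contributes_no_base(bam_factory, one_base_region):
    # 5M 3D 5M starting at 96: the deletion spans positions 101-103 (1-based)
    read = ReadSpec("1", 96, "5M3D5M", (30,) * 10, mapping_quality=60)
    profile = compute_profile(one_base_region, bam_factory([read]), QualityConfig())
    assert profile.cov[0] == 1
    assert profile.qcov[0] == 0  # a deleted base has no BQ, cannot pass the BQ test
    assert profile.medmq[0] == 60.0
    assert profile.flmq[0] == 0.0
    assert math.isnan(profile.medbq[0]) and math.isnan(profile.flbq[0])


def test_inclusive_cutoffs_pass_at_exact_threshold(bam_factory, one_base_region):
    # BQ exactly 10 and MQ exactly 20 count as good quality
    read = simple_read(start=101, length=1, bq=10, mq=20)
    profile = compute_profile(one_base_region, bam_factory([read]), QualityConfig())
    assert profile.qcov[0] == 1
    assert profile.flbq[0] == 0.0 and profile.flmq[0] == 0.0


def test_mq255_fails_positive_cutoff_but_not_zero_cutoff(bam_factory, one_base_region):
    bam = bam_factory([simple_read(start=101, length=1, bq=30, mq=255)])
    strict = compute_profile(one_base_region, bam, QualityConfig(mq_cutoff=20))
    assert strict.qcov[0] == 0 and strict.flmq[0] == 1.0
    lenient = compute_profile(one_base_region, bam, QualityConfig(mq_cutoff=0))
    assert lenient.qcov[0] == 1 and lenient.flmq[0] == 0.0


def test_insertions_and_soft_clips_do_not_cover(bam_factory):
    region = TargetRegion("R_1", "1", 100, 110)
    reads = [
        # insertion between positions 103 and 104
        ReadSpec("1", 101, "3M4I3M", (30,) * 10, mapping_quality=60),
        # soft clips either side; aligned part covers 103-105 only
        ReadSpec("1", 103, "2S3M2S", (30,) * 7, mapping_quality=60),
        # N skip spans 104-106: does NOT cover (unlike a deletion)
        ReadSpec("1", 101, "3M3N3M", (30,) * 6, mapping_quality=60),
    ]
    profile = compute_profile(region, bam_factory(reads), QualityConfig())
    assert list(profile.cov) == [2, 2, 3, 2, 2, 1, 1, 1, 1, 0]


def test_excluded_flags(bam_factory, one_base_region):
    reads = [
        simple_read(start=101, length=1),
        simple_read(start=101, length=1, secondary=True),
        simple_read(start=101, length=1, supplementary=True),
        simple_read(start=101, length=1, qcfail=True),
    ]
    profile = compute_profile(one_base_region, bam_factory(reads), QualityConfig())
    assert profile.cov[0] == 1  # only the plain primary read counts


def test_duplicate_toggle(bam_factory, one_base_region):
    reads = [simple_read(start=101, length=1), simple_read(start=101, length=1, duplicate=True)]
    bam = bam_factory(reads)
    with_dups = compute_profile(one_base_region, bam, QualityConfig(count_duplicates=True))
    without = compute_profile(one_base_region, bam, QualityConfig(count_duplicates=False))
    assert with_dups.cov[0] == 2
    assert without.cov[0] == 1


def test_even_median_is_mean_of_middle_values(bam_factory, one_base_region):
    bqs = (10, 20, 30, 41)
    reads = [simple_read(start=101, length=1, bq=b) for b in bqs]
    profile = compute_profile(one_base_region, bam_factory(reads), QualityConfig())
    assert profile.medbq[0] == 25.0  # (20 + 30) / 2
    reads = [simple_read(start=101, length=1, bq=30, mq=m) for m in (10, 21)]
    profile = compute_profile(one_base_region, bam_factory(reads), QualityConfig())
    assert profile.medmq[0] == 15.5


class TestDirectionalProfiles:
    def test_partition_by_strand(self, bam_factory, one_base_region):
        reads = [
            simple_read(start=101, length=1),
            simple_read(start=101, length=1),
            simple_read(start=101, length=1, reverse=True),
        ]
        fwd, rev = compute_directional_profiles(one_base_region, bam_factory(reads), QualityConfig())
        assert fwd.cov[0] == 2 and rev.cov[0] == 1

    def test_all_forward_leaves_reverse_undefined(self, bam_factory, one_base_region):
        bam = bam_factory([simple_read(start=101, length=1)])
        fwd, rev = compute_directional_profiles(one_base_region, bam, QualityConfig())
        assert rev.cov[0] == 0 and rev.qcov[0] == 0
        assert math.isnan(rev.medbq[0]) and math.isnan(rev.medmq[0])

    def test_strand_split_sums_reconstruct_unsplit(self, bam_factory):
        import random

        from panelqc.fixtures import random_fixture

        rng = random.Random(20240)
        regions, reads = random_fixture(rng, max_reads=50)
        bam = bam_factory(reads)
        cfg = QualityConfig()
        for region in regions:
            full = compute_profile(region, bam, cfg)
            fwd, rev = compute_directional_profiles(region, bam, cfg)
            assert np.array_equal(full.cov, fwd.cov + rev.cov)
            assert np.array_equal(full.qcov, fwd.qcov + rev.qcov)


def test_absent_chromosome_gives_zero_profile_and_warning(bam_factory, caplog):
    bam = bam_factory([simple_read(chrom="1")])
    region = TargetRegion("ONCHR7_1", "chr7", 100, 110)
    with caplog.at_level("WARNING"):
        profile = compute_profile(region, bam, QualityConfig())
    assert profile.cov.sum() == 0
    assert "chr7" in caplog.text


def test_missing_index_is_hard_error(bam_factory, tmp_path, one_base_region):
    bam = bam_factory([simple_read()])
    bai = bam.with_suffix(".bam.bai")
    bai.unlink()
    with pytest.raises(FileNotFoundError, match="index"):
        compute_profile(one_base_region, bam, QualityConfig())


def test_rc_counts_reads_overlapping_by_reference_span(bam_factory):
    region = TargetRegion("R_1", "1", 100, 110)
    reads = [
        simple_read(start=95, length=10),    # overlaps left edge
        simple_read(start=110, length=10),   # last base in region
        simple_read(start=111, length=10),   # starts past region end -> out
        simple_read(start=80, length=10),    # ends before region -> out
        # deletion bridges the whole region: overlap via reference span
        ReadSpec("1", 91, "5M30D5M", (30,) * 10, mapping_quality=60),
    ]
    assert count_overlapping_reads(region, bam_factory(reads), QualityConfig()) == 3


def test_qcov_monotone_in_cutoffs(bam_factory):
    import random

    from panelqc.fixtures import random_fixture

    rng = random.Random(77)
    regions, reads = random_fixture(rng, max_reads=60)
    bam = bam_factory(reads)
    cutoffs = [(0, 0), (0, 20), (10, 20), (10, 40), (30, 40)]
    for region in regions:
        previous = None
        for bq, mq in cutoffs:
            profile = compute_profile(region, bam, QualityConfig(bq_cutoff=bq, mq_cutoff=mq))
            if previous is not None:
                assert np.all(profile.qcov <= previous)
            previous = profile.qcov
        # both cutoffs zero: QCOV = reads contributing an aligned base <= COV
        baseline = compute_profile(region, bam, QualityConfig(bq_cutoff=0, mq_cutoff=0))
        assert np.all(baseline.qcov <= baseline.cov)


def test_zero_cutoffs_make_qcov_equal_cov_without_deletions(bam_factory):
    region = TargetRegion("R_1", "1", 100, 120)
    reads = [simple_read(start=s, length=15, bq=2, mq=0) for s in (95, 100, 108, 114)]
    profile = compute_profile(region, bam_factory(reads), QualityConfig(bq_cutoff=0, mq_cutoff=0))
    assert np.array_equal(profile.qcov, profile.cov)
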