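"""Shared fixtures and the engine-vs-oracle comparison helpers."""

import math
from pathlib import Path

import pytest

from panelqc.fixtures import ReadSpec, build_bam, make_panel_fixture
from panelqc.regions import TargetRegion


@pytest.fixture
def bam_factory(tmp_path):
    """Callable building an indexed BAM from ReadSpec lists in tmp_path."""
    counter = {"n": 0}

    def _build(reads, chrom_lengths=None):
        counter["n"] += 1
        return build_bam(reads, tmp_path / f"fixture{counter['n']}.bam", chrom_lengths)

    return _build


@pytest.fixture(scope="session")
def panel(tmp_path_factory):
    """The deterministic five-region panel fixture (seed 1)."""
    return make_panel_fixture(1, tmp_path_factory.mktemp("panel"))


def assert_value_equal(engine_value, oracle_value, context=""):
    """NaN in the engine corresponds to None/NaN in the oracle; else exact."""
    engine_undef = isinstance(engine_value, float) and math.isnan(engine_value)
    oracle_undef = oracle_value is None or (
        isinstance(oracle_value, float) and math.isnan(oracle_value)
    )
    if oracle_undef:
        assert engine_undef, f"{context}: engine={engine_value}, oracle undefined"
    else:
        assert engine_value == oracle_value, f"{context}: engine={engine_value}, oracle={oracle_value}"


def assert_profile_equal(engine, oracle, context=""):
    """Exact per-position agreement of all six metrics."""
    assert list(engine.positions) == oracle.positions
    assert list(engine.cov) == oracle.cov, f"{context}: COV"
    assert list(engine.qcov) == oracle.qcov, f"{context}: QCOV"
    for i in range(len(oracle.positions)):
        at = f"{context} pos {oracle.positions[i]}"
        assert_value_equal(float(engine.medbq[i]), oracle.medbq[i], f"{at} MEDBQ")
        assert_value_equal(float(engine.flbq[i]), oracle.flbq[i], f"{at} FLBQ")
        assert_value_equal(float(engine.medmq[i]), oracle.medmq[i], f"{at} MEDMQ")
        assert_value_equal(float(engine.flmq[i]), oracle.flmq[i], f"{at} FLMQ")


def assert_summary_equal(engine, oracle, context=""):
    assert engine.rc == oracle.rc, f"{context}: RC"
    assert engine.medcov == oracle.medcov, f"{context}: MEDCOV"
    assert engine.mincov == oracle.mincov, f"{context}: MINCOV"
    assert engine.medqcov == oracle.medqcov, f"{context}: MEDQCOV"
    assert engine.minqcov == oracle.minqcov, f"{context}: MINQCOV"
    assert_value_equal(engine.maxflmq, oracle.maxflmq, f"{context}: MAXFLMQ")
    assert_value_equal(engine.maxflbq, oracle.maxflbq, f"{context}: MAXFLBQ")


def simple_read(chrom="1", start=101, length=10, bq=30, mq=60, **kwargs):
    """One plain fully-matching read."""
    return ReadSpec(chrom, start, f"{length}M", (bq,) * length, mapping_quality=mq, **kwargs)


@pytest.fixture
def one_base_region():
    return TargetRegion("R_1", "1", 100, 101)
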