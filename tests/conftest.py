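import datetime as dt

import pytest

from audiorules.audiogram import (
    FREQUENCIES,
    Audiogram,
    EarRecord,
    FrequencyThresholds,
    WorkerRecord,
)


def make_thresholds(default=10, **overrides):
    """FrequencyThresholds with a flat default and per-frequency overrides.

    Overrides are given as f500=..., f1000=..., etc.
    """
    levels = {f: default for f in FREQUENCIES}
    for key, value in overrides.items():
        levels[int(key.lstrip("f"))] = value
    return FrequencyThresholds(levels)


def make_audiogram(
    default=10,
    ear="left",
    occasion="annual",
    date="2024-01-01",
    worker_id="W1",
    **overrides,
):
    return Audiogram(
        worker_id=worker_id,
        ear=ear,
        occasion=occasion,
        test_date=date,
        thresholds=make_thresholds(default, **overrides),
    )


def make_ear_record(
    baseline=None, annual=None, retest=None, ear="left", retest_date="2024-02-01"
):
    """EarRecord from threshold specs: each arg is (default, overrides) or None."""

    def _gram(spec, occasion, date):
        default, overrides = spec
        return make_audiogram(
            default, ear=ear, occasion=occasion, date=date, **overrides
        )

    baseline = baseline or (10, {})
    annual = annual or (10, {})
    return EarRecord(
        baseline=_gram(baseline, "baseline", "2023-01-01"),
        annual=_gram(annual, "annual", "2024-01-01"),
        retest=None if retest is None else _gram(retest, "retest", retest_date),
    )


def make_worker(left=None, right=None, worker_id="W1"):
    return WorkerRecord(
        worker_id=worker_id,
        left=left if left is not None else make_ear_record(ear="left"),
        right=right if right is not None else make_ear_record(ear="right"),
    )


@pytest.fixture
def flat_worker():
    """Two-ear worker, all thresholds 10 dB HL, no shift: normal hearing."""
    return make_worker()
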